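"""Per-gene continuous concentration-response modeling.

Each gene's log2CPM values across dose groups are fit under a homoscedastic
Normal likelihood to six mean functions (EPA BMDS continuous conventions):

    Linear  mu(d) = a + b*d
    Poly2   mu(d) = a + b*d + c*d^2
    Power   mu(d) = a + b*d^g,           g >= 1
    Exp2    mu(d) = a*exp(s*b*d),        a > 0, b > 0
    Exp3    mu(d) = a*exp(s*(b*d)^g),    a > 0, b > 0, g >= 1
    Exp4    mu(d) = a*(c - (c-1)*exp(-b*d)),  a > 0, b > 0, c > 0

with the sign ``s`` chosen per gene from the direction of the observed dose
trend. The best model is selected by AIC; the benchmark concentration (BMC)
is the smallest positive dose at which the modeled mean departs from the
control mean by ``bmr_mult`` residual standard deviations. A within-dose-group
nonparametric bootstrap gives the 95% BMC interval, and the three published
filter rules (BMC within tested range, BMCu/BMCl <= 40, best model not Poly2)
define the "has concentration response" flag.

All nonlinear families are fit by profiling: conditional on the nonlinear
parameters the remaining ones are linear and solved in closed form, so each
family reduces to a 1-D (or small-grid 2-D) bounded search. Deterministic
starts; no RNG enters the fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

FAMILIES = ("Exp2", "Exp3", "Exp4", "Linear", "Poly2", "Power")

#: number of mean-function parameters per family (residual SD adds one more)
_N_PARAMS = {"Linear": 2, "Poly2": 3, "Power": 3, "Exp2": 2, "Exp3": 3, "Exp4": 3}


@dataclass
class ContinuousModelFit:
    family: str
    params: dict[str, float]
    s: float  # residual SD, sqrt(RSS / (n - k))
    loglik: float
    aic: float
    converged: bool
    direction: int  # +1 rising, -1 falling at the top dose
    n: int

    def predict(self, d: np.ndarray) -> np.ndarray:
        return _MEAN_FUNCS[self.family](np.asarray(d, dtype=float), self.params)


@dataclass
class GeneBMCRecord:
    gene: str
    best_model: str | None
    bmc_uM: float | None = None
    bmcl_uM: float | None = None
    bmcu_uM: float | None = None
    ci_ratio: float | None = None
    in_range: bool = False
    ci_ok: bool = False
    monotonic_ok: bool = False
    has_cr: bool = False
    fit: ContinuousModelFit | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# mean functions


def _mu_linear(d, p):
    return p["a"] + p["b"] * d


def _mu_poly2(d, p):
    return p["a"] + p["b"] * d + p["c"] * d * d


def _mu_power(d, p):
    return p["a"] + p["b"] * np.power(d, p["g"])


def _safe_exp(x):
    # log2CPM responses live within ~±20; cap the exponent so degenerate
    # profile points stay finite (their RSS is then huge and never selected)
    return np.exp(np.clip(x, -700.0, 50.0))


def _mu_exp2(d, p):
    return p["a"] * _safe_exp(p["sign"] * p["b"] * d)


def _mu_exp3(d, p):
    return p["a"] * _safe_exp(p["sign"] * np.power(p["b"] * d, p["g"]))


def _mu_exp4(d, p):
    return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-p["b"] * d))


_MEAN_FUNCS = {
    "Linear": _mu_linear,
    "Poly2": _mu_poly2,
    "Power": _mu_power,
    "Exp2": _mu_exp2,
    "Exp3": _mu_exp3,
    "Exp4": _mu_exp4,
}


# ---------------------------------------------------------------------------
# fitting


def _ols_rss(X: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _gauss_fit_stats(rss: float, n: int, k: int):
    sigma2 = max(rss / n, 1e-300)  # MLE variance for the likelihood/AIC
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    aic = 2.0 * (k + 1) - 2.0 * loglik
    s = float(np.sqrt(rss / max(n - k, 1)))
    return s, loglik, aic


def _trend_sign(y: np.ndarray, d: np.ndarray) -> int:
    top = d == d.max()
    ctrl = d == d.min()
    return 1 if y[top].mean() >= y[ctrl].mean() else -1


def fit_family(y: np.ndarray, doses: np.ndarray, family: str) -> ContinuousModelFit:
    """Maximum-likelihood fit of one mean family (see module docstring).

    ``y``: log2CPM per sample; ``doses``: matching concentrations (>= 4 dose
    groups including control, >= 2 replicates each recommended).
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(doses, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    n = y.size
    k = _N_PARAMS[family]
    sign = _trend_sign(y, d)
    dmax = d.max()
    converged = True

    if family == "Linear":
        coef, rss = _ols_rss(np.column_stack([np.ones(n), d]), y)
        params = {"a": coef[0], "b": coef[1]}
    elif family == "Poly2":
        coef, rss = _ols_rss(np.column_stack([np.ones(n), d, d * d]), y)
        params = {"a": coef[0], "b": coef[1], "c": coef[2]}
    elif family == "Power":
        def prof(g):
            return _ols_rss(np.column_stack([np.ones(n), np.power(d, g)]), y)[1]

        g = _scalar_profile(prof, lo=1.0, hi=8.0)
        coef, rss = _ols_rss(np.column_stack([np.ones(n), np.power(d, g)]), y)
        params = {"a": coef[0], "b": coef[1], "g": g}
    elif family == "Exp2":
        def prof(b):
            u = _safe_exp(sign * b * d)
            a = max(float(u @ y) / max(float(u @ u), 1e-300), 1e-8)
            r = y - a * u
            return float(r @ r)

        b = _scalar_profile(prof, lo=1e-9 / dmax, hi=30.0 / dmax, log=True)
        u = _safe_exp(sign * b * d)
        a = max(float(u @ y) / max(float(u @ u), 1e-300), 1e-8)
        rss = prof(b)
        params = {"a": a, "b": b, "sign": sign}
        converged = a > 1e-8
    elif family == "Exp3":
        def prof_g(g):
            def prof(b):
                u = _safe_exp(sign * np.power(b * d, g))
                a = max(float(u @ y) / max(float(u @ u), 1e-300), 1e-8)
                r = y - a * u
                return float(r @ r)

            b = _scalar_profile(prof, lo=1e-9 / dmax, hi=30.0 / dmax, log=True)
            return prof(b), b

        best = None
        for g in (1.0, 1.5, 2.0, 3.0, 4.0):
            rss_g, b_g = prof_g(g)
            if best is None or rss_g < best[0]:
                best = (rss_g, b_g, g)
        # refine the exponent around the coarse optimum
        for g in np.clip(best[2] + np.array([-0.4, -0.2, 0.2, 0.4]), 1.0, 6.0):
            rss_g, b_g = prof_g(float(g))
            if rss_g < best[0]:
                best = (rss_g, b_g, float(g))
        rss, b, g = best
        u = _safe_exp(sign * np.power(b * d, g))
        a = max(float(u @ y) / max(float(u @ u), 1e-300), 1e-8)
        params = {"a": a, "b": b, "g": g, "sign": sign}
        converged = a > 1e-8
    elif family == "Exp4":
        def prof(b):
            X = np.column_stack([np.ones(n), np.exp(-b * d)])
            return _ols_rss(X, y)[1]

        b = _scalar_profile(prof, lo=1e-9 / dmax, hi=30.0 / dmax, log=True)
        X = np.column_stack([np.ones(n), np.exp(-b * d)])
        (A, B), rss = _ols_rss(X, y)
        a = A + B  # mu(0)
        if a <= 1e-8:
            converged = False
            a = max(a, 1e-8)
        c = A / a
        params = {"a": a, "b": b, "c": c}
        converged = converged and c > 0

    s, loglik, aic = _gauss_fit_stats(rss, n, k)
    return ContinuousModelFit(
        family=family,
        params={kk: float(vv) for kk, vv in params.items()},
        s=s,
        loglik=loglik,
        aic=aic,
        converged=bool(converged),
        direction=sign,
        n=n,
    )


def _scalar_profile(fun, lo: float, hi: float, log: bool = False, n_grid: int = 24) -> float:
    """Deterministic grid scan + bounded refinement of a 1-D profile RSS."""
    grid = np.geomspace(lo, hi, n_grid) if log else np.linspace(lo, hi, n_grid)
    vals = [fun(g) for g in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if a == b:
        return float(grid[i])
    res = minimize_scalar(fun, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10 * (b - a) + 1e-14})
    return float(res.x if res.fun <= vals[i] else grid[i])


def fit_all_families(y: np.ndarray, doses: np.ndarray) -> list[ContinuousModelFit]:
    return [fit_family(y, doses, fam) for fam in FAMILIES]


def select_best_aic(fits: list[ContinuousModelFit]) -> ContinuousModelFit:
    """Minimum-AIC converged fit; ties by fewer parameters, then family order."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select from")
    return min(
        ok,
        key=lambda f: (round(f.aic, 10), _N_PARAMS[f.family], FAMILIES.index(f.family)),
    )


# ---------------------------------------------------------------------------
# BMC


def compute_bmc_sd(
    fit: ContinuousModelFit,
    d_max: float,
    bmr_mult: float = 1.35,
    s_override: float | None = None,
) -> float | None:
    """Smallest d > 0 where |mu(d) - mu(0)| = bmr_mult * s, or None.

    Bracketing on a fine dose grid followed by Brent root refinement; None if
    the benchmark response is not attained within (0, d_max]. ``s_override``
    substitutes the control-group SD for the residual SD when configured.
    """
    s = fit.s if s_override is None else s_override
    if s <= 1e-9:  # exactly flat / zero-noise data: benchmark response undefined
        return None
    target = bmr_mult * s
    mu0 = float(fit.predict(np.array([0.0]))[0])

    def delta(d):
        return abs(float(fit.predict(np.array([d]))[0]) - mu0) - target

    grid = np.concatenate([[d_max * 1e-9], np.geomspace(d_max * 1e-6, d_max, 512)])
    vals = np.array([delta(g) for g in grid])
    idx = np.nonzero(vals > 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(grid[0])
    return float(brentq(delta, grid[i - 1], grid[i], xtol=1e-14, rtol=1e-13))


def bmc_closed_form(fit: ContinuousModelFit, bmr_mult: float = 1.35) -> float | None:
    """Analytic BMC for Linear, Power and Exp2 (cross-check for the numeric root)."""
    p = fit.params
    target = bmr_mult * fit.s
    if fit.family == "Linear":
        return None if p["b"] == 0 else target / abs(p["b"])
    if fit.family == "Power":
        return None if p["b"] == 0 else float((target / abs(p["b"])) ** (1.0 / p["g"]))
    if fit.family == "Exp2":
        a, b, sgn = p["a"], p["b"], p["sign"]
        if a <= 0 or b <= 0:
            return None
        if sgn > 0:
            return float(np.log1p(target / a) / b)
        if target >= a:
            return None
        return float(-np.log1p(-target / a) / b)
    raise ValueError(f"no closed form for {fit.family}")


def bootstrap_ci(
    y: np.ndarray,
    doses: np.ndarray,
    best_family: str,
    bmr_mult: float = 1.35,
    B: int = 250,
    seed: int = 0,
) -> tuple[float | None, float | None, int]:
    """Percentile bootstrap 95% CI of the BMC, resampling within dose groups.

    Residuals are resampled with replacement within each dose group around the
    group mean and rescaled by sqrt(n/(n-1)) — the standard finite-sample
    correction, without which tiny groups (n=4 here) make the interval
    anti-conservative. Only the already-selected family is refit per
    replicate. Returns (BMCl, BMCu, n_finite); if fewer than half the
    replicates yield a finite BMC the CI is undefined (None, None, n_finite).
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    d_max = float(d.max())
    group_idx = [np.nonzero(d == u)[0] for u in np.unique(d)]
    group_mean = [y[idx].mean() for idx in group_idx]
    group_resid = [y[idx] - y[idx].mean() for idx in group_idx]
    group_scale = [
        np.sqrt(idx.size / (idx.size - 1)) if idx.size > 1 else 1.0
        for idx in group_idx
    ]
    bmcs = []
    for _ in range(B):
        yb = np.empty_like(y)
        for idx, mean, resid, scale in zip(group_idx, group_mean, group_resid, group_scale):
            draw = resid[rng.integers(0, idx.size, idx.size)]
            yb[idx] = mean + scale * draw
        try:
            fit_b = fit_family(yb, d, best_family)
        except Exception:
            continue
        if not fit_b.converged:
            continue
        bmc = compute_bmc_sd(fit_b, d_max, bmr_mult)
        if bmc is not None and np.isfinite(bmc):
            bmcs.append(bmc)
    n_fin = len(bmcs)
    if n_fin == 0 or n_fin < B / 2:
        return None, None, n_fin
    lo, hi = np.percentile(bmcs, [2.5, 97.5])
    return float(lo), float(hi), n_fin


# ---------------------------------------------------------------------------
# per-gene pipeline + filter cascade


def model_gene(
    gene: str,
    y: np.ndarray,
    doses: np.ndarray,
    bmr_mult: float = 1.35,
    B: int = 250,
    seed: int = 0,
    use_control_sd: bool = False,
) -> GeneBMCRecord:
    """Fit all six families, select by AIC, compute BMC and bootstrap CI."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(doses, dtype=float)
    d_max = float(d.max())
    fits = fit_all_families(y, d)
    try:
        best = select_best_aic(fits)
    except ValueError:
        return GeneBMCRecord(gene=gene, best_model=None)
    s_override = None
    if use_control_sd:
        ctrl = y[d == d.min()]
        s_override = float(np.std(ctrl, ddof=1)) if ctrl.size > 1 else None
    bmc = compute_bmc_sd(best, d_max, bmr_mult, s_override=s_override)
    rec = GeneBMCRecord(gene=gene, best_model=best.family, fit=best)
    if bmc is None:
        return rec
    rec.bmc_uM = bmc
    rec.in_range = bmc <= d_max
    lo, hi, _ = bootstrap_ci(y, d, best.family, bmr_mult, B=B, seed=seed)
    if lo is not None and lo > 0:
        rec.bmcl_uM, rec.bmcu_uM = lo, hi
        rec.ci_ratio = hi / lo
    return rec


def apply_cr_filters(
    records: list[GeneBMCRecord], tested_max_uM: float, ci_ratio_max: float = 40.0
) -> list[GeneBMCRecord]:
    """Set the three concentration-response flags and their conjunction.

    Rules: BMC finite and within the tested range; BMCu/BMCl <= ci_ratio_max;
    best-fit model not Poly2 (non-monotonic fits are removed).
    """
    for r in records:
        r.in_range = bool(
            r.bmc_uM is not None and np.isfinite(r.bmc_uM) and r.bmc_uM <= tested_max_uM
        )
        r.ci_ok = bool(r.ci_ratio is not None and r.ci_ratio <= ci_ratio_max)
        r.monotonic_ok = bool(r.best_model is not None and r.best_model != "Poly2")
        r.has_cr = r.in_range and r.ci_ok and r.monotonic_ok
    return records


def records_to_frame(records: list[GeneBMCRecord]):
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            dict(
                gene=r.gene,
                best_model=r.best_model,
                s=r.fit.s if r.fit else np.nan,
                aic=r.fit.aic if r.fit else np.nan,
                bmc_uM=r.bmc_uM,
                bmcl_uM=r.bmcl_uM,
                bmcu_uM=r.bmcu_uM,
                ci_ratio=r.ci_ratio,
                in_range=r.in_range,
                ci_ok=r.ci_ok,
                monotonic_ok=r.monotonic_ok,
                has_cr=r.has_cr,
            )
        )
    return pd.DataFrame(rows)
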