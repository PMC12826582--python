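"""Dichotomous concentration-response modeling for morphology endpoints.

The incidence of an endpoint at concentration ``d`` is modeled with a
3-parameter log-logistic curve

    p(d) = g + (1 - g) / (1 + exp(-a - b * ln d)),    p(0) = g,

where ``g`` is the background rate, ``a`` the intercept and ``b > 0`` the
slope on log-concentration. Parameters are found by maximizing the binomial
log-likelihood over the dose groups (multi-start bounded optimization). The
benchmark concentration at extra risk R — the dose where
``(p(d) - g) / (1 - g) = R`` — has the closed form

    BMC_R = exp((logit(R) - a) / b),

which is independent of the background ``g``.

A Fisher-exact / Holm time-course test for incidence against matched controls
is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import MorphologyTable

_BOUNDS = [(0.0, 0.995), (-30.0, 30.0), (1e-3, 60.0)]  # g, a, b


@dataclass
class EndpointBMC:
    """Fitted log-logistic curve and extra-risk BMC for one endpoint."""

    endpoint: str
    g: float
    a: float
    b: float
    loglik: float
    converged: bool
    bmc_uM: float | None = None
    in_range: bool | None = None

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return _p_curve(np.asarray(dose, dtype=float), self.g, self.a, self.b)


def _p_curve(d: np.ndarray, g: float, a: float, b: float) -> np.ndarray:
    """Log-logistic incidence; p(0) = g exactly (control never log-transformed)."""
    d = np.asarray(d, dtype=float)
    out = np.full(d.shape, g, dtype=float)
    pos = d > 0
    out[pos] = g + (1.0 - g) * expit(a + b * np.log(d[pos]))
    return out


def _binom_negloglik(params, dose, affected, total):
    g, a, b = params
    p = np.clip(_p_curve(dose, g, a, b), 1e-12, 1.0 - 1e-12)
    return -np.sum(affected * np.log(p) + (total - affected) * np.log1p(-p))


def fit_log_logistic_3p(table: MorphologyTable, endpoint: str, **selectors) -> EndpointBMC:
    """Maximum-likelihood fit of the 3-parameter log-logistic to one endpoint.

    Requires at least 3 distinct nonzero concentrations plus a control group.
    All-zero or all-one incidence is flagged non-estimable (``converged=False``).
    Eight deterministic starts on a coarse (g, a, b) grid; the reported optimum
    is the best across starts.
    """
    inc = table.incidence(endpoint, **selectors)
    dose = inc["concentration_uM"].to_numpy(dtype=float)
    affected = inc["n_affected"].to_numpy(dtype=float)
    total = inc["n_total"].to_numpy(dtype=float)
    if (dose > 0).sum() < 3 or not (dose == 0).any():
        raise ValueError(
            f"endpoint {endpoint!r}: need >=3 nonzero concentrations plus a control"
        )
    if affected.sum() == 0 or (affected == total).all():
        return EndpointBMC(endpoint, float(affected.sum() / total.sum()), 0.0, 1.0,
                           -_binom_negloglik([affected.sum() / total.sum(), 0.0, 1.0],
                                             dose, affected, total),
                           converged=False)

    g0 = max(1e-3, float(affected[dose == 0].sum() / total[dose == 0].sum()))
    mid = float(np.median(dose[dose > 0]))
    starts = [
        (g, -b * np.log(mid) + off, b)
        for g in (min(g0, 0.5), 0.05)
        for off in (-1.0, 1.0)
        for b in (0.7, 3.0)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            _binom_negloglik,
            x0=np.asarray(x0),
            args=(dose, affected, total),
            method="L-BFGS-B",
            bounds=_BOUNDS,
        )
        if best is None or res.fun < best.fun:
            best = res
    g, a, b = best.x
    return EndpointBMC(
        endpoint=endpoint,
        g=float(g),
        a=float(a),
        b=float(b),
        loglik=float(-best.fun),
        converged=bool(best.success or best.fun < np.inf),
    )


def bmc_extra_risk(fit: EndpointBMC, R: float = 0.20) -> float:
    """Concentration at extra risk R: solves (p(d) - g)/(1 - g) = R.

    Closed form ``exp((logit(R) - a)/b)``; independent of the background g.
    """
    if not 0.0 < R < 1.0:
        raise ValueError("extra risk R must be in (0, 1)")
    if fit.b <= 0:
        raise ValueError("slope b must be positive for a finite BMC")
    if not fit.converged:
        raise ValueError(f"endpoint {fit.endpoint!r}: fit did not converge; no BMC")
    return float(np.exp((logit(R) - fit.a) / fit.b))


def fit_endpoint_bmc(
    table: MorphologyTable,
    endpoint: str,
    extra_risk: float = 0.20,
    **selectors,
) -> EndpointBMC:
    """Fit + BMC in one step; sets ``in_range`` against the tested range."""
    fit = fit_log_logistic_3p(table, endpoint, **selectors)
    if fit.converged:
        fit.bmc_uM = bmc_extra_risk(fit, extra_risk)
        top = table.subset(**selectors).data["concentration_uM"].max()
        fit.in_range = bool(fit.bmc_uM <= top)
    return fit


def endpoint_bmc_table(
    table: MorphologyTable,
    endpoints: list[str],
    extra_risk: float = 0.20,
    suppress_out_of_range: bool = True,
    **selectors,
) -> pd.DataFrame:
    """Per-endpoint fit summary; out-of-range BMCs suppressed by default."""
    rows = []
    for ep in endpoints:
        fit = fit_endpoint_bmc(table, ep, extra_risk, **selectors)
        bmc = fit.bmc_uM
        if suppress_out_of_range and fit.in_range is False:
            bmc = np.nan
        rows.append(
            dict(endpoint=ep, g=fit.g, a=fit.a, b=fit.b, loglik=fit.loglik,
                 converged=fit.converged, bmc20_uM=bmc, in_range=fit.in_range)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher / Holm time course


def fisher_exact_two_sided(table_2x2) -> float:
    """Conditional two-sided Fisher p by the sum-of-probabilities convention.

    All tables with the observed margins whose hypergeometric probability does
    not exceed that of the observed table (up to a 1 + 1e-7 relative slack)
    contribute to p.
    """
    (a, b), (c, d) = table_2x2
    n = a + b + c + d
    if n == 0 or (a + b) == 0 or (c + d) == 0 or (a + c) == 0 and (b + d) == 0:
        return 1.0
    r1, k = a + b, a + c
    lo = max(0, r1 + k - n)
    hi = min(r1, k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, k, r1)
    p_obs = hypergeom.pmf(a, n, k, r1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_holm_timecourse(
    table: MorphologyTable, control_concentration: float = 0.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher's exact test of each treated cell against its matched control,
    Holm-corrected over the full endpoint x concentration x timepoint family.

    Cells with a zero-total group give p = 1 with a warning.
    """
    df = table.data
    rows = []
    for (endpoint, timepoint), sub in df.groupby(["endpoint", "timepoint_hpf"]):
        ctrl = sub[sub["concentration_uM"] == control_concentration]
        if ctrl.empty:
            raise ValueError(
                f"no control (concentration {control_concentration}) for "
                f"endpoint {endpoint!r} at {timepoint} hpf"
            )
        yc = int(ctrl["n_affected"].sum())
        nc = int(ctrl["n_total"].sum())
        treated = sub[sub["concentration_uM"] != control_concentration]
        for conc, grp in treated.groupby("concentration_uM"):
            yt = int(grp["n_affected"].sum())
            nt = int(grp["n_total"].sum())
            if nt == 0 or nc == 0:
                warnings.warn(
                    f"zero-total cell for {endpoint!r} at {conc} uM, {timepoint} hpf"
                )
                p = 1.0
            else:
                p = fisher_exact_two_sided([[yt, nt - yt], [yc, nc - yc]])
            rows.append(
                dict(endpoint=endpoint, concentration_uM=conc, timepoint_hpf=timepoint,
                     n_affected=yt, n_total=nt, control_affected=yc, control_total=nc,
                     pvalue=p)
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        _, padj, _, _ = multipletests(out["pvalue"], method="holm")
        out["padj"] = padj
        out["significant"] = out["padj"] <= alpha
    return out
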