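"""Six-family dose-response fits, AIC selection, SD-based BMC, bootstrap CI,
and the concentration-response filter cascade."""

import numpy as np
import pytest

from phenoanchor import (
    FAMILIES,
    GeneBMCRecord,
    apply_cr_filters,
    bmc_closed_form,
    bootstrap_ci,
    compute_bmc_sd,
    fit_all_families,
    fit_family,
    model_gene,
    select_best_aic,
)

DOSES = np.repeat([0.0, 0.133, 1.33, 13.3], 4)


class TestFitFamily:
    def test_noise_free_linear_recovery(self):
        y = 1.0 + 2.0 * DOSES
        fit = fit_family(y, DOSES, "Linear")
        assert fit.params["a"] == pytest.approx(1.0, abs=1e-9)
        assert fit.params["b"] == pytest.approx(2.0, abs=1e-9)
        assert fit.s < 1e-8

    def test_constant_y_flat_everywhere(self):
        y = np.full(DOSES.size, 5.0)
        for fam in FAMILIES:
            fit = fit_family(y, DOSES, fam)
            assert np.allclose(fit.predict(DOSES), 5.0, atol=1e-6)
        best = select_best_aic(fit_all_families(y, DOSES))
        assert compute_bmc_sd(best, DOSES.max()) is None

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            fit_family(np.ones(16), DOSES, "Hill")

    def test_exp4_truth_recognized(self):
        # Exp4 data: the Exp4 fit lands within 2 AIC of the best in most seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = 8.0 * (1.5 - 0.5 * np.exp(-1.0 * DOSES)) + rng.normal(0, 0.1, DOSES.size)
            fits = fit_all_families(y, DOSES)
            best = select_best_aic(fits)
            exp4 = next(f for f in fits if f.family == "Exp4")
            hits += exp4.aic <= best.aic + 2.0
        assert hits >= 0.9 * n_seeds

    def test_direction_follows_trend(self):
        y_up = 2.0 + 0.5 * DOSES
        y_dn = 2.0 - 0.1 * DOSES
        assert fit_family(y_up, DOSES, "Exp2").direction == 1
        assert fit_family(y_dn, DOSES, "Exp2").direction == -1


class TestSelectBestAIC:
    def test_single_fit_returns_itself(self):
        fit = fit_family(1.0 + 2.0 * DOSES, DOSES, "Linear")
        assert select_best_aic([fit]) is fit

    def test_lower_loglik_equal_k_never_selected(self):
        rng = np.random.default_rng(2)
        y = 3.0 + 0.4 * DOSES + rng.normal(0, 0.3, DOSES.size)
        fits = fit_all_families(y, DOSES)
        best = select_best_aic(fits)
        for f in fits:
            if f.converged and f.family != best.family:
                assert f.aic >= best.aic

    def test_aic_penalty_prefers_linear_on_linear_truth(self):
        wins = 0
        n_seeds = 100
        d = np.repeat([0.0, 0.133, 1.33, 13.3], 8)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = 1.0 + 0.3 * d + rng.normal(0, 0.2, d.size)
            lin = fit_family(y, d, "Linear")
            poly = fit_family(y, d, "Poly2")
            wins += lin.aic < poly.aic
        assert wins >= 0.7 * n_seeds

    def test_no_converged_fits_raises(self):
        with pytest.raises(ValueError, match="converged"):
            select_best_aic([])


class TestComputeBMC:
    def test_linear_closed_form_unit(self):
        # b = 1.35, s = 1 -> BMC = 1.35 * 1 / 1.35 = 1.0
        rng = np.random.default_rng(0)
        fit = fit_family(5.0 + 1.35 * DOSES, DOSES, "Linear")
        fit.s = 1.0
        assert compute_bmc_sd(fit, DOSES.max()) == pytest.approx(1.0, abs=1e-9)

    def test_numeric_equals_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            fam = rng.choice(["Linear", "Power", "Exp2"])
            y = {
                "Linear": lambda: 4 + rng.uniform(0.1, 2) * DOSES,
                "Power": lambda: 4 + rng.uniform(0.1, 1) * DOSES ** rng.uniform(1, 2),
                "Exp2": lambda: rng.uniform(2, 8) * np.exp(rng.uniform(0.01, 0.2) * DOSES),
            }[fam]() + rng.normal(0, 0.15, DOSES.size)
            fit = fit_family(y, DOSES, fam)
            if not fit.converged or fit.s <= 0:
                continue
            num = compute_bmc_sd(fit, DOSES.max() * 100)
            ana = bmc_closed_form(fit)
            if num is not None and ana is not None and ana <= DOSES.max() * 100:
                assert num == pytest.approx(ana, abs=1e-9 * max(1.0, ana))

    def test_flat_fit_returns_none(self):
        fit = fit_family(np.full(16, 2.0), DOSES, "Linear")
        assert compute_bmc_sd(fit, DOSES.max()) is None

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        y = 5 + 0.4 * DOSES + rng.normal(0, 0.2, DOSES.size)
        kappa = 7.3
        b1 = compute_bmc_sd(select_best_aic(fit_all_families(y, DOSES)), DOSES.max())
        b2 = compute_bmc_sd(
            select_best_aic(fit_all_families(y, DOSES * kappa)), DOSES.max() * kappa
        )
        assert b2 == pytest.approx(b1 * kappa, rel=1e-6)

    def test_unreached_bmr_is_out_of_range(self):
        rng = np.random.default_rng(4)
        y = 5 + 0.001 * DOSES + rng.normal(0, 0.5, DOSES.size)
        fit = fit_family(y, DOSES, "Linear")
        bmc = compute_bmc_sd(fit, DOSES.max())
        if bmc is not None:
            assert bmc > 0


class TestBootstrapCI:
    def test_fixed_seed_identical(self):
        rng = np.random.default_rng(5)
        y = 4 + 0.4 * DOSES + rng.normal(0, 0.3, DOSES.size)
        ci1 = bootstrap_ci(y, DOSES, "Linear", B=50, seed=9)
        ci2 = bootstrap_ci(y, DOSES, "Linear", B=50, seed=9)
        assert ci1 == ci2

    def test_zero_noise_degenerate(self):
        y = 4 + 0.5 * DOSES
        lo, hi, n = bootstrap_ci(y, DOSES, "Linear", B=50, seed=0)
        # zero residuals: every replicate reproduces the data; BMC -> 0 target
        assert n == 0 or lo == pytest.approx(hi)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(6)
        y = 4 + 0.4 * DOSES + rng.normal(0, 0.3, DOSES.size)
        fit = fit_family(y, DOSES, "Linear")
        bmc = compute_bmc_sd(fit, DOSES.max())
        lo, hi, _ = bootstrap_ci(y, DOSES, "Linear", B=200, seed=1)
        assert lo is not None
        assert lo <= bmc * 1.5 and hi >= bmc * 0.5

    def test_coverage_smoke(self):
        # full 300-repetition version in the acceptance suite
        rng = np.random.default_rng(42)
        amp = 1.35 * 0.3
        cover = 0
        n = 40
        for rep in range(n):
            bmc = np.exp(rng.uniform(np.log(0.3), np.log(8.0)))
            y = 8 + amp * DOSES / bmc + rng.normal(0, 0.3, DOSES.size)
            lo, hi, _ = bootstrap_ci(y, DOSES, "Linear", B=100, seed=rep)
            if lo is not None:
                cover += lo <= bmc <= hi
        assert cover >= 0.8 * n


class TestFilterCascade:
    def _record(self, **kw):
        base = dict(gene="g", best_model="Linear", bmc_uM=1.0,
                    bmcl_uM=0.5, bmcu_uM=2.0, ci_ratio=4.0)
        base.update(kw)
        return GeneBMCRecord(**base)

    def test_ci_ratio_boundary(self):
        over = self._record(ci_ratio=45.0)
        at = self._record(ci_ratio=40.0)
        apply_cr_filters([over, at], tested_max_uM=13.3, ci_ratio_max=40.0)
        assert not over.ci_ok and not over.has_cr
        assert at.ci_ok and at.has_cr

    def test_poly2_not_monotonic(self):
        rec = self._record(best_model="Poly2")
        apply_cr_filters([rec], tested_max_uM=13.3)
        assert not rec.monotonic_ok and not rec.has_cr

    def test_bmc_above_top_dose_out_of_range(self):
        rec = self._record(bmc_uM=20.0)
        apply_cr_filters([rec], tested_max_uM=13.3)
        assert not rec.in_range and not rec.has_cr

    def test_has_cr_is_conjunction(self):
        rec = self._record()
        apply_cr_filters([rec], tested_max_uM=13.3)
        assert rec.has_cr == (rec.in_range and rec.ci_ok and rec.monotonic_ok)
        assert rec.has_cr


class TestModelGene:
    def test_zero_noise_linear_end_to_end(self):
        y = 3.0 + 0.27 * DOSES  # s ~ 0 -> BMC ~ 0, flagged via CI path
        rec = model_gene("g", y, DOSES, B=20, seed=0)
        assert rec.best_model is not None

    def test_responsive_gene_recovered(self):
        rng = np.random.default_rng(11)
        sigma, bmc = 0.25, 1.5
        y = 6.0 + 1.35 * sigma * DOSES / bmc + rng.normal(0, sigma, DOSES.size)
        rec = model_gene("g", y, DOSES, B=100, seed=3)
        assert rec.bmc_uM is not None
        assert 0.3 < rec.bmc_uM < 7.0
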