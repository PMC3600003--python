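"""Logistic fits, stepwise-AIC selection, pseudo-r² and TSS distances."""

import math

import numpy as np
import pandas as pd
import pytest

from circenrich.io import LdMap
from circenrich.model import (
    ModelFit,
    ModelTerm,
    combined_annotation_or,
    distance_to_tss,
    fit_logistic,
    lr_deviance_test,
    pseudo_r2,
    stepwise_aic,
)
from circenrich.stats import DegenerateTableError

from conftest import make_catalog
from test_permutation import matrix_from_array

LOGISTIC_VAR = math.pi**2 / 3


def make_fit(loglik=-100.0, n_terms=1, eta=None, n_obs=10):
    eta = np.zeros(n_obs) if eta is None else np.asarray(eta, float)
    terms = tuple(
        ModelTerm(f"x{i}", 0.0, 1.0, 0.0, 1.0) for i in range(n_terms)
    )
    return ModelFit(
        terms=terms, loglik=loglik, aic=2 * n_terms - 2 * loglik,
        n_obs=len(eta), forced_terms=frozenset(), separation_flag=False,
        linear_predictor=eta,
    )


class TestFitLogistic:
    def test_intercept_only_balanced_response(self):
        y = np.array([0, 1] * 50)
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.term("const").estimate == pytest.approx(0.0, abs=1e-8)

    def test_saturated_binary_covariate_oracle(self):
        # response rate 0.8 when x=1, 0.2 when x=0: the saturated logit has
        # slope logit(0.8) - logit(0.2) = 2 ln 4
        x = np.repeat([0.0, 1.0], 100)
        y = np.concatenate([np.tile([1, 0, 0, 0, 0], 20)[:100],
                            np.tile([1, 1, 1, 1, 0], 20)[:100]])
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        want = math.log(0.8 / 0.2) - math.log(0.2 / 0.8)
        assert fit.term("x").estimate == pytest.approx(want, rel=1e-4)
        assert want == pytest.approx(2.7726, abs=1e-4)

    def test_beta_coefficient_is_wald_z(self):
        rng = np.random.default_rng(0)
        x = rng.random(500)
        y = (rng.random(500) < 1 / (1 + np.exp(-(x - 0.5)))).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        for t in fit.terms:
            assert t.beta_coefficient == pytest.approx(t.estimate / t.se)
            # squared Wald z reproduces the Wald chi-square
            from scipy import stats as sps

            chi2_p = sps.chi2.sf(t.beta_coefficient**2, 1)
            assert chi2_p == pytest.approx(t.pvalue, abs=1e-6)

    def test_separation_flagged(self):
        x = np.repeat([0.0, 1.0], 20)
        fit = fit_logistic(x.copy(), pd.DataFrame({"x": x}))
        assert fit.separation_flag

    def test_single_class_response_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_constant_covariate_rejected(self):
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(y, pd.DataFrame({"x": np.ones(10)}))

    def test_aic_identity(self):
        rng = np.random.default_rng(1)
        x = rng.random(200)
        y = (rng.random(200) < 0.3).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.aic == pytest.approx(2 * len(fit.terms) - 2 * fit.loglik)


class TestStepwise:
    @staticmethod
    def _simulate(rng, n, beta_annot):
        platform = (rng.random(n) < 0.5).astype(float)
        annot = (rng.random(n) < 0.2).astype(float)
        noise1 = (rng.random(n) < 0.2).astype(float)
        noise2 = (rng.random(n) < 0.3).astype(float)
        eta = -2.0 + 0.5 * platform + beta_annot * annot
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = pd.DataFrame(
            {"annot": annot, "noise1": noise1, "noise2": noise2,
             "platform_a": platform}
        )
        return y, data

    def test_planted_strong_effect_selected(self):
        rng = np.random.default_rng(5)
        y, data = self._simulate(rng, 50_000, math.log(4.0))
        log = []
        fit = stepwise_aic(y, data, ["platform_a"],
                          ["annot", "noise1", "noise2"], step_log=log)
        chosen = [t.name for t in fit.terms if t.name.startswith(("annot", "noise"))]
        assert "annot" in chosen

    def test_null_candidates_mostly_rejected(self):
        rng = np.random.default_rng(6)
        y, data = self._simulate(rng, 50_000, 0.0)
        fit = stepwise_aic(y, data, ["platform_a"],
                          ["annot", "noise1", "noise2"])
        # with no signal the base model should survive (AIC penalty 2 per term)
        extra = [t.name for t in fit.terms
                 if t.name not in ("const", "platform_a")]
        assert len(extra) <= 1  # chance inclusions happen ~15% per candidate

    def test_final_aic_never_above_base(self):
        rng = np.random.default_rng(7)
        y, data = self._simulate(rng, 20_000, math.log(3.0))
        base = fit_logistic(y, data[["platform_a"]], forced_terms=["platform_a"])
        fit = stepwise_aic(y, data, ["platform_a"], ["annot", "noise1", "noise2"])
        assert fit.aic <= base.aic

    def test_step_log_monotone_decreasing(self):
        rng = np.random.default_rng(8)
        y, data = self._simulate(rng, 20_000, math.log(3.0))
        log = []
        stepwise_aic(y, data, ["platform_a"], ["annot", "noise1", "noise2"],
                     step_log=log)
        aics = [a for _, _, a in log]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_blacklist_excluded_from_candidacy(self):
        rng = np.random.default_rng(9)
        y, data = self._simulate(rng, 20_000, math.log(4.0))
        fit = stepwise_aic(y, data, ["platform_a"],
                          ["annot", "noise1", "noise2"], blacklist={"annot"})
        assert "annot" not in fit.term_names


class TestPseudoR2:
    def test_full_equals_empty_is_zero(self):
        fit = make_fit(loglik=-100.0, eta=np.zeros(10))
        r2 = pseudo_r2(fit, fit)
        assert r2.mcfadden == 0.0
        assert r2.mckelvey_zavoina == 0.0

    def test_mcfadden_direct_formula(self):
        r2 = pseudo_r2(make_fit(loglik=-100.0), make_fit(loglik=-50.0))
        assert r2.mcfadden == pytest.approx(0.5)

    def test_mckelvey_zavoina_half_at_latent_variance(self):
        # linear predictor with sample variance exactly pi^2/3
        eta = np.array([-1.0, 1.0]) * math.sqrt(LOGISTIC_VAR / 2)
        r2 = pseudo_r2(make_fit(), make_fit(eta=eta))
        assert np.var(eta, ddof=1) == pytest.approx(LOGISTIC_VAR)
        assert r2.mckelvey_zavoina == pytest.approx(0.5)

    def test_zero_empty_loglik_errors(self):
        with pytest.raises(ValueError):
            pseudo_r2(make_fit(loglik=0.0), make_fit(loglik=-1.0))

    def test_mcfadden_increases_with_informative_covariate(self):
        rng = np.random.default_rng(10)
        x = (rng.random(5_000) < 0.3).astype(float)
        y = (rng.random(5_000) < 1 / (1 + np.exp(-(-1.0 + 1.5 * x)))).astype(float)
        junk = (rng.random(5_000) < 0.5).astype(float)
        empty = fit_logistic(y, pd.DataFrame({"j": junk}))
        full = fit_logistic(y, pd.DataFrame({"j": junk, "x": x}))
        assert pseudo_r2(empty, full).mcfadden > pseudo_r2(empty, empty).mcfadden


class TestDevianceTest:
    def test_identical_models_zero_deviance(self):
        fit = make_fit(loglik=-80.0, n_terms=2)
        bigger = make_fit(loglik=-80.0, n_terms=3)
        cmp_ = lr_deviance_test(fit, bigger)
        assert cmp_.deviance == 0.0
        assert cmp_.pvalue == pytest.approx(1.0)

    def test_direct_formula(self):
        cmp_ = lr_deviance_test(make_fit(loglik=-100.0, n_terms=1),
                                make_fit(loglik=-50.0, n_terms=26))
        assert cmp_.deviance == pytest.approx(100.0)
        assert cmp_.df == 25

    def test_negative_deviance_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            cmp_ = lr_deviance_test(make_fit(loglik=-50.0, n_terms=1),
                                    make_fit(loglik=-50.000001, n_terms=2))
        assert cmp_.deviance == 0.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lr_deviance_test(make_fit(n_terms=3), make_fit(n_terms=3))


class TestCombinedAnnotationOr:
    def test_formula_oracle_toy_table(self):
        # table (96, 4, 770, 230): OR = (96*230)/(4*770) ~ 7.17
        values = np.zeros((1100, 1), bool)
        status = np.zeros(1100, bool)
        status[:100] = True
        values[:96, 0] = True  # 96 associated hits, 4 non-hits
        values[100:870, 0] = True  # 770 background hits, 230 non-hits
        res = combined_annotation_or(matrix_from_array(values), ["t0"], status)
        assert res.odds_ratio == pytest.approx((96 * 230) / (4 * 770))
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_any_of_set_semantics(self):
        values = np.array([[1, 0], [0, 1], [0, 0], [0, 0]], bool)
        status = np.array([1, 1, 0, 1], bool)
        res = combined_annotation_or(matrix_from_array(values), ["t0", "t1"], status)
        # hits: rows 0,1; assoc rows 0,1,3 -> a=2 b=1 c=0 d=1
        assert math.isinf(res.odds_ratio)

    def test_all_snps_hit_is_degenerate(self):
        values = np.ones((10, 1), bool)
        status = np.array([1] * 3 + [0] * 7, bool)
        with pytest.raises(DegenerateTableError):
            combined_annotation_or(matrix_from_array(values), ["t0"], status)

    def test_independent_status_gives_or_near_one(self):
        rng = np.random.default_rng(11)
        values = (rng.random((50_000, 1)) < 0.3)
        status = rng.random(50_000) < 0.1
        res = combined_annotation_or(matrix_from_array(values), ["t0"], status)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)

    def test_empty_positive_set_rejected(self):
        with pytest.raises(ValueError):
            combined_annotation_or(matrix_from_array(np.ones((4, 1), bool)),
                                   [], np.array([1, 0, 0, 1], bool))


class TestDistanceToTss:
    def _tss(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])

    def test_plus_strand_upstream_geometry(self):
        cat = make_catalog([("s", "1", 1_000, {"g"})])
        d = distance_to_tss(cat, LdMap({}), self._tss([("1", 1_500, "+")]))
        assert d[0] == 500

    def test_minus_strand_upstream_geometry(self):
        cat = make_catalog([("s", "1", 1_000, {"g"})])
        d = distance_to_tss(cat, LdMap({}), self._tss([("1", 400, "-")]))
        assert d[0] == 600

    def test_downstream_only_is_missing_then_capped(self):
        # SNP downstream of the only (+) TSS: no upstream TSS at all
        cat = make_catalog([("s", "1", 2_000, {"g"})])
        tss = self._tss([("1", 1_500, "+")])
        assert np.isnan(distance_to_tss(cat, LdMap({}), tss)[0])
        assert distance_to_tss(cat, LdMap({}), tss, cap=1e6)[0] == 1e6

    def test_minimum_over_ld_partners(self):
        cat = make_catalog([("a", "1", 1_000, {"g"}), ("b", "1", 1_400, {"g"})])
        tss = self._tss([("1", 1_500, "+")])
        ld = LdMap({"a": {"b"}})
        d = distance_to_tss(cat, ld, tss)
        assert d[0] == 100  # partner b at 1400 is closer upstream
        d_own = distance_to_tss(cat, ld, tss, snp_only=True)
        assert d_own[0] == 500

    def test_nearest_of_many_tss(self):
        cat = make_catalog([("s", "1", 1_000, {"g"})])
        tss = self._tss([("1", 900, "-"), ("1", 1_200, "+"), ("1", 5_000, "+")])
        assert distance_to_tss(cat, LdMap({}), tss)[0] == 100

    def test_empty_tss_rejected(self):
        cat = make_catalog([("s", "1", 1_000, {"g"})])
        with pytest.raises(ValueError):
            distance_to_tss(cat, LdMap({}), self._tss([]))
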