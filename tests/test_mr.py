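"""MR estimators, sensitivity analyses and multiple-testing control."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmoloc.exceptions import AnalysisError, ParameterError
from mrmoloc.mr import (
    MRModel,
    bonferroni_threshold,
    ivw,
    leave_one_out,
    reverse_mr,
    steiger_from_r2,
    steiger_test,
    wald_ratio,
)
from mrmoloc.synth import SimScenario, simulate_traits_and_sumstats
from mrmoloc.sumstats import harmonize

from conftest import make_pair, make_variant


class TestWaldRatio:
    def test_zero_numerator_gives_zero_estimate(self):
        res = wald_ratio(make_pair(beta_outcome=0.0, se_outcome=0.05,
                                   beta_exposure=0.5))
        assert res.estimate == 0.0
        assert res.pval == pytest.approx(1.0)

    def test_closed_form_ratio_and_scale(self):
        res = wald_ratio(make_pair(beta_exposure=0.5, beta_outcome=0.10,
                                   se_outcome=0.05))
        assert res.estimate == pytest.approx(0.20)
        assert res.se == pytest.approx(0.10)
        assert res.n_instruments == 1

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(AnalysisError, match="undefined"):
            wald_ratio(make_pair(beta_exposure=0.0))

    def test_second_order_se_adds_exposure_uncertainty(self):
        p = make_pair(beta_exposure=0.5, se_exposure=0.1, beta_outcome=0.1,
                      se_outcome=0.05)
        first = wald_ratio(p)
        second = wald_ratio(p, second_order=True)
        expected = math.sqrt(0.05**2 / 0.5**2 + 0.1**2 * 0.1**2 / 0.5**4)
        assert second.se == pytest.approx(expected)
        assert second.se > first.se


class TestIVW:
    def test_single_pair_reduces_to_wald_ratio(self):
        p = make_pair()
        w = wald_ratio(p)
        i = ivw([p], min_instruments=1)
        assert i.estimate == pytest.approx(w.estimate, rel=1e-14)
        assert i.se == pytest.approx(w.se, rel=1e-14)

    def test_equal_weights_average_ratios(self):
        pairs = [make_pair("rs1", beta_exposure=0.5, beta_outcome=0.05,
                           se_outcome=0.05),
                 make_pair("rs2", beta_exposure=0.5, beta_outcome=0.15,
                           se_outcome=0.05)]
        res = ivw(pairs)
        assert res.estimate == pytest.approx(0.2)

    def test_too_few_instruments_is_error(self):
        with pytest.raises(AnalysisError, match=">= 2"):
            ivw([make_pair()])

    def test_matches_wls_through_origin_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(50):
            k = rng.integers(2, 8)
            gamma = rng.normal(0.3, 0.1, k) + 0.05
            Gamma = rng.normal(0.05, 0.05, k)
            sy = rng.uniform(0.01, 0.1, k)
            pairs = [make_pair(f"rs{j}", beta_exposure=gamma[j],
                               beta_outcome=Gamma[j], se_outcome=sy[j])
                     for j in range(k)]
            res = ivw(pairs)
            fit = sm.WLS(Gamma, gamma, weights=1.0 / sy**2).fit()
            assert res.estimate == pytest.approx(fit.params[0], abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_sign_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        k = 4
        pairs = [make_pair(f"rs{j}", beta_exposure=rng.uniform(0.1, 0.5),
                           beta_outcome=rng.normal(0, 0.1),
                           se_outcome=rng.uniform(0.02, 0.1))
                 for j in range(k)]
        base = ivw(pairs).estimate
        neg_exp = [make_pair(p.variant_id, beta_exposure=-p.beta_exposure,
                             beta_outcome=p.beta_outcome,
                             se_outcome=p.se_outcome) for p in pairs]
        neg_out = [make_pair(p.variant_id, beta_exposure=p.beta_exposure,
                             beta_outcome=-p.beta_outcome,
                             se_outcome=p.se_outcome) for p in pairs]
        assert ivw(neg_exp).estimate == pytest.approx(-base, rel=1e-12)
        assert ivw(neg_out).estimate == pytest.approx(-base, rel=1e-12)

    def test_pvalue_stays_finite_below_underflow(self):
        pairs = [make_pair(f"rs{j}", beta_exposure=1.0, beta_outcome=1.0,
                           se_outcome=1e-3) for j in range(3)]
        res = ivw(pairs)
        assert res.pval == 0.0  # underflows as a float
        assert np.isfinite(res.neg_log10_pval)
        assert res.neg_log10_pval > 300


class TestLeaveOneOut:
    def test_identical_pairs_give_identical_estimates(self):
        pairs = [make_pair(f"rs{j}") for j in range(3)]
        full = ivw(pairs)
        for _, res in leave_one_out(pairs):
            assert res.estimate == pytest.approx(full.estimate)

    def test_cardinality_and_reduced_set_exactness(self):
        rng = np.random.default_rng(3)
        pairs = [make_pair(f"rs{j}", beta_outcome=rng.normal(0.1, 0.02))
                 for j in range(5)]
        loo = leave_one_out(pairs)
        assert len(loo) == 5
        for i, (vid, res) in enumerate(loo):
            assert vid == pairs[i].variant_id
            reduced = ivw(pairs[:i] + pairs[i + 1:])
            assert res.estimate == pytest.approx(reduced.estimate, abs=0)
            assert res.se == pytest.approx(reduced.se, abs=0)

    def test_outlier_has_largest_influence(self):
        pairs = [make_pair(f"rs{j}", beta_outcome=0.10) for j in range(3)]
        pairs.append(make_pair("rs_outlier", beta_outcome=0.60))
        full = ivw(pairs).estimate
        deltas = {vid: abs(res.estimate - full)
                  for vid, res in leave_one_out(pairs)}
        assert max(deltas, key=deltas.get) == "rs_outlier"

    def test_fewer_than_three_is_error(self):
        with pytest.raises(AnalysisError):
            leave_one_out([make_pair("rs1"), make_pair("rs2")])


class TestSteiger:
    def test_exact_tie_is_null(self):
        res = steiger_from_r2(0.02, 0.02, 5000, 5000)
        assert res.z == 0.0
        assert res.pval == pytest.approx(1.0)
        assert not res.correct_direction

    def test_fisher_z_closed_form(self):
        # independent evaluation of the Fisher-transform z statistic
        r1, r2, n = math.sqrt(0.04), math.sqrt(0.0004), 5000
        z_expected = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(2 / (n - 3))
        res = steiger_from_r2(0.04, 0.0004, n, n)
        assert res.z == pytest.approx(z_expected)
        assert res.correct_direction
        assert res.pval < 1e-10

    def test_reversed_variance_explained_flags_wrong_direction(self):
        res = steiger_from_r2(0.001, 0.05, 5000, 5000)
        assert not res.correct_direction
        assert res.z < 0

    def test_from_pair_uses_t_statistic_form(self):
        p = make_pair(beta_exposure=0.3, se_exposure=0.02,
                      beta_outcome=0.03, se_outcome=0.02)
        res = steiger_test(p)
        t2e = (0.3 / 0.02) ** 2
        assert res.r2_exposure == pytest.approx(t2e / (t2e + 5000 - 2))
        assert res.correct_direction

    def test_af_form_for_sd_scale_betas(self):
        p = make_pair(beta_exposure=0.3, eaf_exposure=0.3)
        res = steiger_test(p, r2_method="af")
        assert res.r2_exposure == pytest.approx(2 * 0.3 * 0.7 * 0.09)

    def test_missing_sample_size_is_error(self):
        p = make_pair(n_exposure=0)
        with pytest.raises(AnalysisError):
            steiger_test(p)


class TestBonferroni:
    def test_printed_thresholds(self):
        assert bonferroni_threshold(9, 9) == pytest.approx(6.17e-4, rel=5e-3)
        assert bonferroni_threshold(8, 9) == pytest.approx(6.94e-4, rel=5e-3)
        assert bonferroni_threshold(1, 1) == 0.05

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni_threshold(0, 9)


def _mr_scenario(true_slope, seed, n=10_000):
    gammas = [0.35, 0.3, 0.4, 0.3, 0.35]
    return SimScenario(
        n_variants=5,
        maf=np.full(5, 0.3),
        ld_rho=0.0,
        cohort_sizes={"exposure": n, "outcome": n},
        causal_map={"exposure": list(enumerate(gammas)), "outcome": []},
        trait_types={"exposure": "quantitative", "outcome": "quantitative"},
        noise_sd={"exposure": 1.0, "outcome": 1.0},
        causal_beta_exposure_to_outcome=true_slope,
        mr_exposure="exposure",
        mr_outcome="outcome",
        seed=seed,
    )


class TestReverseMR:
    def test_forward_significant_reverse_covers_zero(self):
        # genotype -> exposure -> disease, plus disease-specific loci that do
        # not act through the exposure (the reverse-MR instruments)
        scenario = SimScenario(
            n_variants=10,
            maf=np.full(10, 0.3),
            ld_rho=0.0,
            cohort_sizes={"exposure": 10_000, "outcome": 10_000},
            causal_map={
                "exposure": [(j, 0.35) for j in range(5)],
                "outcome": [(j, 0.15) for j in range(5, 10)],
            },
            trait_types={"exposure": "quantitative", "outcome": "quantitative"},
            noise_sd={"exposure": 1.0, "outcome": 1.0},
            causal_beta_exposure_to_outcome=0.1,
            mr_exposure="exposure",
            mr_outcome="outcome",
            seed=2024,
        )
        sim = simulate_traits_and_sumstats(scenario)
        exp_inst = sim.sumstats["exposure"].subset(
            sim.truth.causal_variants["exposure"])
        pairs = harmonize(exp_inst, sim.sumstats["outcome"])
        forward = ivw(pairs)
        lo, hi = forward.conf_int()
        assert lo > 0  # forward CI excludes 0
        rev = reverse_mr(sim.sumstats["outcome"], sim.sumstats["exposure"],
                         sim.ld)
        assert rev.flag == ""
        rlo, rhi = rev.conf_int()
        assert rlo < 0 < rhi  # reverse CI covers 0

    def test_no_significant_instruments_flags_underpowered(self):
        sim = simulate_traits_and_sumstats(_mr_scenario(0.0, seed=5, n=500))
        res = reverse_mr(sim.sumstats["outcome"], sim.sumstats["exposure"],
                         sim.ld)
        assert res.flag == "underpowered"
        assert math.isnan(res.estimate)


class TestMRModel:
    def test_from_sumstats_fit_and_summary(self):
        sim = simulate_traits_and_sumstats(_mr_scenario(0.25, seed=11))
        model = MRModel.from_sumstats(sim.sumstats["exposure"],
                                      sim.sumstats["outcome"], ld=sim.ld)
        res = model.fit()
        assert res.method == "ivw"
        assert res.n_instruments >= 2
        text = res.summary()
        assert "exposure" in text and "95% CI" in text
        loo = model.leave_one_out()
        assert len(loo) == res.n_instruments

    def test_auto_method_selects_wald_for_single_instrument(self):
        model = MRModel([make_pair()])
        assert model.fit().method == "wald_ratio"
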