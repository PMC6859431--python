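"""Bayesian colocalization: ABFs, configuration space, exact regional sums."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from mrmoloc.exceptions import AnalysisError, ParameterError
from mrmoloc.moloc import (
    Configuration,
    MolocModel,
    RegionData,
    _injective_inclusion_exclusion,
    configuration_likelihood,
    enumerate_configurations,
    eqtl_prefilter,
    log_abf_matrix,
    run_moloc,
    wakefield_abf,
)
from mrmoloc.synth import SimScenario, simulate_traits_and_sumstats


def _region(betas, ses, ns=None, trait_types=None, ids=None):
    labels = sorted(betas)
    m = len(next(iter(betas.values())))
    return RegionData(
        variant_ids=ids or [f"rs{i}" for i in range(m)],
        traits={
            lab: {
                "beta": np.asarray(betas[lab], dtype=float),
                "se": np.asarray(ses[lab], dtype=float),
                "n": (ns or {}).get(lab, 5000),
                "trait_type": (trait_types or {}).get(lab, "quantitative"),
                "trait_id": lab,
            }
            for lab in labels
        },
    )


def _random_region(rng, m=6, n_traits=3):
    labels = "abcd"[:n_traits]
    betas = {lab: rng.normal(0, 0.2, m) for lab in labels}
    ses = {lab: rng.uniform(0.02, 0.1, m) for lab in labels}
    return _region(betas, ses)


def brute_force_config_logbf(region, config, prior_sds=None):
    """Exhaustive oracle: loop over every placement of one causal variant per
    sharing group on distinct variants, log-sum the per-placement products."""
    if not config.groups:
        return 0.0
    abf = log_abf_matrix(region, prior_sds)
    m = region.n_variants
    k = len(config.groups)
    terms = []
    for placement in itertools.permutations(range(m), k):
        total = 0.0
        for group, v in zip(config.groups, placement):
            for trait in group:
                total += abf[trait][v]
        terms.append(total)
    return float(logsumexp(terms))


class TestWakefieldABF:
    def test_null_z_penalty_negative(self):
        lbf = wakefield_abf(0.0, 0.05, 0.15)
        r = 0.15**2 / (0.05**2 + 0.15**2)
        assert lbf == pytest.approx(0.5 * math.log1p(-r))
        assert lbf < 0

    def test_degenerate_prior_gives_unit_bf(self):
        assert wakefield_abf(0.1, 0.05, 0.0) == 0.0

    def test_closed_form_oracle(self):
        beta, se, sd = 0.1, 0.02, 0.15
        v, w = se**2, sd**2
        expected = 0.5 * math.log(1 - w / (v + w)) + 0.5 * (beta / se) ** 2 * (
            w / (v + w))
        assert wakefield_abf(beta, se, sd) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ParameterError):
            wakefield_abf(0.1, 0.0, 0.15)


class TestConfigurationSpace:
    @pytest.mark.parametrize("n,count", [(1, 2), (2, 5), (3, 15), (4, 52)])
    def test_counts_match_exhaustive_enumeration(self, n, count):
        configs = enumerate_configurations(n)
        assert len(configs) == count
        assert len(set(configs)) == count

    def test_two_trait_space_is_the_hand_enumeration(self):
        labels = {c.label for c in enumerate_configurations(2)}
        assert labels == {"null", "a", "b", "a.b", "ab"}

    def test_three_trait_space_contains_all_share(self):
        labels = [c.label for c in enumerate_configurations(3)]
        assert labels[0] == "null"
        assert "abc" in labels and "ab.c" in labels and "a.b.c" in labels

    def test_out_of_range_rejected(self):
        for n in (0, 5):
            with pytest.raises(ParameterError):
                enumerate_configurations(n)


class TestConfigurationLikelihood:
    def test_null_configuration_is_zero(self):
        region = _random_region(np.random.default_rng(0))
        assert configuration_likelihood(region, Configuration(())) == 0.0

    def test_single_variant_region_single_trait(self):
        region = _region({"a": [0.3], "b": [0.0], "c": [0.0]},
                         {"a": [0.05], "b": [0.05], "c": [0.05]})
        cfg = Configuration((frozenset("a"),))
        expected = log_abf_matrix(region)["a"][0]
        assert configuration_likelihood(region, cfg) == pytest.approx(expected)

    def test_two_groups_need_two_variants(self):
        region = _region({"a": [0.3], "b": [0.2], "c": [0.0]},
                         {"a": [0.05], "b": [0.05], "c": [0.05]})
        cfg = Configuration((frozenset("a"), frozenset("b")))
        with pytest.raises(AnalysisError):
            configuration_likelihood(region, cfg)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("m", [3, 8])
    def test_all_configurations_match_brute_force(self, seed, m):
        region = _random_region(np.random.default_rng(seed), m=m)
        for cfg in enumerate_configurations(3):
            expected = brute_force_config_logbf(region, cfg)
            got = configuration_likelihood(region, cfg)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_inclusion_exclusion_agrees_with_enumeration(self):
        # force the inclusion-exclusion path and compare against enumeration
        rng = np.random.default_rng(7)
        region = _random_region(rng, m=12)
        abf = log_abf_matrix(region)
        weights = [abf["a"], abf["b"], abf["c"]]
        from mrmoloc.moloc import _injective_enumeration

        assert _injective_inclusion_exclusion(weights) == pytest.approx(
            _injective_enumeration(weights), abs=1e-9)


class TestRunMoloc:
    def test_posteriors_sum_to_one(self):
        for seed in range(5):
            region = _random_region(np.random.default_rng(seed), m=10)
            res = run_moloc(region)
            assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
            assert res.ppa_all == res.posteriors["abc"]

    def test_strong_null_favors_null_configuration(self):
        m = 20
        region = _region({lab: np.zeros(m) for lab in "abc"},
                         {lab: np.full(m, 0.01) for lab in "abc"})
        res = run_moloc(region)
        assert res.posteriors["null"] > 0.99
        assert not res.decision

    def test_shared_variant_scenario_colocalizes(self):
        sim = simulate_traits_and_sumstats(_three_trait_scenario(True, seed=3))
        res = MolocModel.from_sumstats(
            {"a": sim.sumstats["expression"], "b": sim.sumstats["protein"],
             "c": sim.sumstats["disease"]}).fit()
        assert res.decision
        assert res.ppa_all >= 0.8

    def test_distinct_variant_scenario_does_not(self):
        sim = simulate_traits_and_sumstats(_three_trait_scenario(False, seed=3))
        res = MolocModel.from_sumstats(
            {"a": sim.sumstats["expression"], "b": sim.sumstats["protein"],
             "c": sim.sumstats["disease"]}).fit()
        assert not res.decision
        assert res.ppa_all < 0.2

    def test_cell_specific_sharing(self):
        # expression in one cell type shares the causal variant; a second cell
        # type's expression is null: only the first should colocalize
        scenario = _three_trait_scenario(True, seed=9)
        scenario.cohort_sizes["expression_null"] = 5000
        scenario.causal_map["expression_null"] = []
        scenario.trait_types["expression_null"] = "quantitative"
        scenario.noise_sd["expression_null"] = 1.0
        sim = simulate_traits_and_sumstats(scenario)
        sharing = MolocModel.from_sumstats(
            {"a": sim.sumstats["expression"], "b": sim.sumstats["protein"],
             "c": sim.sumstats["disease"]}).fit()
        null_cell = MolocModel.from_sumstats(
            {"a": sim.sumstats["expression_null"], "b": sim.sumstats["protein"],
             "c": sim.sumstats["disease"]}).fit()
        assert sharing.decision and not null_cell.decision

    def test_monotone_in_shared_signal_strength(self):
        rng = np.random.default_rng(4)
        m = 8
        betas = {lab: rng.normal(0, 0.05, m) for lab in "abc"}
        ses = {lab: np.full(m, 0.05) for lab in "abc"}
        last = -1.0
        for scale in (0.5, 1.0, 2.0, 4.0):
            b2 = {lab: b.copy() for lab, b in betas.items()}
            for lab in "abc":
                b2[lab][3] = 0.2 * scale
            res = run_moloc(_region(b2, ses))
            assert res.ppa_all >= last - 1e-12
            last = res.ppa_all

    def test_label_permutation_permutes_posteriors(self):
        region = _random_region(np.random.default_rng(12), m=6)
        res = run_moloc(region)
        swapped = RegionData(
            variant_ids=region.variant_ids,
            traits={"a": region.traits["b"], "b": region.traits["a"],
                    "c": region.traits["c"]},
        )
        res2 = run_moloc(swapped)
        assert res2.posteriors["abc"] == pytest.approx(res.posteriors["abc"],
                                                       rel=1e-9)
        assert res2.posteriors["a"] == pytest.approx(res.posteriors["b"],
                                                     rel=1e-9)
        assert res2.posteriors["ab.c"] == pytest.approx(res.posteriors["ab.c"],
                                                        rel=1e-9)

    def test_best_snp_is_argmax_abf(self):
        region = _random_region(np.random.default_rng(2), m=9)
        res = run_moloc(region)
        abf = log_abf_matrix(region)
        for lab in "abc":
            assert res.best_snp[lab] == region.variant_ids[int(np.argmax(abf[lab]))]


class TestEqtlPrefilter:
    @pytest.mark.parametrize("z,expected", [
        (4.9, True),      # p ~ 1e-6
        (3.0, False),     # p ~ 2.7e-3
    ])
    def test_threshold(self, z, expected):
        region = _region({"a": [z * 0.05, 0.0], "b": [0.0, 0.0], "c": [0.0, 0.0]},
                         {lab: [0.05, 0.05] for lab in "abc"})
        assert eqtl_prefilter(region, "a") is expected

    def test_boundary_is_strict(self):
        # a minimum p exactly at the threshold must NOT pass (strict <)
        region = _region({"a": [0.2, 0.0], "b": [0.0, 0.0], "c": [0.0, 0.0]},
                         {lab: [0.05, 0.05] for lab in "abc"})
        p_min = float(region.pvalues("a").min())
        assert eqtl_prefilter(region, "a", p_threshold=p_min) is False
        assert eqtl_prefilter(region, "a", p_threshold=p_min * 1.0001) is True


def _three_trait_scenario(shared: bool, seed: int, n_variants=40, n=5000):
    """Expression, protein and disease in independent cohorts; causal variants
    either all at index 20 (shared) or spread (5, 20, 35; distinct)."""
    idx = {"expression": 20, "protein": 20, "disease": 20} if shared else {
        "expression": 5, "protein": 20, "disease": 35}
    return SimScenario(
        n_variants=n_variants,
        maf=np.full(n_variants, 0.3),
        ld_rho=0.25,
        cohort_sizes={"expression": n, "protein": n, "disease": n},
        causal_map={
            "expression": [(idx["expression"], 0.5)],
            "protein": [(idx["protein"], 0.5)],
            "disease": [(idx["disease"], 0.4)],
        },
        trait_types={"expression": "quantitative", "protein": "quantitative",
                     "disease": "binary"},
        noise_sd={"expression": 1.0, "protein": 1.0},
        disease_prevalence=0.3,
        seed=seed,
    )
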