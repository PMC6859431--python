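"""Synthetic GWAS summary statistics with controlled causal architecture.

The generator emulates the statistical structure of the real data the framework
consumes — per-cohort marginal summary statistics over a shared LD region for
gene expression (per cell type), a circulating protein and a disease — without
any external download:

* haplotypes arise by thresholding a latent AR(1)-correlated standard normal
  vector at the quantile matching each variant's minor-allele frequency, and a
  genotype is the sum of two independent haplotypes, giving analytically
  controllable LD decay;
* every trait is measured in its own independent cohort, so exposure and
  outcome statistics satisfy the two-sample design by construction;
* quantitative traits are linear in genotype plus Gaussian noise; binary traits
  follow a logistic model whose intercept is calibrated to a target prevalence,
  optionally driven by the exposure trait's phenotype to create a true
  exposure->disease causal effect;
* summary statistics are marginal (single-variant) regressions — linear for
  quantitative traits, a one-step score estimator of the per-variant log odds
  for binary traits — matching what GWAS consortia release and what both MR and
  colocalization consume.

A truth record (causal indices, effect sizes, true causal slope) accompanies
every simulation so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import ParameterError, SimulationError
from .sumstats import LDMatrix, SumStats, pval_from_z

#: simulated variants live on one chromosome at evenly spaced positions
SIM_CHROM = "1"
SIM_POS_START = 1_000_000
SIM_POS_STEP = 2_000
#: counted (effect) allele and reference allele for all simulated variants
SIM_EFFECT_ALLELE = "A"
SIM_OTHER_ALLELE = "G"

_PVAL_FLOOR = 1e-300


@dataclass
class SimScenario:
    """Full generative specification of an LD region and its causal wiring.

    Each trait in ``cohort_sizes`` is simulated in its own independent cohort
    (two-sample design). ``causal_map`` wires traits directly to genotype;
    ``causal_beta_exposure_to_outcome`` additionally makes ``mr_outcome`` depend
    on the simulated phenotype of ``mr_exposure`` (the true MR slope).
    """

    n_variants: int
    maf: np.ndarray
    ld_rho: float
    cohort_sizes: dict[str, int]
    causal_map: dict[str, list[tuple[int, float]]]
    trait_types: dict[str, str]
    noise_sd: dict[str, float] = field(default_factory=dict)
    pos_step: int = SIM_POS_STEP
    disease_prevalence: float = 0.1
    causal_beta_exposure_to_outcome: float = 0.0
    mr_exposure: str | None = None
    mr_outcome: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (self.n_variants,):
            raise ParameterError("maf vector length must equal n_variants")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ParameterError("all maf must lie in (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ParameterError(f"ld_rho {self.ld_rho} outside [0, 1)")
        for trait, n in self.cohort_sizes.items():
            if n <= 0:
                raise ParameterError(f"cohort size for {trait} must be > 0")
        for trait, effects in self.causal_map.items():
            for idx, _ in effects:
                if not 0 <= idx < self.n_variants:
                    raise ParameterError(
                        f"causal index {idx} for {trait} outside [0, {self.n_variants})"
                    )
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ParameterError("disease_prevalence must lie in (0, 1)")
        if self.causal_beta_exposure_to_outcome != 0.0:
            if self.mr_exposure is None or self.mr_outcome is None:
                raise ParameterError(
                    "mr_exposure and mr_outcome must be set when "
                    "causal_beta_exposure_to_outcome is nonzero"
                )

    @property
    def variant_ids(self) -> list[str]:
        return [f"rs{i + 1}" for i in range(self.n_variants)]

    @property
    def positions(self) -> np.ndarray:
        return SIM_POS_START + self.pos_step * np.arange(self.n_variants)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimScenario":
        d = dict(d)
        d["maf"] = np.asarray(d["maf"], dtype=float)
        d["causal_map"] = {
            t: [(int(i), float(b)) for i, b in effects]
            for t, effects in d["causal_map"].items()
        }
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulation, sufficient to score recovery."""

    causal_map: dict[str, list[tuple[int, float]]]
    causal_variants: dict[str, list[str]]
    true_mr_slope: float
    mr_exposure: str | None
    mr_outcome: str | None


@dataclass
class SimOutput:
    """Per-trait summary statistics over an identical variant set, the LD
    matrix estimated from the exposure cohort's genotypes, and the truth."""

    sumstats: dict[str, SumStats]
    ld: LDMatrix
    truth: SimTruth

    def write(self, outdir) -> None:
        """Write each trait's table, the LD matrix and a truth file as text."""
        import json
        from pathlib import Path

        from .sumstats import write_sumstats

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for trait, ss in self.sumstats.items():
            write_sumstats(ss, outdir / f"{trait}.sumstats.tsv")
        self.ld.write(outdir / "ld.tsv")
        truth = {
            "causal_map": {t: [[i, b] for i, b in e] for t, e in self.truth.causal_map.items()},
            "causal_variants": self.truth.causal_variants,
            "true_mr_slope": self.truth.true_mr_slope,
            "mr_exposure": self.truth.mr_exposure,
            "mr_outcome": self.truth.mr_outcome,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def simulate_genotypes(n_individuals: int, maf: Sequence[float], ld_rho: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Simulate an (individuals x variants) genotype matrix with AR(1) LD.

    Each haplotype is a latent standard-normal AR(1) sequence with adjacent
    correlation ``ld_rho``, thresholded at Phi^{-1}(maf_j) so the minor allele
    appears with probability maf_j; a genotype is the sum of two independent
    haplotypes (values 0/1/2). Deterministic given the seed.
    """
    maf = np.asarray(maf, dtype=float)
    if not 0.0 <= ld_rho < 1.0:
        raise ParameterError(f"ld_rho {ld_rho} outside [0, 1)")
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ParameterError("all maf must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = maf.shape[0]
    thresh = stats.norm.ppf(maf)
    genotypes = np.zeros((n_individuals, m), dtype=np.int8)
    scale = np.sqrt(1.0 - ld_rho**2)
    for _ in range(2):  # two haplotypes per individual
        z = rng.standard_normal((n_individuals, m))
        latent = np.empty_like(z)
        latent[:, 0] = z[:, 0]
        for j in range(1, m):
            latent[:, j] = ld_rho * latent[:, j - 1] + scale * z[:, j]
        genotypes += latent < thresh
    return genotypes


def _marginal_linear(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple linear regression of y on genotype (vectorized).

    Returns (beta, se) with the usual n-2 residual-variance denominator.
    """
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    rss = syy - beta * sxy
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def _marginal_logistic_score(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-step score estimator of the per-variant log odds ratio.

    Under the intercept-only null fit (p-bar = case fraction), the score is
    U_j = sum_i g_ij (y_i - p-bar) and the information I_j =
    p-bar (1 - p-bar) sum_i (g_ij - g-bar_j)^2; the one-step estimate U/I with
    standard error I^{-1/2} is the standard fast GWAS approximation to
    per-variant logistic regression on the log-odds scale.
    """
    pbar = y.mean()
    gc = g - g.mean(axis=0)
    u = g.T @ (y - pbar)
    info = pbar * (1 - pbar) * np.einsum("ij,ij->j", gc, gc)
    beta = u / info
    se = 1.0 / np.sqrt(info)
    return beta, se


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept alpha such that mean(expit(alpha + eta)) == prevalence."""
    lo, hi = -30.0, 30.0
    f = lambda a: special.expit(a + eta).mean() - prevalence
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def simulate_traits_and_sumstats(scenario: SimScenario) -> SimOutput:
    """Simulate every trait of a scenario and return marginal summary statistics.

    Each trait gets its own genotype cohort (independent RNG substream).
    Quantitative traits are sums of causal effects times genotype plus
    Normal(0, noise_sd) noise. Binary traits follow a logistic model with the
    intercept calibrated to ``disease_prevalence``; when the scenario couples
    ``mr_outcome`` to ``mr_exposure``, the outcome's linear predictor gains the
    exposure phenotype (simulated in the outcome's own cohort) scaled by the
    true causal slope.

    Raises :class:`SimulationError` if a binary trait draws zero cases or zero
    controls at the chosen prevalence and cohort size.
    """
    rng = np.random.default_rng(scenario.seed)
    trait_order = list(scenario.cohort_sizes)
    streams = {t: s for t, s in zip(trait_order, rng.spawn(len(trait_order)))}

    sumstats: dict[str, SumStats] = {}
    ld: LDMatrix | None = None
    ld_trait = scenario.mr_exposure or trait_order[0]

    for trait in trait_order:
        sub = streams[trait]
        n = scenario.cohort_sizes[trait]
        g = simulate_genotypes(n, scenario.maf, scenario.ld_rho, sub)
        eta = _genetic_value(g, scenario.causal_map.get(trait, []))

        coupled = (
            trait == scenario.mr_outcome
            and scenario.causal_beta_exposure_to_outcome != 0.0
        )
        if coupled:
            # exposure phenotype realized in *this* cohort drives the outcome
            exp_eta = _genetic_value(g, scenario.causal_map.get(scenario.mr_exposure, []))
            exp_noise = scenario.noise_sd.get(scenario.mr_exposure, 1.0)
            exp_pheno = exp_eta + exp_noise * sub.standard_normal(n)
            eta = eta + scenario.causal_beta_exposure_to_outcome * exp_pheno

        if scenario.trait_types[trait] == "quantitative":
            y = eta + scenario.noise_sd.get(trait, 1.0) * sub.standard_normal(n)
            beta, se = _marginal_linear(g, y)
        else:
            alpha = _calibrate_intercept(eta, scenario.disease_prevalence)
            y = (sub.random(n) < special.expit(alpha + eta)).astype(float)
            if y.sum() == 0 or y.sum() == n:
                raise SimulationError(
                    f"binary trait {trait}: no {'cases' if y.sum() == 0 else 'controls'} "
                    f"drawn at prevalence {scenario.disease_prevalence} with n={n}; "
                    "use a larger cohort"
                )
            beta, se = _marginal_logistic_score(g, y)

        eaf = np.clip(g.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
        pval = np.maximum(pval_from_z(beta / se), _PVAL_FLOOR)
        df = pd.DataFrame(
            {
                "variant_id": scenario.variant_ids,
                "chr": SIM_CHROM,
                "pos": scenario.positions,
                "effect_allele": SIM_EFFECT_ALLELE,
                "other_allele": SIM_OTHER_ALLELE,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n,
            }
        )
        sumstats[trait] = SumStats(
            df, trait_id=trait, trait_type=scenario.trait_types[trait], validate=False
        )
        if trait == ld_trait:
            ld = _estimate_ld(g, scenario.variant_ids)

    if ld is None:  # exposure trait not simulated; use the first cohort
        ld = _estimate_ld(
            simulate_genotypes(
                scenario.cohort_sizes[trait_order[0]], scenario.maf, scenario.ld_rho,
                np.random.default_rng(scenario.seed),
            ),
            scenario.variant_ids,
        )

    truth = SimTruth(
        causal_map=dict(scenario.causal_map),
        causal_variants={
            t: [scenario.variant_ids[i] for i, _ in effects]
            for t, effects in scenario.causal_map.items()
        },
        true_mr_slope=scenario.causal_beta_exposure_to_outcome,
        mr_exposure=scenario.mr_exposure,
        mr_outcome=scenario.mr_outcome,
    )
    return SimOutput(sumstats=sumstats, ld=ld, truth=truth)


def _genetic_value(g: np.ndarray, effects: list[tuple[int, float]]) -> np.ndarray:
    eta = np.zeros(g.shape[0])
    for idx, beta in effects:
        eta = eta + beta * g[:, idx]
    return eta


def _estimate_ld(g: np.ndarray, variant_ids: list[str]) -> LDMatrix:
    r = np.corrcoef(g, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variant_ids=list(variant_ids), r=r)


# ---------------------------------------------------------------------------
# canonical validation scenarios
# ---------------------------------------------------------------------------

def mr_two_sample_scenario(true_slope: float, seed: int, n_per_cohort: int = 5000,
                           n_instruments: int = 5, gamma: float = 0.5,
                           maf: float = 0.3) -> SimScenario:
    """Two-sample MR scenario with independent instruments of equal strength.

    The exposure is quantitative with ``n_instruments`` unlinked causal
    variants (per-allele effect ``gamma`` SD); the outcome is quantitative and
    driven solely by the exposure phenotype with slope ``true_slope``. The
    outcome's residual SD is 3, so even at the largest slopes studied the
    exposure explains only a few percent of outcome variance — the regime real
    molecular-exposure/disease pairs occupy, and the regime in which the
    fixed-effect IVW standard error (outcome-side uncertainty only) is
    calibrated.
    """
    return SimScenario(
        n_variants=n_instruments,
        maf=np.full(n_instruments, maf),
        ld_rho=0.0,
        cohort_sizes={"exposure": n_per_cohort, "outcome": n_per_cohort},
        causal_map={"exposure": [(j, gamma) for j in range(n_instruments)],
                    "outcome": []},
        trait_types={"exposure": "quantitative", "outcome": "quantitative"},
        noise_sd={"exposure": 1.0, "outcome": 3.0},
        causal_beta_exposure_to_outcome=true_slope,
        mr_exposure="exposure",
        mr_outcome="outcome",
        seed=seed,
    )


def three_trait_region_scenario(shared: bool, seed: int, n_variants: int = 40,
                                n_per_trait: int = 5000) -> SimScenario:
    """Expression / protein / disease over one LD region, each trait in its
    own cohort; the causal variants are either identical across traits
    (``shared=True``, index 20) or spread apart (indices 5, 20, 35)."""
    idx = {"expression": 20, "protein": 20, "disease": 20} if shared else {
        "expression": 5, "protein": 20, "disease": 35}
    return SimScenario(
        n_variants=n_variants,
        maf=np.full(n_variants, 0.3),
        ld_rho=0.25,
        cohort_sizes={"expression": n_per_trait, "protein": n_per_trait,
                      "disease": n_per_trait},
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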