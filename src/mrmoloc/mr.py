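"""Two-sample Mendelian randomization estimators and sensitivity analyses.

Estimation follows the classical summary-data formulas. For a single variant j
with gene–exposure estimate γ̂_j and gene–outcome estimate Γ̂_j, the Wald ratio

    β̂_j = Γ̂_j / γ̂_j

has first-order delta-method standard error σ_Yj / |γ̂_j|, where σ_Yj is the
outcome-side standard error. With several independent instruments the
inverse-variance-weighted (IVW) estimate is the weighted mean of the per-
instrument Wald ratios with weights w_j = γ̂_j² σ_Yj⁻²,

    β̂_IVW = Σ_j w_j β̂_j / Σ_j w_j ,   se = (Σ_j w_j)^(-1/2)  (fixed effect),

which equals the slope of a weighted least-squares regression of Γ̂ on γ̂
through the origin with weights σ_Yj⁻². Exposure-side uncertainty is not
propagated, matching the standard fixed-effect formulation.

Sensitivity analyses: leave-one-out refits of IVW, reverse MR (instrumenting
the disease and testing its effect on the molecular trait), and the Steiger
directionality test comparing variance explained in exposure vs outcome via a
Fisher-z test on the difference of two independent correlations.

:class:`MRModel` wraps these as a model object built from harmonized pairs
whose ``fit()`` returns an :class:`MRResults` carrying estimate, standard
error, p-value and a ``summary()`` table; the module-level functions are the
underlying primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import AnalysisError, ParameterError
from .sumstats import (
    HarmonizedPair,
    LDMatrix,
    SumStats,
    VariantAssociation,
    chi2_logsf_log10,
    harmonize,
    ld_clump,
)

__all__ = [
    "MRModel",
    "MRResults",
    "SteigerResult",
    "bonferroni_threshold",
    "ivw",
    "leave_one_out",
    "reverse_mr",
    "steiger_test",
    "steiger_from_r2",
    "wald_ratio",
]


def _pval_and_log10(z: float) -> tuple[float, float]:
    """Two-sided normal p and its -log10, computed in log space so the log10
    value stays finite below double-precision underflow."""
    log10p = chi2_logsf_log10(z)
    return float(10.0**log10p) if log10p > -300 else 0.0, float(-log10p)


@dataclass
class MRResults:
    """Causal-effect estimate from a two-sample MR fit.

    ``estimate`` is on the outcome scale per unit exposure (log odds ratio per
    exposure unit for binary outcomes). ``neg_log10_pval`` remains finite when
    ``pval`` underflows. ``flag`` is empty for a regular fit; reverse-MR sets
    it to "underpowered" when the outcome GWAS yields no instruments.
    """

    exposure_id: str
    outcome_id: str
    method: str  # wald_ratio | ivw
    estimate: float
    se: float
    pval: float
    n_instruments: int
    instrument_ids: list[str] = field(default_factory=list)
    neg_log10_pval: float = math.nan
    flag: str = ""

    def __post_init__(self) -> None:
        if self.method == "wald_ratio" and self.n_instruments != 1:
            raise AnalysisError("wald_ratio results must have exactly one instrument")
        if math.isnan(self.neg_log10_pval) and self.se > 0:
            self.neg_log10_pval = -chi2_logsf_log10(self.estimate / self.se)

    @property
    def zvalue(self) -> float:
        return self.estimate / self.se

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-theory (1 - alpha) confidence interval."""
        q = stats.norm.ppf(1 - alpha / 2)
        return self.estimate - q * self.se, self.estimate + q * self.se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Two-sample MR results",
            "=" * 58,
            f"exposure:      {self.exposure_id}",
            f"outcome:       {self.outcome_id}",
            f"method:        {self.method}",
            f"instruments:   {self.n_instruments}",
            f"estimate:      {self.estimate:+.4f}",
            f"std error:     {self.se:.4f}",
            f"95% CI:        [{lo:+.4f}, {hi:+.4f}]",
            f"p-value:       {self.pval:.3e}",
        ]
        if self.flag:
            lines.append(f"flag:          {self.flag}")
        return "\n".join(lines)


def wald_ratio(pair: HarmonizedPair, exposure_id: str = "exposure",
               outcome_id: str = "outcome", second_order: bool = False) -> MRResults:
    """Single-instrument Wald ratio estimate Γ̂/γ̂.

    The default standard error is the first-order delta method σ_Y/|γ̂|, which
    ignores γ̂'s sampling error; ``second_order=True`` adds the Γ̂²σ_γ²/γ̂⁴
    correction term.
    """
    if not pair.usable:
        raise AnalysisError(f"{pair.variant_id}: cannot estimate from a {pair.status} pair")
    if pair.beta_exposure == 0:
        raise AnalysisError(f"{pair.variant_id}: undefined ratio (exposure beta is 0)")
    est = pair.beta_outcome / pair.beta_exposure
    var = (pair.se_outcome / pair.beta_exposure) ** 2
    if second_order:
        var += (pair.beta_outcome**2 * pair.se_exposure**2) / pair.beta_exposure**4
    se = math.sqrt(var)
    pval, nlp = _pval_and_log10(est / se)
    return MRResults(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method="wald_ratio",
        estimate=est,
        se=se,
        pval=pval,
        n_instruments=1,
        instrument_ids=[pair.variant_id],
        neg_log10_pval=nlp,
    )


def ivw(pairs: Sequence[HarmonizedPair], min_instruments: int = 2,
        exposure_id: str = "exposure", outcome_id: str = "outcome") -> MRResults:
    """Fixed-effect inverse-variance-weighted estimate over independent instruments.

    Weighted mean of per-instrument Wald ratios with weights γ̂_j² σ_Yj⁻²;
    equivalently the weighted least-squares slope of Γ̂ on γ̂ through the
    origin with weights σ_Yj⁻².
    """
    usable = [p for p in pairs if p.usable]
    if len(usable) < min_instruments:
        raise AnalysisError(
            f"IVW needs >= {min_instruments} usable instruments, got {len(usable)}"
        )
    if any(p.beta_exposure == 0 for p in usable):
        bad = next(p.variant_id for p in usable if p.beta_exposure == 0)
        raise AnalysisError(f"{bad}: undefined Wald ratio (exposure beta is 0)")
    gamma = np.array([p.beta_exposure for p in usable])
    Gamma = np.array([p.beta_outcome for p in usable])
    sy = np.array([p.se_outcome for p in usable])
    w = gamma**2 / sy**2
    est = float(np.sum(w * (Gamma / gamma)) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    pval, nlp = _pval_and_log10(est / se)
    return MRResults(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method="ivw",
        estimate=est,
        se=se,
        pval=pval,
        n_instruments=len(usable),
        instrument_ids=[p.variant_id for p in usable],
        neg_log10_pval=nlp,
    )


def leave_one_out(pairs: Sequence[HarmonizedPair], exposure_id: str = "exposure",
                  outcome_id: str = "outcome") -> list[tuple[str, MRResults]]:
    """IVW refits excluding one instrument at a time.

    Flags undue influence of any single SNP on a multi-instrument estimate.
    Requires >= 3 usable pairs so each reduced set still supports IVW; returns
    one (left_out_id, results) per instrument, in input order.
    """
    usable = [p for p in pairs if p.usable]
    if len(usable) < 3:
        raise AnalysisError(f"leave-one-out needs >= 3 usable instruments, got {len(usable)}")
    out = []
    for i, p in enumerate(usable):
        reduced = usable[:i] + usable[i + 1:]
        out.append((p.variant_id, ivw(reduced, exposure_id=exposure_id,
                                      outcome_id=outcome_id)))
    return out


def reverse_mr(outcome_sumstats: SumStats | Sequence[VariantAssociation],
               exposure_sumstats: SumStats | Sequence[VariantAssociation],
               ld: LDMatrix, p_threshold: float = 5e-8,
               r2_threshold: float = 0.001,
               exposure_id: str = "outcome_as_exposure",
               outcome_id: str = "exposure_as_outcome") -> MRResults:
    """MR with the roles reversed: instrument the disease, test its effect on
    the molecular trait.

    Instruments are selected from the disease GWAS by LD clumping at the usual
    thresholds, harmonized toward the molecular trait as outcome, and estimated
    by Wald ratio (one instrument) or IVW (two or more). If the disease GWAS
    has no genome-wide-significant instruments after clumping the result is
    returned with ``flag="underpowered"`` rather than raising.
    """
    instruments = ld_clump(outcome_sumstats, ld, p_threshold=p_threshold,
                           r2_threshold=r2_threshold)
    n_inst = len(instruments) if isinstance(instruments, SumStats) else len(instruments)
    if n_inst == 0:
        return MRResults(
            exposure_id=exposure_id,
            outcome_id=outcome_id,
            method="ivw",
            estimate=math.nan,
            se=math.nan,
            pval=math.nan,
            n_instruments=0,
            neg_log10_pval=math.nan,
            flag="underpowered",
        )
    pairs = harmonize(instruments, exposure_sumstats)
    usable = [p for p in pairs if p.usable]
    if not usable:
        return MRResults(
            exposure_id=exposure_id, outcome_id=outcome_id, method="ivw",
            estimate=math.nan, se=math.nan, pval=math.nan, n_instruments=0,
            neg_log10_pval=math.nan, flag="underpowered",
        )
    if len(usable) == 1:
        return wald_ratio(usable[0], exposure_id=exposure_id, outcome_id=outcome_id)
    return ivw(usable, exposure_id=exposure_id, outcome_id=outcome_id)


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: does the instrument explain more variance in the
    exposure than in the outcome?"""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    z: float
    pval: float


def steiger_from_r2(r2_exposure: float, r2_outcome: float,
                    n_exposure: int, n_outcome: int) -> SteigerResult:
    """Steiger test from variance-explained values in two independent samples.

    Fisher-transforms r = sqrt(r²) on each side and compares the difference to
    its standard error sqrt(1/(n1-3) + 1/(n2-3)); two-sided normal p.
    """
    if n_exposure <= 3 or n_outcome <= 3:
        raise AnalysisError("Steiger test needs sample sizes > 3 on both sides")
    r_exp = math.sqrt(max(r2_exposure, 0.0))
    r_out = math.sqrt(max(r2_outcome, 0.0))
    z_diff = math.atanh(min(r_exp, 1 - 1e-15)) - math.atanh(min(r_out, 1 - 1e-15))
    se = math.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = z_diff / se
    pval = float(stats.chi2.sf(z * z, df=1))
    return SteigerResult(
        r2_exposure=r2_exposure,
        r2_outcome=r2_outcome,
        correct_direction=r2_exposure > r2_outcome,
        z=z,
        pval=pval,
    )


def steiger_test(pair: HarmonizedPair,
                 trait_types: tuple[str, str] = ("quantitative", "quantitative"),
                 r2_method: str = "t") -> SteigerResult:
    """Steiger directionality test for one instrument.

    Per-variant variance explained is computed from summary statistics. The
    default ``r2_method="t"`` uses the unit-free t-statistic form
    r² = t²/(t² + n - 2) on whatever scale the betas are reported (log odds for
    binary traits); ``r2_method="af"`` uses r² = 2·eaf·(1-eaf)·beta², valid for
    quantitative traits whose betas are in phenotype-SD units.
    """
    if not pair.usable:
        raise AnalysisError(f"{pair.variant_id}: cannot test a {pair.status} pair")
    if pair.n_exposure <= 3 or pair.n_outcome <= 3:
        raise AnalysisError(f"{pair.variant_id}: missing or insufficient sample sizes")
    if r2_method not in ("t", "af"):
        raise ParameterError(f"unknown r2_method {r2_method!r}")

    def _r2(beta, se, eaf, n, trait_type):
        if r2_method == "af" and trait_type == "quantitative":
            return 2.0 * eaf * (1.0 - eaf) * beta**2
        t2 = (beta / se) ** 2
        return t2 / (t2 + n - 2)

    r2_exp = _r2(pair.beta_exposure, pair.se_exposure, pair.eaf_exposure,
                 pair.n_exposure, trait_types[0])
    r2_out = _r2(pair.beta_outcome, pair.se_outcome, pair.eaf_outcome,
                 pair.n_outcome, trait_types[1])
    return steiger_from_r2(r2_exp, r2_out, pair.n_exposure, pair.n_outcome)


def bonferroni_threshold(n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """Multiple-testing threshold alpha / (exposures x outcomes)."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ParameterError("exposure and outcome counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)


class MRModel:
    """Two-sample MR model over a set of harmonized instrument pairs.

    Parameters
    ----------
    pairs :
        Harmonized exposure/outcome pairs; dropped pairs are ignored at fit
        time but retained for bookkeeping.
    exposure_id, outcome_id :
        Trait labels carried into the results.

    Examples
    --------
    >>> model = MRModel.from_sumstats(expo, outc, ld=ld)   # doctest: +SKIP
    >>> res = model.fit()                                   # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(self, pairs: Sequence[HarmonizedPair], exposure_id: str = "exposure",
                 outcome_id: str = "outcome"):
        self.pairs = list(pairs)
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id

    @classmethod
    def from_sumstats(cls, exposure: SumStats, outcome: SumStats,
                      ld: LDMatrix | None = None, p_threshold: float = 5e-8,
                      r2_threshold: float = 0.001,
                      palindrome_eaf_window: float = 0.08) -> "MRModel":
        """Build a model by clumping the exposure GWAS (if ``ld`` is given) and
        harmonizing against the outcome GWAS."""
        instruments = exposure
        if ld is not None:
            instruments = ld_clump(exposure, ld, p_threshold=p_threshold,
                                   r2_threshold=r2_threshold)
        if len(instruments) == 0:
            raise AnalysisError("no instruments survive selection")
        pairs = harmonize(instruments, outcome, palindrome_eaf_window=palindrome_eaf_window)
        return cls(pairs, exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)

    @property
    def usable_pairs(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if p.usable]

    def fit(self, method: str = "auto", min_instruments: int = 2) -> MRResults:
        """Estimate the causal effect.

        ``method`` is "wald_ratio", "ivw", or "auto" (Wald ratio with one
        usable instrument, IVW otherwise).
        """
        usable = self.usable_pairs
        if method == "auto":
            method = "wald_ratio" if len(usable) == 1 else "ivw"
        if method == "wald_ratio":
            if len(usable) != 1:
                raise AnalysisError(
                    f"wald_ratio requires exactly one usable instrument, got {len(usable)}"
                )
            return wald_ratio(usable[0], exposure_id=self.exposure_id,
                              outcome_id=self.outcome_id)
        if method == "ivw":
            return ivw(usable, min_instruments=min_instruments,
                       exposure_id=self.exposure_id, outcome_id=self.outcome_id)
        raise ParameterError(f"unknown method {method!r}")

    def leave_one_out(self) -> list[tuple[str, MRResults]]:
        return leave_one_out(self.usable_pairs, exposure_id=self.exposure_id,
                             outcome_id=self.outcome_id)

    def steiger(self, trait_types: tuple[str, str] = ("quantitative", "quantitative"),
                r2_method: str = "t") -> list[SteigerResult]:
        return [steiger_test(p, trait_types, r2_method) for p in self.usable_pairs]
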