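"""Multiple-trait Bayesian colocalization over summary statistics.

Given aligned per-variant effect estimates for up to four traits in one LD
region — here typically (a) gene expression in a cell type, (b) a circulating
protein and (c) a disease — the method asks which traits, if any, share a
single causal variant. Evidence per variant and trait is the Wakefield
approximate Bayes factor; with V = se², W = prior_sd², r = W/(V+W) and
z = beta/se,

    log ABF = ½ log(1 − r) + ½ z² r .

A *configuration* assigns a subset of traits as associated and partitions that
subset into sharing groups (e.g. ``ab.c``: expression and protein share one
causal variant, disease has its own). For three traits there are exactly 15
configurations including the null. The regional Bayes factor of a
configuration sums, over all placements of one causal variant per group on
*distinct* variants, the product of the member traits' ABFs at their group's
variant — computed exactly (masked enumeration for small placement spaces,
signed inclusion–exclusion otherwise), entirely in log space.

Posteriors combine these Bayes factors with per-variant prior probabilities
p1, p2, p3 (a variant is causal for exactly one, two, three traits; defaults
1e-4, 1e-6, 1e-7). ``PPA_abc`` — the posterior of the single-group
configuration in which all traits share one variant — is the colocalization
score; PPA_abc >= 0.8 declares colocalization. The single-causal-variant-per-
group assumption is retained throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import AnalysisError, ParameterError
from .sumstats import SumStats, pval_from_z

__all__ = [
    "Configuration",
    "MolocModel",
    "MolocResults",
    "RegionData",
    "configuration_likelihood",
    "enumerate_configurations",
    "eqtl_prefilter",
    "run_moloc",
    "wakefield_abf",
]

TRAIT_LABELS = "abcd"

#: per-variant prior that a variant is causal for exactly 1, 2, 3 traits
DEFAULT_PRIORS = (1e-4, 1e-6, 1e-7)
#: effect-size prior SD by trait type
DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}

# exact masked enumeration is used while the placement tensor stays below this
_MAX_ENUM_CELLS = 2_000_000


def wakefield_abf(beta, se, prior_sd: float):
    """Log Wakefield approximate Bayes factor (association vs null) for one
    estimate; vectorized over ``beta``/``se``.

    prior_sd = 0 degenerates to a point-null prior and returns log ABF = 0.
    """
    se = np.asarray(se, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(se <= 0):
        raise ParameterError("se must be > 0")
    if prior_sd < 0:
        raise ParameterError("prior_sd must be >= 0")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True, order=True)
class Configuration:
    """One colocalization hypothesis: associated traits partitioned into
    groups that each share a single causal variant."""

    groups: tuple[frozenset, ...]

    def __init__(self, groups: Sequence[frozenset]):
        canon = tuple(sorted((frozenset(g) for g in groups), key=lambda g: min(g)))
        object.__setattr__(self, "groups", canon)

    @property
    def associated(self) -> frozenset:
        return frozenset().union(*self.groups) if self.groups else frozenset()

    @property
    def label(self) -> str:
        if not self.groups:
            return "null"
        return ".".join("".join(sorted(g)) for g in self.groups)

    def __repr__(self) -> str:
        return f"Configuration({self.label})"


def _set_partitions(items: list):
    """All partitions of ``items`` into non-empty blocks (deterministic order)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def enumerate_configurations(n_traits: int) -> list[Configuration]:
    """All colocalization configurations for ``n_traits`` traits (1-4).

    Every subset of traits may be associated, and each associated subset is
    partitioned into sharing groups; the null (no trait associated) is
    included. Yields 2, 5, 15, 52 configurations for 1-4 traits. Ordering is
    canonical: by number of associated traits, then number of groups, then
    label.
    """
    if not 1 <= n_traits <= 4:
        raise ParameterError(f"n_traits must be in [1, 4], got {n_traits}")
    labels = list(TRAIT_LABELS[:n_traits])
    configs = []
    for k in range(len(labels) + 1):
        for subset in itertools.combinations(labels, k):
            for part in _set_partitions(list(subset)):
                configs.append(Configuration(tuple(frozenset(b) for b in part)))
    configs = sorted(set(configs), key=lambda c: (len(c.associated), len(c.groups), c.label))
    return configs


@dataclass
class RegionData:
    """Aligned per-variant summary statistics for 2-4 traits in one region.

    ``traits`` maps the short label ("a", "b", "c", ...) to a dict with keys
    ``beta``, ``se`` (arrays over the shared variant list), ``n``,
    ``trait_type`` and ``trait_id``.
    """

    variant_ids: list[str]
    traits: dict[str, dict]

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        if m == 0:
            raise AnalysisError("region has no variants")
        for label, t in self.traits.items():
            t["beta"] = np.asarray(t["beta"], dtype=float)
            t["se"] = np.asarray(t["se"], dtype=float)
            if t["beta"].shape != (m,) or t["se"].shape != (m,):
                raise AnalysisError(f"trait {label}: beta/se length != {m} variants")
            if not np.all(np.isfinite(t["beta"])) or not np.all(np.isfinite(t["se"])):
                raise AnalysisError(f"trait {label}: non-finite beta/se in region")
            if np.any(t["se"] <= 0):
                raise AnalysisError(f"trait {label}: non-positive se in region")

    @property
    def labels(self) -> list[str]:
        return list(self.traits)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def pvalues(self, label: str) -> np.ndarray:
        t = self.traits[label]
        return pval_from_z(t["beta"] / t["se"])

    @classmethod
    def from_sumstats(cls, trait_sumstats: Mapping[str, SumStats],
                      variant_ids: Sequence[str] | None = None) -> "RegionData":
        """Assemble a region from per-trait SumStats restricted to their shared
        variants (order of the first trait), optionally pre-restricted to
        ``variant_ids``."""
        labels = list(trait_sumstats)
        if not 2 <= len(labels) <= 4:
            raise ParameterError("need 2-4 traits for colocalization")
        maps = {lab: trait_sumstats[lab].by_variant() for lab in labels}
        first = trait_sumstats[labels[0]]
        shared = [v for v in first.df["variant_id"] if all(v in maps[l] for l in labels[1:])]
        if variant_ids is not None:
            wanted = set(variant_ids)
            shared = [v for v in shared if v in wanted]
        if not shared:
            raise AnalysisError("no shared variants across region traits")
        traits = {}
        for lab in labels:
            recs = [maps[lab][v] for v in shared]
            traits[lab] = {
                "beta": np.array([r.beta for r in recs]),
                "se": np.array([r.se for r in recs]),
                "n": int(np.median([r.n for r in recs])),
                "trait_type": trait_sumstats[lab].trait_type,
                "trait_id": trait_sumstats[lab].trait_id,
            }
        return cls(variant_ids=list(shared), traits=traits)


def _resolve_prior_sds(region: RegionData,
                       prior_sds: Mapping[str, float] | None) -> dict[str, float]:
    if prior_sds is None:
        return {lab: DEFAULT_PRIOR_SD[t["trait_type"]] for lab, t in region.traits.items()}
    return dict(prior_sds)


def log_abf_matrix(region: RegionData,
                   prior_sds: Mapping[str, float] | None = None) -> dict[str, np.ndarray]:
    """Per-trait vectors of per-variant log Wakefield ABFs."""
    sds = _resolve_prior_sds(region, prior_sds)
    return {
        lab: wakefield_abf(t["beta"], t["se"], sds[lab])
        for lab, t in region.traits.items()
    }


def _injective_log_sum(weights: list[np.ndarray]) -> float:
    """log of the sum over placements of k groups on k *distinct* variants of
    the product of group weights; ``weights[g]`` holds log w_g per variant."""
    k = len(weights)
    m = weights[0].shape[0]
    if k == 1:
        return float(logsumexp(weights[0]))
    if m < k:
        raise AnalysisError(
            f"region has {m} variants but configuration needs {k} distinct causal variants"
        )
    if m**k <= _MAX_ENUM_CELLS and k <= 3:
        return _injective_enumeration(weights)
    return _injective_inclusion_exclusion(weights)


def _injective_enumeration(weights: list[np.ndarray]) -> float:
    k = len(weights)
    m = weights[0].shape[0]
    if k == 2:
        grid = weights[0][:, None] + weights[1][None, :]
        np.fill_diagonal(grid, -np.inf)
        return float(logsumexp(grid))
    grid = (weights[0][:, None, None] + weights[1][None, :, None]
            + weights[2][None, None, :])
    i, j, l = np.ogrid[:m, :m, :m]
    grid = np.where((i == j) | (i == l) | (j == l), -np.inf, grid)
    return float(logsumexp(grid))


def _injective_inclusion_exclusion(weights: list[np.ndarray]) -> float:
    """Exact sum over injective placements via Moebius inversion over
    partitions of the group set: collapsing a block of groups onto one shared
    variant contributes prod-of-blocks with sign (-1)^(|B|-1) (|B|-1)!."""
    k = len(weights)
    log_terms, signs = [], []
    for part in _set_partitions(list(range(k))):
        log_t = 0.0
        coef = 1.0
        for block in part:
            log_t += float(logsumexp(np.sum([weights[g] for g in block], axis=0)))
            coef *= ((-1.0) ** (len(block) - 1)) * math.factorial(len(block) - 1)
        log_terms.append(log_t)
        signs.append(coef)
    total, sign = logsumexp(np.array(log_terms), b=np.array(signs), return_sign=True)
    if sign <= 0:
        raise AnalysisError("numerical cancellation in injective placement sum")
    return float(total)


def configuration_likelihood(region: RegionData, config: Configuration,
                             prior_sds: Mapping[str, float] | None = None,
                             _abf: Mapping[str, np.ndarray] | None = None) -> float:
    """Log regional Bayes factor of one configuration against the null.

    Each sharing group places one causal variant; distinct groups occupy
    distinct variants, summed exactly. Unassociated traits contribute a factor
    of one; the null configuration has log BF 0 by definition.
    """
    if not config.groups:
        return 0.0
    abf = dict(_abf) if _abf is not None else log_abf_matrix(region, prior_sds)
    unknown = config.associated - set(region.labels)
    if unknown:
        raise ParameterError(f"configuration references unknown traits: {sorted(unknown)}")
    if len(config.groups) >= 2 and region.n_variants < 2:
        raise AnalysisError(
            "region has fewer than 2 variants but configuration has >= 2 sharing groups"
        )
    weights = [np.sum([abf[t] for t in sorted(g)], axis=0) for g in config.groups]
    return _injective_log_sum(weights)


@dataclass
class MolocResults:
    """Posterior over colocalization configurations for one region.

    ``ppa_all`` is the posterior that *all* traits share one causal variant
    (PPA_abc for three traits); ``decision`` is ``ppa_all >= ppa_threshold``.
    ``best_snp`` maps each trait to the variant with the largest per-variant
    ABF for that trait (the strongest single-variant signal).
    """

    posteriors: dict[str, float]
    ppa_all: float
    best_snp: dict[str, str]
    priors: tuple
    prior_sds: dict[str, float]
    ppa_threshold: float
    decision: bool
    n_variants: int
    trait_ids: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Multiple-trait colocalization results",
            "=" * 58,
            f"variants in region:  {self.n_variants}",
            "traits:              "
            + ", ".join(f"{lab}={tid}" for lab, tid in self.trait_ids.items()),
            f"priors (p1,p2,p3):   {self.priors}",
            "",
            f"{'configuration':<16}{'posterior':>12}",
            "-" * 28,
        ]
        for label, post in sorted(self.posteriors.items(), key=lambda kv: -kv[1]):
            if post >= 5e-5:
                lines.append(f"{label:<16}{post:>12.4f}")
        lines += [
            "-" * 28,
            f"PPA(all share one variant) = {self.ppa_all:.4f}"
            f"  ->  {'colocalized' if self.decision else 'not colocalized'}"
            f" (threshold {self.ppa_threshold})",
        ]
        return "\n".join(lines)


def run_moloc(region: RegionData, priors: Sequence[float] = DEFAULT_PRIORS,
              prior_sds: Mapping[str, float] | None = None,
              ppa_threshold: float = 0.8) -> MolocResults:
    """Score every colocalization configuration of a region and extract the
    posterior that all traits share a single causal variant.

    posterior(config) ∝ prior(config) × BF(config), with
    prior(config) = Π over sharing groups of p_{group size}; normalized over
    the full configuration set.
    """
    if region.n_variants < 2:
        raise AnalysisError("colocalization needs >= 2 variants in the region")
    if any(p <= 0 for p in priors):
        raise ParameterError("priors must be positive")
    n_traits = len(region.traits)
    if n_traits > len(priors):
        raise ParameterError(f"need per-variant priors up to group size {n_traits}")
    sds = _resolve_prior_sds(region, prior_sds)
    abf = log_abf_matrix(region, sds)
    configs = enumerate_configurations(n_traits)
    log_post = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        log_prior = sum(math.log(priors[len(g) - 1]) for g in cfg.groups)
        log_bf = configuration_likelihood(region, cfg, sds, _abf=abf)
        if not np.isfinite(log_bf):
            raise AnalysisError(f"non-finite Bayes factor for configuration {cfg.label}")
        log_post[i] = log_prior + log_bf
    log_post -= logsumexp(log_post)
    posteriors = {cfg.label: float(np.exp(lp)) for cfg, lp in zip(configs, log_post)}
    all_label = "".join(sorted(region.labels))
    ppa_all = posteriors[all_label]
    best_snp = {lab: region.variant_ids[int(np.argmax(abf[lab]))] for lab in region.labels}
    return MolocResults(
        posteriors=posteriors,
        ppa_all=ppa_all,
        best_snp=best_snp,
        priors=tuple(priors),
        prior_sds=sds,
        ppa_threshold=ppa_threshold,
        decision=ppa_all >= ppa_threshold,
        n_variants=region.n_variants,
        trait_ids={lab: t["trait_id"] for lab, t in region.traits.items()},
    )


def eqtl_prefilter(region: RegionData, trait: str, p_threshold: float = 1e-4) -> bool:
    """True iff the trait has at least one variant with p strictly below
    ``p_threshold`` in the region (used to skip tissues with no eQTL signal)."""
    return bool(np.min(region.pvalues(trait)) < p_threshold)


class MolocModel:
    """Colocalization model for one region; ``fit()`` returns MolocResults.

    Thin statsmodels-style wrapper over :func:`run_moloc` so colocalization
    composes with :class:`~mrmoloc.mr.MRModel` in pipelines.
    """

    def __init__(self, region: RegionData, priors: Sequence[float] = DEFAULT_PRIORS,
                 prior_sds: Mapping[str, float] | None = None):
        self.region = region
        self.priors = tuple(priors)
        self.prior_sds = prior_sds

    @classmethod
    def from_sumstats(cls, trait_sumstats: Mapping[str, SumStats],
                      variant_ids: Sequence[str] | None = None,
                      priors: Sequence[float] = DEFAULT_PRIORS,
                      prior_sds: Mapping[str, float] | None = None) -> "MolocModel":
        return cls(RegionData.from_sumstats(trait_sumstats, variant_ids),
                   priors=priors, prior_sds=prior_sds)

    def fit(self, ppa_threshold: float = 0.8) -> MolocResults:
        return run_moloc(self.region, priors=self.priors, prior_sds=self.prior_sds,
                         ppa_threshold=ppa_threshold)
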