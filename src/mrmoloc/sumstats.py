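"""GWAS summary-statistics data model, I/O and preprocessing.

This module holds the per-variant association record (:class:`VariantAssociation`),
its tabular container (:class:`SumStats`), LD matrices and gene annotations, and
the preprocessing steps every two-sample MR analysis needs before estimation:

* allele harmonization of exposure and outcome effects to a shared effect allele
  (:func:`harmonize`), including strand-flip recovery and removal of ambiguous
  palindromic variants;
* cis/trans classification of a variant relative to a gene body with a 1 Mb
  window (:func:`classify_cis_trans`);
* minor-allele-frequency filtering (:func:`filter_maf`);
* greedy LD clumping to a mutually independent, genome-wide-significant
  instrument set (:func:`ld_clump`).

Summary statistics travel as tab-separated text with a header row; the column
names are remappable so external files need not be rewritten.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, FormatError, ParameterError, ValidationError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the tab-separated summary-statistics format
SUMSTATS_COLUMNS = [
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

TRAIT_TYPES = ("quantitative", "binary")


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class VariantAssociation:
    """Marginal association of one variant with one trait.

    ``beta`` is per effect-allele copy: log odds ratio for binary traits,
    phenotype-SD or natural units for quantitative traits.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    trait_id: str = ""
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: effect_allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: other_allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: identical alleles")
        if not 0.0 < self.eaf < 1.0:
            raise ValidationError(f"{self.variant_id}: eaf {self.eaf} outside (0, 1)")
        if not self.se > 0.0:
            raise ValidationError(f"{self.variant_id}: se {self.se} must be > 0")
        if not 0.0 < self.pval <= 1.0:
            raise ValidationError(f"{self.variant_id}: pval {self.pval} outside (0, 1]")
        if not self.n > 0:
            raise ValidationError(f"{self.variant_id}: n {self.n} must be > 0")
        if self.trait_type not in TRAIT_TYPES:
            raise ValidationError(
                f"{self.variant_id}: trait_type {self.trait_type!r} not in {TRAIT_TYPES}"
            )
        _check_p_z_consistency(self.variant_id, self.beta, self.se, self.pval)

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se


def _check_p_z_consistency(variant_id: str, beta: float, se: float, pval: float) -> None:
    """Require the reported p-value to agree with |beta/se| under a normal
    approximation to within 10% on the -log10 scale (0.05 absolute floor for
    near-null records, where the relative criterion is vacuous)."""
    logp_expected = -chi2_logsf_log10(beta / se)
    logp_reported = -math.log10(pval) if pval > 0 else math.inf
    tol = max(0.1 * abs(logp_expected), 0.05)
    if abs(logp_reported - logp_expected) > tol:
        raise ValidationError(
            f"{variant_id}: pval {pval:.3g} inconsistent with |beta/se|="
            f"{abs(beta / se):.3f} (expected p ~ {10 ** -logp_expected:.3g})"
        )


def chi2_logsf_log10(z: float) -> float:
    """log10 of the two-sided normal p-value for z, computed via log_ndtr so
    that it stays finite and accurate far below double-precision underflow."""
    from scipy.special import log_ndtr

    return (math.log(2.0) + log_ndtr(-abs(z))) / math.log(10)


def pval_from_z(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value(s) from z score(s)."""
    return stats.chi2.sf(np.asarray(z, dtype=float) ** 2, df=1)


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic span of a gene (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class LDMatrix:
    """Signed pairwise LD correlations over an ordered variant set."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValidationError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValidationError("LD matrix has |r| > 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def write(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", index_label="variant_id", float_format="%.17g"
        )


def read_ld_matrix(path) -> LDMatrix:
    """Read a square tab-separated LD matrix with variant_id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise FormatError("LD matrix row and column variant ids differ")
    return LDMatrix(variant_ids=[str(v) for v in df.index], r=df.to_numpy(dtype=float))


def read_gene_annotations(path, zero_based: bool = False) -> list[GeneAnnotation]:
    """Read 4-column gene annotations (gene_id, chr, start, end).

    With ``zero_based=True`` the input is treated as BED-style half-open and
    converted to the internal 1-based inclusive convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "chr", "start", "end"])
    offset = 1 if zero_based else 0
    return [
        GeneAnnotation(str(r.gene_id), str(r.chr), int(r.start) + offset, int(r.end))
        for r in df.itertuples()
    ]


class SumStats:
    """Ordered collection of :class:`VariantAssociation` for one trait.

    Backed by a pandas DataFrame with the canonical columns; construction
    validates every row. Row order is preserved through I/O.
    """

    def __init__(self, df: pd.DataFrame, trait_id: str, trait_type: str, validate: bool = True):
        if trait_type not in TRAIT_TYPES:
            raise ParameterError(f"trait_type {trait_type!r} not in {TRAIT_TYPES}")
        missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        self.df = df[SUMSTATS_COLUMNS].reset_index(drop=True).copy()
        self.df["variant_id"] = self.df["variant_id"].astype(str)
        self.df["chr"] = self.df["chr"].astype(str)
        self.trait_id = trait_id
        self.trait_type = trait_type
        if validate:
            self._validate()

    def _validate(self) -> None:
        for i, rec in enumerate(self.df.itertuples(index=False)):
            try:
                self._record_from_row(rec)
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc

    def _record_from_row(self, row) -> VariantAssociation:
        return VariantAssociation(
            variant_id=str(row.variant_id),
            chromosome=str(row.chr),
            position=int(row.pos),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=int(row.n),
            trait_id=self.trait_id,
            trait_type=self.trait_type,
        )

    def records(self) -> list[VariantAssociation]:
        return [self._record_from_row(r) for r in self.df.itertuples(index=False)]

    @classmethod
    def from_records(cls, records: Sequence[VariantAssociation], trait_id: str | None = None,
                     trait_type: str | None = None) -> "SumStats":
        if not records:
            raise AnalysisError("cannot build SumStats from an empty record list")
        trait_id = trait_id if trait_id is not None else records[0].trait_id
        trait_type = trait_type if trait_type is not None else records[0].trait_type
        df = pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in records],
                "chr": [r.chromosome for r in records],
                "pos": [r.position for r in records],
                "effect_allele": [r.effect_allele for r in records],
                "other_allele": [r.other_allele for r in records],
                "eaf": [r.eaf for r in records],
                "beta": [r.beta for r in records],
                "se": [r.se for r in records],
                "pval": [r.pval for r in records],
                "n": [r.n for r in records],
            }
        )
        return cls(df, trait_id=trait_id, trait_type=trait_type, validate=False)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.records())

    def subset(self, variant_ids: Iterable[str]) -> "SumStats":
        """Rows whose variant_id is in ``variant_ids``, original order kept."""
        keep = set(variant_ids)
        df = self.df[self.df["variant_id"].isin(keep)]
        return SumStats(df, self.trait_id, self.trait_type, validate=False)

    def by_variant(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records()}


def read_sumstats(path, trait_id: str, trait_type: str,
                  column_map: Mapping[str, str] | None = None) -> SumStats:
    """Read a tab-separated summary-statistics table into a validated SumStats.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    trait_id, trait_type :
        Trait label and type ("quantitative" or "binary") attached to each record.
    column_map :
        Optional mapping from canonical column name to the name used in the file,
        e.g. ``{"variant_id": "SNP", "pval": "P"}``.

    Raises
    ------
    FormatError
        If a mandatory column is absent (the error names it).
    ValidationError
        If a row fails field validation; the message carries the row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("eaf", "beta", "se", "pval"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(f"non-numeric {col} value at line {line}")
        df[col] = coerced
    return SumStats(df, trait_id=trait_id, trait_type=trait_type)


def write_sumstats(ss: SumStats, path) -> None:
    """Write summary statistics as canonical tab-separated text (round-trips
    field-identically with :func:`read_sumstats`)."""
    ss.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects aligned to one shared effect allele.

    ``beta_exposure`` is the gene–exposure estimate (γ̂_j), ``beta_outcome``
    the gene–outcome estimate (Γ̂_j) and ``se_outcome`` its standard error
    (σ_Yj); these are the quantities the Wald ratio and IVW estimators consume.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    eaf_outcome: float
    n_exposure: int
    n_outcome: int
    status: str = "aligned"  # aligned | flipped | dropped_palindromic | dropped_incompatible

    def __post_init__(self) -> None:
        if self.status in ("aligned", "flipped"):
            if not self.se_exposure > 0 or not self.se_outcome > 0:
                raise ValidationError(f"{self.variant_id}: non-positive se in harmonized pair")

    @property
    def usable(self) -> bool:
        return self.status in ("aligned", "flipped")


def _dropped(variant_id: str, status: str) -> HarmonizedPair:
    # dropped records carry no effect estimates into downstream analysis
    return HarmonizedPair(
        variant_id=variant_id,
        beta_exposure=math.nan,
        se_exposure=math.nan,
        beta_outcome=math.nan,
        se_outcome=math.nan,
        eaf_exposure=math.nan,
        eaf_outcome=math.nan,
        n_exposure=0,
        n_outcome=0,
        status=status,
    )


def harmonize(exposure: SumStats | Sequence[VariantAssociation],
              outcome: SumStats | Sequence[VariantAssociation],
              palindrome_eaf_window: float = 0.08) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Rules, applied per shared variant:

    * identical allele pair, same orientation -> ``aligned``, effects untouched;
    * alleles swapped (outcome's effect allele is the exposure's other allele)
      -> outcome beta negated and eaf replaced by 1-eaf, status ``flipped``;
    * non-palindromic pairs are additionally matched up to strand
      complementation before being declared incompatible;
    * palindromic pairs (A/T or C/G) with minor-allele frequency within
      ``palindrome_eaf_window`` of 0.5 in either study are
      ``dropped_palindromic`` (allele frequency cannot resolve the strand);
      unambiguous palindromes are aligned by effect-allele-frequency
      concordance;
    * anything else -> ``dropped_incompatible``.

    Returns one :class:`HarmonizedPair` per shared variant, in exposure order.
    Raises :class:`AnalysisError` if the two variant sets do not intersect.
    """
    exp_map = exposure.by_variant() if isinstance(exposure, SumStats) else {
        r.variant_id: r for r in exposure}
    out_map = outcome.by_variant() if isinstance(outcome, SumStats) else {
        r.variant_id: r for r in outcome}
    shared = [v for v in exp_map if v in out_map]
    if not shared:
        raise AnalysisError("no shared instruments between exposure and outcome")

    pairs = []
    for vid in shared:
        e, o = exp_map[vid], out_map[vid]
        pairs.append(_harmonize_one(e, o, palindrome_eaf_window))
    return pairs


def _harmonize_one(e: VariantAssociation, o: VariantAssociation,
                   window: float) -> HarmonizedPair:
    e_pal = _is_palindromic(e.effect_allele, e.other_allele)

    if e_pal:
        if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
            return _dropped(e.variant_id, "dropped_incompatible")
        if min(e.eaf, 1 - e.eaf) > 0.5 - window or min(o.eaf, 1 - o.eaf) > 0.5 - window:
            return _dropped(e.variant_id, "dropped_palindromic")
        # frequency-resolved orientation: effect alleles agree iff eafs fall on
        # the same side of 0.5 (label match and strand flip are equivalent here)
        flip = (e.eaf - 0.5) * (o.eaf - 0.5) < 0
    else:
        oa, ob = o.effect_allele, o.other_allele
        if (oa, ob) == (e.effect_allele, e.other_allele):
            flip = False
        elif (oa, ob) == (e.other_allele, e.effect_allele):
            flip = True
        else:
            oa_c, ob_c = COMPLEMENT[oa], COMPLEMENT[ob]
            if (oa_c, ob_c) == (e.effect_allele, e.other_allele):
                flip = False
            elif (oa_c, ob_c) == (e.other_allele, e.effect_allele):
                flip = True
            else:
                return _dropped(e.variant_id, "dropped_incompatible")

    beta_o = -o.beta if flip else o.beta
    eaf_o = 1 - o.eaf if flip else o.eaf
    return HarmonizedPair(
        variant_id=e.variant_id,
        beta_exposure=e.beta,
        se_exposure=e.se,
        beta_outcome=beta_o,
        se_outcome=o.se,
        eaf_exposure=e.eaf,
        eaf_outcome=eaf_o,
        n_exposure=e.n,
        n_outcome=o.n,
        status="flipped" if flip else "aligned",
    )


def classify_cis_trans(variant: VariantAssociation, gene: GeneAnnotation,
                       window: int = 1_000_000) -> str:
    """Classify a variant as "cis" or "trans" relative to a gene.

    cis means same chromosome and position within [start - window, end + window]
    (gene body plus the window on both ends, 1-based inclusive); anything else,
    including a different chromosome, is trans.
    """
    if variant.chromosome != gene.chromosome:
        return "trans"
    if gene.start - window <= variant.position <= gene.end + window:
        return "cis"
    return "trans"


def filter_maf(records: SumStats | Sequence[VariantAssociation],
               min_maf: float = 0.05):
    """Keep records whose minor-allele frequency min(eaf, 1-eaf) >= min_maf."""
    if isinstance(records, SumStats):
        maf = np.minimum(records.df["eaf"], 1.0 - records.df["eaf"])
        return SumStats(records.df[maf >= min_maf], records.trait_id,
                        records.trait_type, validate=False)
    return [r for r in records if r.maf >= min_maf]


def ld_clump(records: SumStats | Sequence[VariantAssociation], ld: LDMatrix,
             p_threshold: float = 5e-8, r2_threshold: float = 0.001):
    """Greedy LD clumping to an independent genome-wide-significant set.

    Discards records with pval >= ``p_threshold``; then repeatedly takes the
    remaining record with the smallest p-value as an index variant and removes
    everything with r² > ``r2_threshold`` against it. Ties in p are broken by
    lexicographic variant_id so the result is invariant to input order. The
    returned collection preserves the input's row order.

    Raises :class:`AnalysisError` if a significant record is absent from ``ld``.
    """
    recs = records.records() if isinstance(records, SumStats) else list(records)
    sig = [r for r in recs if r.pval < p_threshold]
    for r in sig:
        if r.variant_id not in ld:
            raise AnalysisError(f"variant {r.variant_id} absent from LD matrix")
    candidates = sorted(sig, key=lambda r: (r.pval, r.variant_id))
    kept_ids: list[str] = []
    while candidates:
        index = candidates.pop(0)
        kept_ids.append(index.variant_id)
        candidates = [
            r for r in candidates if ld.r2(index.variant_id, r.variant_id) <= r2_threshold
        ]
    kept_set = set(kept_ids)
    kept = [r for r in recs if r.variant_id in kept_set]
    if isinstance(records, SumStats):
        return records.subset(kept_set)
    return kept
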