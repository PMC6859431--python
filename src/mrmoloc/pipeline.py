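"""End-to-end orchestration: conservative MR -> liberal MR -> sensitivity
analyses -> per-cell-type colocalization -> consolidated report.

The study design mirrors the cytokine/immune-mediated-disease framework:

1. **Conservative MR** — one cis-acting instrument per molecular exposure
   (smallest p-value among genome-wide-significant, MAF-filtered variants
   within 1 Mb of the gene), Wald ratio per outcome. Exposures with no
   eligible cis instrument are reported as skipped with the reason.
2. **Liberal MR** — all LD-clumped instruments (cis or trans), IVW per
   outcome; exposures left with fewer than two instruments after clumping are
   excluded; leave-one-out runs whenever three or more instruments remain.
3. **Sensitivity** — reverse MR for every Bonferroni-surviving pair and a
   Steiger directionality test for every analyzed pair (variance explained
   summed over the pair's instruments).
4. **Colocalization** — for every pair with p < 0.05 in either MR mode and
   every expression dataset (cell type) passing the eQTL prefilter, a
   three-trait moloc run (expression, protein, disease) over the cis region.

Bonferroni thresholds use the exposure/outcome counts actually analyzed in
each mode. Identical config + seed reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import AnalysisError, ValidationError
from .moloc import DEFAULT_PRIORS, RegionData, eqtl_prefilter, run_moloc
from .mr import (
    MRResults,
    bonferroni_threshold,
    ivw,
    leave_one_out,
    reverse_mr,
    steiger_from_r2,
    wald_ratio,
)
from .sumstats import (
    GeneAnnotation,
    LDMatrix,
    SumStats,
    classify_cis_trans,
    filter_maf,
    harmonize,
    ld_clump,
    read_gene_annotations,
    read_ld_matrix,
    read_sumstats,
)


@dataclass
class Thresholds:
    """All analysis thresholds in one place (defaults follow the framework)."""

    instrument_p: float = 5e-8
    clump_r2: float = 0.001
    cis_window: int = 1_000_000
    min_maf: float = 0.05
    moloc_entry_p: float = 0.05
    ppa: float = 0.8
    eqtl_prefilter_p: float = 1e-4
    alpha: float = 0.05
    palindrome_eaf_window: float = 0.08

    def validate(self) -> None:
        for name in ("instrument_p", "clump_r2", "min_maf", "moloc_entry_p",
                     "ppa", "eqtl_prefilter_p", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"threshold {name}={v} outside (0, 1)")
        if self.cis_window < 0:
            raise ValidationError("cis_window must be >= 0")


@dataclass
class StudyConfig:
    """Declarative description of a full study.

    ``exposures``: list of dicts with trait_id, gene_id, path.
    ``outcomes``: list of dicts with trait_id, path, trait_type.
    ``expression``: {cell_type: {gene_id: path}}.
    """

    exposures: list[dict]
    outcomes: list[dict]
    expression: dict[str, dict[str, str]]
    ld_matrix: str
    gene_annotations: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    priors: tuple = DEFAULT_PRIORS
    output_dir: str = "mrmoloc_out"
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            exposures=raw["exposures"],
            outcomes=raw["outcomes"],
            expression=raw.get("expression", {}),
            ld_matrix=raw["ld_matrix"],
            gene_annotations=raw["gene_annotations"],
            thresholds=thr,
            priors=tuple(raw.get("priors", DEFAULT_PRIORS)),
            output_dir=raw.get("output_dir", "mrmoloc_out"),
            seed=int(raw.get("seed", 0)),
            base_dir=path.parent,
        )

    def _resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self) -> None:
        """Check thresholds and that every referenced path resolves."""
        self.thresholds.validate()
        paths = [self.ld_matrix, self.gene_annotations]
        paths += [e["path"] for e in self.exposures]
        paths += [o["path"] for o in self.outcomes]
        for genes in self.expression.values():
            paths += list(genes.values())
        for p in paths:
            if not self._resolve(p).exists():
                raise ValidationError(f"path not found: {p}")

    def config_hash(self) -> str:
        payload = {
            "exposures": self.exposures,
            "outcomes": self.outcomes,
            "expression": self.expression,
            "ld_matrix": str(self.ld_matrix),
            "gene_annotations": str(self.gene_annotations),
            "thresholds": vars(self.thresholds),
            "priors": list(self.priors),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class StudyData:
    """All study inputs loaded and indexed."""

    def __init__(self, config: StudyConfig):
        config.validate()
        self.config = config
        self.ld: LDMatrix = read_ld_matrix(config._resolve(config.ld_matrix))
        genes = read_gene_annotations(config._resolve(config.gene_annotations))
        self.genes: dict[str, GeneAnnotation] = {g.gene_id: g for g in genes}
        self.exposures: dict[str, SumStats] = {}
        self.exposure_gene: dict[str, str] = {}
        for e in config.exposures:
            self.exposures[e["trait_id"]] = read_sumstats(
                config._resolve(e["path"]), e["trait_id"],
                e.get("trait_type", "quantitative"))
            self.exposure_gene[e["trait_id"]] = e["gene_id"]
        self.outcomes: dict[str, SumStats] = {}
        for o in config.outcomes:
            self.outcomes[o["trait_id"]] = read_sumstats(
                config._resolve(o["path"]), o["trait_id"], o["trait_type"])
        self.expression: dict[str, dict[str, SumStats]] = {}
        for cell_type, per_gene in config.expression.items():
            self.expression[cell_type] = {
                gene: read_sumstats(config._resolve(p), f"{gene}@{cell_type}",
                                    "quantitative")
                for gene, p in per_gene.items()
            }


_MR_COLUMNS = ["exposure", "outcome", "method", "nsnp", "b", "se", "pval",
               "neg_log10_pval", "passes_bonferroni", "status", "reason"]


def _mr_row(res: MRResults, status="ok", reason=""):
    return {
        "exposure": res.exposure_id, "outcome": res.outcome_id, "method": res.method,
        "nsnp": res.n_instruments, "b": res.estimate, "se": res.se, "pval": res.pval,
        "neg_log10_pval": res.neg_log10_pval, "passes_bonferroni": False,
        "status": status, "reason": reason,
    }


def _skip_row(exposure, outcome, reason):
    return {
        "exposure": exposure, "outcome": outcome, "method": "", "nsnp": 0,
        "b": math.nan, "se": math.nan, "pval": math.nan,
        "neg_log10_pval": math.nan, "passes_bonferroni": False,
        "status": "skipped", "reason": reason,
    }


def _apply_bonferroni(df: pd.DataFrame, alpha: float) -> tuple[pd.DataFrame, float]:
    """Flag rows passing the Bonferroni threshold computed from the counts of
    exposures and outcomes actually analyzed (status == ok)."""
    ok = df[df["status"] == "ok"]
    n_exp = ok["exposure"].nunique()
    n_out = ok["outcome"].nunique()
    if n_exp == 0 or n_out == 0:
        return df, math.nan
    thr = bonferroni_threshold(n_exp, n_out, alpha)
    df = df.copy()
    df["passes_bonferroni"] = (df["status"] == "ok") & (df["pval"] <= thr)
    return df, thr


def select_conservative_instrument(exposure: SumStats, gene: GeneAnnotation,
                                   thr: Thresholds):
    """Best single cis instrument: smallest p among cis, genome-wide-
    significant, MAF-filtered variants (ties by variant_id). Returns
    (record, None) or (None, skip reason)."""
    cis = [r for r in exposure.records()
           if classify_cis_trans(r, gene, thr.cis_window) == "cis"]
    sig = [r for r in cis if r.pval < thr.instrument_p]
    if not sig:
        return None, "no significant cis instrument"
    kept = [r for r in sig if r.maf >= thr.min_maf]
    if not kept:
        return None, "maf"
    return min(kept, key=lambda r: (r.pval, r.variant_id)), None


def run_conservative(data: StudyData) -> pd.DataFrame:
    """Single-cis-instrument Wald-ratio MR for every exposure-outcome pair."""
    thr = data.config.thresholds
    rows = []
    for exp_id, exp_ss in data.exposures.items():
        gene = data.genes.get(data.exposure_gene[exp_id])
        if gene is None:
            for out_id in data.outcomes:
                rows.append(_skip_row(exp_id, out_id, "gene annotation missing"))
            continue
        inst, reason = select_conservative_instrument(exp_ss, gene, thr)
        for out_id, out_ss in data.outcomes.items():
            if inst is None:
                rows.append(_skip_row(exp_id, out_id, reason))
                continue
            pairs = harmonize([inst], out_ss.records(),
                              palindrome_eaf_window=thr.palindrome_eaf_window)
            usable = [p for p in pairs if p.usable]
            if not usable:
                rows.append(_skip_row(exp_id, out_id,
                                      f"instrument {pairs[0].status}"))
                continue
            rows.append(_mr_row(wald_ratio(usable[0], exposure_id=exp_id,
                                           outcome_id=out_id)))
    df = pd.DataFrame(rows, columns=_MR_COLUMNS)
    df, thr_used = _apply_bonferroni(df, thr.alpha)
    df.attrs["bonferroni_threshold"] = thr_used
    return df


def select_liberal_instruments(exposure: SumStats, ld: LDMatrix, thr: Thresholds):
    """All clumped instruments (cis or trans) after the MAF filter."""
    filtered = filter_maf(exposure, thr.min_maf)
    if len(filtered) == 0:
        return []
    clumped = ld_clump(filtered, ld, p_threshold=thr.instrument_p,
                       r2_threshold=thr.clump_r2)
    return clumped.records()


def run_liberal(data: StudyData) -> tuple[pd.DataFrame, dict]:
    """Multi-instrument IVW MR with leave-one-out tables.

    Exposures reduced to fewer than two instruments after clumping are
    excluded with the reason; leave-one-out runs whenever a fit retains at
    least three usable instruments.
    """
    thr = data.config.thresholds
    rows, loo_tables = [], {}
    for exp_id, exp_ss in data.exposures.items():
        instruments = select_liberal_instruments(exp_ss, data.ld, thr)
        if len(instruments) < 2:
            reason = "no instruments" if not instruments else "single instrument"
            for out_id in data.outcomes:
                rows.append(_skip_row(exp_id, out_id, reason))
            continue
        for out_id, out_ss in data.outcomes.items():
            pairs = harmonize(instruments, out_ss.records(),
                              palindrome_eaf_window=thr.palindrome_eaf_window)
            usable = [p for p in pairs if p.usable]
            if len(usable) < 2:
                rows.append(_skip_row(
                    exp_id, out_id,
                    "single instrument" if len(usable) == 1 else "no instruments"))
                continue
            rows.append(_mr_row(ivw(usable, exposure_id=exp_id, outcome_id=out_id)))
            if len(usable) >= 3:
                loo = leave_one_out(usable, exposure_id=exp_id, outcome_id=out_id)
                loo_tables[(exp_id, out_id)] = pd.DataFrame(
                    {
                        "excluded_variant": [vid for vid, _ in loo],
                        "nsnp": [r.n_instruments for _, r in loo],
                        "b": [r.estimate for _, r in loo],
                        "se": [r.se for _, r in loo],
                        "pval": [r.pval for _, r in loo],
                    }
                )
    df = pd.DataFrame(rows, columns=_MR_COLUMNS)
    df, thr_used = _apply_bonferroni(df, thr.alpha)
    df.attrs["bonferroni_threshold"] = thr_used
    return df, loo_tables


def _pair_instruments(data: StudyData, mode: str, exp_id: str, out_id: str,
                      nsnp_hint: int | None = None):
    """Reconstruct the harmonized pairs a reported MR row was fitted on."""
    thr = data.config.thresholds
    exp_ss = data.exposures[exp_id]
    if mode == "conservative":
        gene = data.genes[data.exposure_gene[exp_id]]
        inst, _ = select_conservative_instrument(exp_ss, gene, thr)
        instruments = [inst] if inst is not None else []
    else:
        instruments = select_liberal_instruments(exp_ss, data.ld, thr)
    if not instruments:
        return []
    pairs = harmonize(instruments, data.outcomes[out_id].records(),
                      palindrome_eaf_window=thr.palindrome_eaf_window)
    return [p for p in pairs if p.usable]


def run_sensitivity(data: StudyData, conservative: pd.DataFrame,
                    liberal: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reverse MR for Bonferroni survivors; Steiger for every analyzed pair.

    The Steiger test pools variance explained across a fit's instruments
    (independent after clumping, so r-squared values add).
    """
    thr = data.config.thresholds
    surviving = set()
    for df in (conservative, liberal):
        for r in df[df["passes_bonferroni"]].itertuples():
            surviving.add((r.exposure, r.outcome))

    reverse_rows = []
    for exp_id, out_id in sorted(surviving):
        res = reverse_mr(data.outcomes[out_id], data.exposures[exp_id], data.ld,
                         p_threshold=thr.instrument_p, r2_threshold=thr.clump_r2,
                         exposure_id=out_id, outcome_id=exp_id)
        reverse_rows.append({
            "exposure": out_id, "outcome": exp_id, "method": res.method,
            "nsnp": res.n_instruments, "b": res.estimate, "se": res.se,
            "pval": res.pval, "flag": res.flag,
        })
    reverse_df = pd.DataFrame(
        reverse_rows,
        columns=["exposure", "outcome", "method", "nsnp", "b", "se", "pval", "flag"])

    steiger_rows = []
    for mode, df in (("conservative", conservative), ("liberal", liberal)):
        for r in df[df["status"] == "ok"].itertuples():
            pairs = _pair_instruments(data, mode, r.exposure, r.outcome)
            if not pairs:
                continue
            out_type = data.outcomes[r.outcome].trait_type
            r2_exp = r2_out = 0.0
            for p in pairs:
                t2e = (p.beta_exposure / p.se_exposure) ** 2
                t2o = (p.beta_outcome / p.se_outcome) ** 2
                r2_exp += t2e / (t2e + p.n_exposure - 2)
                r2_out += t2o / (t2o + p.n_outcome - 2)
            st = steiger_from_r2(r2_exp, r2_out, pairs[0].n_exposure,
                                 pairs[0].n_outcome)
            steiger_rows.append({
                "mode": mode, "exposure": r.exposure, "outcome": r.outcome,
                "outcome_type": out_type, "nsnp": len(pairs),
                "r2_exposure": st.r2_exposure, "r2_outcome": st.r2_outcome,
                "correct_direction": st.correct_direction, "z": st.z,
                "pval": st.pval,
            })
    steiger_df = pd.DataFrame(
        steiger_rows,
        columns=["mode", "exposure", "outcome", "outcome_type", "nsnp",
                 "r2_exposure", "r2_outcome", "correct_direction", "z", "pval"])
    return reverse_df, steiger_df


_MOLOC_COLUMNS = ["exposure", "outcome", "cell_type", "gene", "n_variants",
                  "ppa_abc", "decision", "best_snp_a", "best_snp_b", "best_snp_c",
                  "status", "reason"]


def run_moloc_stage(data: StudyData, conservative: pd.DataFrame,
                    liberal: pd.DataFrame) -> pd.DataFrame:
    """Three-trait colocalization for every MR pair entering at p < 0.05.

    Entry uses the better (smaller) of the conservative and liberal p-values
    per pair. For each entering pair and each configured expression dataset
    (cell type), the region is the exposure gene's cis window; cell types
    without expression data for the gene are marked "not expressed" and those
    failing the eQTL prefilter "no eQTL".
    """
    thr = data.config.thresholds
    best_p: dict[tuple[str, str], float] = {}
    for df in (conservative, liberal):
        for r in df[df["status"] == "ok"].itertuples():
            key = (r.exposure, r.outcome)
            if not math.isnan(r.pval):
                best_p[key] = min(best_p.get(key, math.inf), r.pval)

    rows = []
    for (exp_id, out_id), p in sorted(best_p.items()):
        if p >= thr.moloc_entry_p:
            continue
        gene_id = data.exposure_gene[exp_id]
        gene = data.genes[gene_id]
        exp_ss = data.exposures[exp_id]
        out_ss = data.outcomes[out_id]
        region_ids = [
            r.variant_id for r in exp_ss.records()
            if classify_cis_trans(r, gene, thr.cis_window) == "cis"
        ]
        for cell_type in sorted(data.expression):
            base = {"exposure": exp_id, "outcome": out_id, "cell_type": cell_type,
                    "gene": gene_id, "n_variants": 0, "ppa_abc": math.nan,
                    "decision": False, "best_snp_a": "", "best_snp_b": "",
                    "best_snp_c": ""}
            eqtl = data.expression[cell_type].get(gene_id)
            if eqtl is None:
                rows.append({**base, "status": "skipped", "reason": "not expressed"})
                continue
            try:
                region = RegionData.from_sumstats(
                    {"a": eqtl, "b": exp_ss, "c": out_ss}, variant_ids=region_ids)
            except AnalysisError as exc:
                rows.append({**base, "status": "error", "reason": str(exc)})
                continue
            if not eqtl_prefilter(region, "a", thr.eqtl_prefilter_p):
                rows.append({**base, "status": "skipped", "reason": "no eQTL"})
                continue
            res = run_moloc(region, priors=data.config.priors,
                            ppa_threshold=thr.ppa)
            rows.append({
                **base, "n_variants": res.n_variants, "ppa_abc": res.ppa_all,
                "decision": res.decision, "best_snp_a": res.best_snp["a"],
                "best_snp_b": res.best_snp["b"], "best_snp_c": res.best_snp["c"],
                "status": "ok", "reason": "",
            })
    return pd.DataFrame(rows, columns=_MOLOC_COLUMNS)


@dataclass
class StudyReport:
    """Consolidated study output; every number traces to a module operation."""

    conservative: pd.DataFrame
    liberal: pd.DataFrame
    leave_one_out: dict
    reverse: pd.DataFrame
    steiger: pd.DataFrame
    moloc: pd.DataFrame
    log: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.6g")
        self.conservative.to_csv(outdir / "mr_conservative.tsv", **fmt)
        self.liberal.to_csv(outdir / "mr_liberal.tsv", **fmt)
        for (exp_id, out_id), df in self.leave_one_out.items():
            df.to_csv(outdir / f"loo_{exp_id}_{out_id}.tsv", **fmt)
        self.reverse.to_csv(outdir / "mr_reverse.tsv", **fmt)
        self.steiger.to_csv(outdir / "steiger.tsv", **fmt)
        self.moloc.to_csv(outdir / "moloc.tsv", **fmt)
        (outdir / "run_log.json").write_text(json.dumps(self.log, indent=2))
        (outdir / "summary.txt").write_text(self.summary())

    def summary(self) -> str:
        lines = ["mrmoloc study summary", "=" * 58]
        for name, df in (("conservative MR", self.conservative),
                         ("liberal MR", self.liberal)):
            ok = df[df["status"] == "ok"]
            sig = ok[ok["passes_bonferroni"]]
            thr = df.attrs.get("bonferroni_threshold",
                               self.log.get(f"bonferroni_{name.split()[0]}"))
            lines.append(
                f"{name}: {len(ok)} pairs analyzed, {len(sig)} pass Bonferroni"
                f" (threshold {thr:.3g})" if thr == thr else
                f"{name}: {len(ok)} pairs analyzed")
            for r in sig.itertuples():
                lines.append(f"  {r.exposure} -> {r.outcome}: b={r.b:+.3f}"
                             f" (se {r.se:.3f}), p={r.pval:.3e}, nsnp={r.nsnp}")
        ok_moloc = self.moloc[self.moloc["status"] == "ok"]
        lines.append(f"colocalization: {len(ok_moloc)} regions scored")
        for r in ok_moloc.itertuples():
            mark = "COLOC" if r.decision else "  -  "
            lines.append(f"  [{mark}] {r.exposure} / {r.outcome} in {r.cell_type}:"
                         f" PPA_abc={r.ppa_abc:.4f}")
        return "\n".join(lines) + "\n"


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full framework for a validated study configuration."""
    from . import __version__

    data = StudyData(config)
    conservative = run_conservative(data)
    liberal, loo = run_liberal(data)
    reverse, steiger = run_sensitivity(data, conservative, liberal)
    moloc_table = run_moloc_stage(data, conservative, liberal)
    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bonferroni_conservative": conservative.attrs.get("bonferroni_threshold"),
        "bonferroni_liberal": liberal.attrs.get("bonferroni_threshold"),
        "n_exposures": len(config.exposures),
        "n_outcomes": len(config.outcomes),
        "cell_types": sorted(config.expression),
    }
    return StudyReport(conservative=conservative, liberal=liberal,
                       leave_one_out=loo, reverse=reverse, steiger=steiger,
                       moloc=moloc_table, log=log)


# ---------------------------------------------------------------------------
# packaged demo study: one cytokine, one disease, three cell types, one of
# which shares the causal variant with protein and disease
# ---------------------------------------------------------------------------

#: region design for the demo (indices into the 240-variant region)
DEMO_N_VARIANTS = 240
DEMO_SHARED_INDEX = 25       # drives monocyte expression, protein and disease
DEMO_TCELL_INDEX = 60        # distinct (unlinked) causal variant for T cells
DEMO_PROTEIN_EXTRA = [80, 86, 92]   # trans-acting protein instruments
#: the disease's own polygenic background: trans loci with no protein effect,
#: spaced so LD clumping keeps them as mutually independent instruments
DEMO_DISEASE_OWN = list(range(100, 240, 3))


def demo_scenario(seed: int = 7):
    """Generative scenario behind the packaged demo study.

    One circulating cytokine (quantitative, n=5000) causally raises the risk
    of a disease (binary, n=50000, 30% case fraction, true slope 0.12 on the
    log-odds scale per cytokine unit). The cytokine has one cis association
    signal (rs26, per-allele effect 0.18) and three trans instruments (effect
    0.3, beyond the 1 Mb window); the cis variant also drives the gene's
    expression in monocytes (0.8 SD per allele, n=5000) and carries a direct
    disease effect (0.093 log odds) — the shared causal variant. T-cell
    expression is driven by an unlinked cis variant (rs61), neutrophil
    expression has no genetic signal, so colocalization should fire for
    monocytes only. The disease additionally has a polygenic background of
    trans loci (indices 100+, no cytokine effect): these supply the
    reverse-MR instruments, so the reverse analysis — as in real disease
    GWAS, where most risk loci do not act through any one cytokine — is
    dominated by cytokine-null instruments and stays null.
    """
    from .synth import SimScenario

    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, DEMO_N_VARIANTS)
    # common causal variants: keeps instrument strength comparable across seeds
    maf[[DEMO_SHARED_INDEX, DEMO_TCELL_INDEX] + DEMO_PROTEIN_EXTRA
        + DEMO_DISEASE_OWN] = 0.3
    return SimScenario(
        n_variants=DEMO_N_VARIANTS,
        maf=maf,
        ld_rho=0.25,
        pos_step=20_000,
        cohort_sizes={
            "CYTO1": 5_000,
            "IMD1": 50_000,
            "CYTO1_expr_monocyte": 5_000,
            "CYTO1_expr_neutrophil": 5_000,
            "CYTO1_expr_tcell": 5_000,
        },
        causal_map={
            "CYTO1": [(DEMO_SHARED_INDEX, 0.18)]
            + [(i, 0.3) for i in DEMO_PROTEIN_EXTRA],
            "IMD1": [(DEMO_SHARED_INDEX, 0.093)]
            + [(i, 0.3) for i in DEMO_DISEASE_OWN],
            "CYTO1_expr_monocyte": [(DEMO_SHARED_INDEX, 0.8)],
            "CYTO1_expr_neutrophil": [],
            "CYTO1_expr_tcell": [(DEMO_TCELL_INDEX, 0.8)],
        },
        trait_types={
            "CYTO1": "quantitative",
            "IMD1": "binary",
            "CYTO1_expr_monocyte": "quantitative",
            "CYTO1_expr_neutrophil": "quantitative",
            "CYTO1_expr_tcell": "quantitative",
        },
        noise_sd={t: 1.0 for t in ("CYTO1", "CYTO1_expr_monocyte",
                                   "CYTO1_expr_neutrophil", "CYTO1_expr_tcell")},
        disease_prevalence=0.3,
        causal_beta_exposure_to_outcome=0.12,
        mr_exposure="CYTO1",
        mr_outcome="IMD1",
        seed=seed,
    )


def make_demo_study(outdir, seed: int = 7) -> StudyConfig:
    """Simulate the demo scenario, write its data files under ``outdir`` and
    return a ready-to-run :class:`StudyConfig`."""
    from .synth import SIM_CHROM, simulate_traits_and_sumstats

    outdir = Path(outdir)
    scenario = demo_scenario(seed)
    sim = simulate_traits_and_sumstats(scenario)
    sim.write(outdir)
    # gene body around the shared causal variant; the 1 Mb window covers the region
    pos = scenario.positions
    gene_row = f"CYTO1\t{SIM_CHROM}\t{pos[DEMO_SHARED_INDEX] - 5000}\t{pos[DEMO_SHARED_INDEX] + 5000}\n"
    (outdir / "genes.tsv").write_text(gene_row)
    config = StudyConfig(
        exposures=[{"trait_id": "CYTO1", "gene_id": "CYTO1",
                    "path": "CYTO1.sumstats.tsv"}],
        outcomes=[{"trait_id": "IMD1", "path": "IMD1.sumstats.tsv",
                   "trait_type": "binary"}],
        expression={
            "monocyte": {"CYTO1": "CYTO1_expr_monocyte.sumstats.tsv"},
            "neutrophil": {"CYTO1": "CYTO1_expr_neutrophil.sumstats.tsv"},
            "tcell": {"CYTO1": "CYTO1_expr_tcell.sumstats.tsv"},
        },
        ld_matrix="ld.tsv",
        gene_annotations="genes.tsv",
        output_dir=str(outdir / "results"),
        seed=seed,
        base_dir=outdir,
    )
    yaml_payload = {
        "exposures": config.exposures,
        "outcomes": config.outcomes,
        "expression": config.expression,
        "ld_matrix": "ld.tsv",
        "gene_annotations": "genes.tsv",
        "seed": seed,
    }
    (outdir / "study.yaml").write_text(yaml.safe_dump(yaml_payload, sort_keys=False))
    return config
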