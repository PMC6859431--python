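# Methods

## Scope and model

mrmoloc estimates the causal effect of a molecular exposure (circulating
protein) on a disease from two-sample GWAS summary statistics, and asks
whether the exposure's gene expression in specific cell types, the protein,
and the disease share a single causal variant. The two components — MR
estimation and multiple-trait colocalization — make different assumptions and
are deliberately kept composable but independent.

### Two-sample MR

Instruments are variants robustly associated with the exposure
(p < 5×10⁻⁸), mutually independent after greedy LD clumping (r² < 0.001,
ties in p broken by lexicographic variant id so results are
platform-independent), with MAF ≥ 0.05. Two modes mirror the two
instrument-selection philosophies:

* **conservative** — one cis instrument (within 1 Mb of the gene body on
  either side, 1-based inclusive coordinates; the smallest-p eligible
  variant). Estimation is the Wald ratio Γ̂/γ̂ with first-order delta-method
  standard error σ_Y/|γ̂|; the second-order correction (adding
  Γ̂²σ_γ²/γ̂⁴) is available as an option but off by default, matching common
  two-sample practice.
* **liberal** — all clumped instruments, cis or trans, combined by
  fixed-effect IVW with weights γ̂²σ_Y⁻². The printed weighting uses only the
  outcome-side standard error; exposure-side uncertainty is *not* propagated.
  An exposure with fewer than two post-clump instruments is ineligible for
  this mode and reported as excluded, with the reason.

Key identities the test suite enforces: IVW equals the weighted
least-squares slope of Γ̂ on γ̂ through the origin; with one instrument IVW
reduces exactly to the Wald ratio; each leave-one-out estimate equals IVW on
the corresponding reduced set exactly.

The fixed-effect standard error is calibrated when instruments are strong and
the exposure explains a small share of outcome variance. When the exposure
explains a large share (tens of percent), neglecting exposure-side
uncertainty makes the CI anti-conservative by a few percent — an intrinsic
property of the estimator as defined, not corrected here.

Multiple testing uses Bonferroni α/(n_exposures × n_outcomes) with the counts
of pairs *actually analyzed per mode*, not the nominal panel size.

### Sensitivity analyses

* **Leave-one-out** refits IVW excluding each instrument in turn (requires
  ≥ 3 usable instruments); the exclusion with the largest estimate shift
  flags single-SNP influence.
* **Reverse MR** instruments the disease (same clumping thresholds) and
  estimates its effect on the protein. A disease GWAS with no
  genome-wide-significant instruments yields a flagged "underpowered" result
  rather than an error — the realistic outcome for small molecular-trait
  GWAS. Note that in a single shared locus, reverse MR is informative only
  when the disease has instruments that do *not* act through the exposure;
  with purely mediated architecture the reverse estimate converges to the
  reciprocal of the forward slope, which is why the demo study gives the
  disease a polygenic trans background.
* **Steiger directionality**: per-variant variance explained is computed by
  the unit-free t-statistic form r² = t²/(t² + n − 2) on each side (log-odds
  scale for binary traits); the frequency form 2·eaf·(1−eaf)·β², valid when
  betas are in phenotype-SD units, is selectable. r² values are summed over
  a fit's (independent) instruments and compared by Fisher-z,
  z = [atanh r_exp − atanh r_out] / √(1/(n_exp−3) + 1/(n_out−3)).

### Multiple-trait colocalization

Per variant and trait, evidence is the Wakefield approximate Bayes factor,
log ABF = ½log(1−r) + ½z²r, r = W/(V+W), with effect-size prior SD √W = 0.15
for quantitative traits and 0.2 for binary (log-odds) traits — the
coloc-family convention, configurable. A configuration partitions the
associated subset of traits into sharing groups; for three traits the space
has exactly 15 configurations including the null. The regional Bayes factor
of a configuration sums, over all placements of one causal variant per group
on **distinct** variants, the product of member-trait ABFs: computed exactly
by masked log-sum-exp enumeration while the placement tensor is small
(≤ 2×10⁶ cells), otherwise by signed inclusion–exclusion over partitions of
the group set (also exact; Möbius coefficients (−1)^{|B|−1}(|B|−1)!). All
arithmetic is in log space. Posteriors combine the regional Bayes factors
with per-variant priors p₁ = 10⁻⁴, p₂ = 10⁻⁶, p₃ = 10⁻⁷ (prior of a
configuration = product of p_{group size} over its groups) and are
normalized over the full space; PPA_abc ≥ 0.8 declares colocalization.
One causal variant per sharing group is assumed throughout — regions with
genuinely multi-signal traits inside the analysis window violate it and
depress PPA_abc (see Limitations).

Cell types enter only if the expression trait shows at least one association
with p < 10⁻⁴ in the region (strict inequality); pairs enter colocalization
only with MR p < 0.05 in either mode (the smaller of the two).

## Synthetic data

Haplotypes are latent AR(1) standard-normal sequences (adjacent correlation
`ld_rho`) thresholded at Φ⁻¹(MAF); genotypes are sums of two independent
haplotypes. This gives geometrically decaying, analytically controllable LD;
the genotype-scale correlation is attenuated relative to the latent scale by
the dichotomization. Each trait is simulated in its own cohort from an
independent RNG substream — the two-sample property holds by construction.
Quantitative traits are linear in genotype plus Gaussian noise; binary traits
are Bernoulli draws from a logistic model whose intercept is solved (Brent's
method) to hit the target prevalence, optionally driven by the exposure
phenotype realized in the outcome's own cohort (a true causal slope).
Summary statistics are marginal: per-variant simple linear regression
(quantitative) or a one-step score estimator of the log odds ratio,
U/I with U = Σg(y−p̄), I = p̄(1−p̄)Σ(g−ḡ)² (binary) — the standard fast
GWAS approximation, consistent for small effects.

What the generator does **not** emulate: genome-wide polygenicity, imputation
uncertainty, sample overlap between cohorts, population structure, real
haplotype block structure, winner's-curse instrument selection across
regions. Passing tests therefore demonstrate the estimators and the
colocalization arithmetic are correct under the stated generative model, not
that real-data artefacts are handled.

### Canonical validation scenarios (problem sizes)

* **Estimator coverage** (`mr_two_sample_scenario`): 5 unlinked instruments,
  per-allele effect 0.5 SD, MAF 0.3, 5 000 individuals per cohort, outcome
  residual SD 3 — the exposure explains ≤ 4% of outcome variance, the regime
  real molecular-exposure/disease pairs occupy. 95% CI coverage is ~94.5%
  (the ~0.5% deficit is ratio-estimator heavy-tailedness, not SE
  miscalibration; empirical SD / mean SE ≈ 1.01). 200 replicates per slope.
* **Colocalization discrimination** (`three_trait_region_scenario`): 40
  variants, `ld_rho` 0.25, 5 000 per trait; expression/protein effects
  0.5 SD, disease log-OR 0.4 at 30% prevalence; causal variants identical
  (shared) or at indices 5/20/35 (distinct). 100 replicates per arm.
* **Demo study**: 240 variants at 20 kb spacing, `ld_rho` 0.25; cis window
  covers the first 76. Shared variant rs26: monocyte expression 0.8 SD
  (z ≈ 33), protein 0.18 SD (z ≈ 8), direct disease log-OR 0.093 plus
  mediation slope 0.12 (z ≈ 6 at n = 50 000, 30% cases). Protein trans
  instruments (0.3 SD) at indices 80/86/92; disease polygenic background of
  47 trans loci (log-OR 0.3) to supply cytokine-null reverse-MR instruments.
  T-cell expression driven by unlinked rs61; neutrophil expression null.
  Effect sizes were fixed by a priori power analysis of the z-scores each
  stage needs.

These sizes keep the full validation suite within a few minutes on one CPU
while leaving comfortable Monte-Carlo margins.

## Numerical choices

* p-values from z-scores are computed via `log_ndtr`, keeping −log10 p finite
  and accurate beyond double-precision underflow (`chi2.logsf` returns −inf
  there); stored p-values floor at 10⁻³⁰⁰ in generated tables.
* Record validation requires reported p to agree with |β/se| within 10% on
  the −log10 scale, with a 0.05 absolute floor for near-null records where
  the relative criterion is vacuous.
* Summary-statistics writers use `%.17g` and readers `round_trip` float
  parsing, so write→read is bit-identical.
* Harmonization: non-palindromic allele pairs are matched up to strand
  complementation; palindromic pairs with MAF within 0.08 of 0.5 in either
  study are dropped; unambiguous palindromes are oriented by which side of
  0.5 the effect-allele frequencies fall on.
* Clump tie-breaks and conservative-instrument tie-breaks are lexicographic
  by variant id; identical config + seed reproduce byte-identical outputs.
* Degenerate inputs raise typed errors early: γ̂ = 0 Wald ratios, empty
  variant intersections, regions with fewer variants than sharing groups,
  binary cohorts drawing zero cases.

## Open design points resolved here

* The 1 Mb cis window is anchored to the whole gene body (± 1 Mb from either
  end), the more inclusive reading; anchoring at the TSS would only shrink
  the candidate set.
* The liberal-mode Bonferroni threshold follows the formula
  α/(exposures × outcomes) evaluated with the analyzed counts.
* Steiger defaults to the t-statistic r² form because beta units in real
  files are rarely guaranteed to be SD-scaled; the frequency form remains an
  option.
* Colocalization priors and prior SDs are the cited conventions of the
  coloc/moloc family; they are configurable because the appropriate values
  are study-dependent.

## Limitations

* Fixed-effect IVW only; no MR-Egger/weighted-median pleiotropy-robust
  estimators and no correlated-instrument IVW.
* Single causal variant per trait per region in colocalization; conditional
  or multi-causal decomposition is out of scope.
* Reverse MR applies no Steiger filtering to its instruments; at a genuinely
  shared locus with a strong disease signal the reverse estimate absorbs
  that locus's ratio (diluted by however many disease instruments exist).
* The LD matrix is user-supplied or estimated from a simulated cohort; no
  reference panels, no liftover, no VCF input.
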