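# Methods

This note documents the statistical models behind each `glycohub`
stage, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that
affect results.

## Meta-analysis of standardized mean differences

For gene *g* in one cohort×region stratum with case values *x* (n₁ ≥ 2)
and control values *y* (n₀ ≥ 2), the effect is Hedges' g: the pooled-SD
standardized mean difference d = (x̄ − ȳ)/s_p with the small-sample
correction J = 1 − 3/(4(n₁+n₀) − 9), and variance
se² = J²[(n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀))] (the Hedges–Olkin
convention). Strata with a zero pooled SD, or with fewer than two
samples in either arm, contribute nothing for that gene.

Strata are combined under an additive random-effects model:
wᵢ = 1/(seᵢ² + τ²), μ̂ = Σwᵢgᵢ/Σwᵢ, se(μ̂) = (Σwᵢ)^(−1/2). The
between-study variance τ² is estimated by REML (fixed-point iteration
on the restricted-likelihood stationarity condition, started at the
DerSimonian–Laird moment estimate, floored at zero, max 100 iterations
at tolerance 1e-8; non-convergence falls back to DerSimonian–Laird
with a logged warning). DerSimonian–Laird is available directly via
`method="dl"`. A single stratum passes through with τ² = 0. The REML
estimate is verified in the test suite against a grid-search maximizer
of the restricted likelihood and against R's `metafor::rma`.

**p-value reference.** The statistic z = μ̂/se(μ̂) is compared against a
t distribution with the total residual degrees of freedom
Σᵢ(n₁ᵢ + n₀ᵢ − 2) rather than a standard normal. Each stratum's
standard error is estimated from the same samples as the effect, and
the normal reference is anti-conservative exactly in the far tail that
matters when thousands of genes are screened and BH-corrected (in
simulation, ~2.5× the nominal rate at p = 1e-4 for two strata of 20+20
samples). With realistic arm sizes the t reference is numerically
indistinguishable from the normal for moderate p; under an all-null
simulation it restores the expected behavior of zero BH discoveries.

Multiple testing uses Benjamini–Hochberg step-up. When a glycogene
annotation is supplied, the analysis and the BH family are restricted
to glycogenes by default (the hypothesis space of the screen);
`correction_universe="global"` corrects over all genes first and
subsets afterwards. Strata can be pooled across regions (default) or
combined per region (`per_region=True`); the two modes bracket the
ambiguity in how multi-region cohorts are commonly pooled.

## Enrichment

**ORA** is the hypergeometric upper tail P[X ≥ k] with the universe
taken as all analyzed genes; query genes outside the universe are
dropped with a warning. Top-N extraction sorts by (q, p, name) so ties
are deterministic.

**Preranked GSEA** uses the weighted Kolmogorov–Smirnov running sum
with weight exponent 1 (the classic default): hit steps
|score|/Σ_set|score|, miss steps −1/(N − |S|); the enrichment score is
the extremum of the running sum, and score ties are broken by gene
name so rankings are reproducible. The null is gene-label permutation
(random same-size sets), appropriate because the input is a preranked
effect-size list, not per-sample phenotypes. NES divides the ES by the
mean |null ES| of the same sign and p is the same-sign permutation
tail (1 + hits)/(1 + same-sign count). Consequence: the attainable p
floor is roughly 2/n_perm, so collection-wide runs that must clear BH
at q < 0.05 over tens of sets need ≥ ~250 permutations
(`pipeline.run_hub_pipeline` default).

**Dual post-hoc test.** For each (glycosylation pathway, enriched
pathway) pair: (1) hypergeometric over-representation of the glyco
members within the enriched pathway, and (2) Wilcoxon rank-sum
comparing |combined effect| of the enriched pathway's glyco members
against its remaining members. The comparison population for the
Wilcoxon is genuinely open; "against the rest of the pathway" is the
default because it asks whether glyco members are *distinctive within*
the pathway, and `background="global"` switches to the genome-wide
comparison. BH runs within each test family separately, and a pair
passes only if both q-values are ≤ the FDR (inclusive).

The Wilcoxon implementation is exact (scipy enumeration) for
n₁+n₂ ≤ 12 without ties, otherwise a normal approximation with
midranks, tie correction and continuity correction; completely tied
inputs return p = 1. The identical routine backs the single-cell
marker test.

## Hub selection

Enriched pathways containing at least one differentially expressed
glycogene form one partition of a bipartite membership graph, the DE
glycogenes the other. A glycogene's degree is its number of incident
pathways ("in how many dysregulated processes does this enzyme sit"),
ranked with competition ranking and alphabetic tie order; the rank-1
gene is the functional hub, with all tied genes returned and flagged
when the maximum is shared. The enrichment threshold feeding this
stage is GSEA q < 0.05 by default.

## Pathway–ECM association

The ECM signature is the union of member genes of every pathway whose
name contains "ECM", "Extracellular" or "Collagen"
(case-insensitive); the outcome per stratum is the signature's mean
activity (an eigengene — first PC of the standardized member
submatrix, sign-aligned to the member mean — is available). Each
candidate pathway is summarized by the leading principal components
(default 1) of its standardized member submatrix, excluding genes
shared with the ECM signature to avoid outcome leakage; the
association statistic is the regression F, with significance from
permuting the outcome across samples (default 999 permutations,
seeded; permutation counts are compared on R², which is monotone in F
at fixed dimensions). Per-stratum p-values are combined with Fisher's
method, X² = −2Σln pᵢ on 2k df, with zero p-values clamped to the
smallest positive float with a warning.

This is deliberately *ordinary* PCA plus a permutation test, not
adaptive elastic-net sparse PCA: the sparsity refinement belongs to a
specific implementation rather than to the model, and dropping it
keeps the stage deterministic, dependency-light and easy to verify.
Combination runs across all cohort×region strata at once; per-cohort
grouping is a caller-side filter on the input strata. Strata with
fewer than 10 samples are skipped in CLI association runs.

Correlation analyses (e.g. a collagen gene against an amyloid
signature eigengene) use per-stratum Pearson r with the exact t-test
p; Pearson is the default because the bulk values are already
log-scale and approximately Gaussian, and a rank correlation can be
substituted upstream by rank-transforming the matrix.

## Single cell

Counts are normalized per cell as ln(1 + c·scale/total), scale 10⁴.
Feature selection follows the VST recipe: a degree-2 polynomial of
log₁₀ variance on log₁₀ mean (raw counts) predicts a per-gene expected
SD; counts standardized against it are clipped at √n_cells and genes
are ranked by the variance of the clipped values. The polynomial
replaces a loess fit to keep the stage deterministic with no extra
dependency; on the smooth mean–variance trends of NB-simulated and
typical real data the two are interchangeable for top-n selection.

Marker tests are Wilcoxon rank-sum on normalized values with
log₂-fold-changes computed from expm1-backtransformed means
(pseudocount 1e-9) and default reporting filters of detection ≥ 0.1
and |lfc| ≥ 0.25, both configurable. ECM activity per cell type is
−log₁₀(q) of token-matched pathways ("ECM", "Extracellular",
"Matrisome", "Collagen") from each type's marker ORA, q floored at the
smallest positive float.

**Ligand–receptor scoring** is a saturating mass-action summary:
L̄ = mean normalized ligand expression over sender cells, R̄ = mean
receptor expression over receiver cells (geometric mean across
required subunits), score = L̄R̄/(Kh + L̄R̄) with half-saturation
Kh = 0.5 (exposed). This replaces trimean-plus-cofactor communication
models with the smallest model that preserves their two key
monotonicities (more ligand → higher score, bounded below 1);
significance comes from permuting cell-type labels,
p = (1 + #{score_perm ≥ score_obs})/(1 + n_perm). Cell-type labels are
required inputs throughout — no clustering or embedding is performed.

## Network propagation

On the normalized expression of one annotated cell type, the soft
adjacency is aᵢⱼ = |Pearson r|^β with β = 8 by default (the
conventional signed-absolute WGCNA power; `fit_soft_threshold`
maximizes the scale-free-fit R² over a β grid when data suggest
otherwise). Zero-variance genes are dropped with a warning. The
topological overlap is TOMᵢⱼ = (Σᵤaᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ),
unit diagonal; edges are kept if strictly above the
linear-interpolation percentile (default 90) of the *unique-pair*
(upper-triangle) weights. No metacell aggregation is performed — the
network is computed on cells directly, which is noisier per pair but
unbiased, and the β exponent plus TOM smoothing absorb most of the
pair-level noise at the module scale.

RWR iterates p ← (1−r)Wp + r·p₀ with W the column-normalized weight
matrix (isolated nodes receive a self-loop so columns stay
stochastic), p₀ uniform over the seed genes, restart r = 0.7,
L1 tolerance 1e-10, max 10⁴ iterations (non-convergence is an error;
the fixed point is verified against the dense linear solve
(I − (1−r)W)p = r·p₀ in the tests). Neighbor prioritization excludes
the seeds, sorts by steady-state probability with alphabetic ties, and
feeds ORA for the functional readout.

## Synthetic data: what it emulates and what it does not

`simulate_bulk` draws Gaussian log-scale expression per cohort×region
stratum (gene baselines shared across cohorts), shifts planted DE
genes by δ·SD in cases, draws planted gene pairs from a bivariate
Gaussian at the requested ρ (a non-PSD requested structure is an
error), and imposes the ECM-driver relation through a per-sample
latent factor loading on driver genes (unit) and ECM signature genes
(stated coefficient) with Gaussian noise. `simulate_pathways` builds a
coherent gene-set collection: twelve seeded sets carrying about half
planted-DE members, the hub glycogene in exactly its specified number
of them, decoy DE glycogenes in at most three each, background fill
with a configurable overlap fraction (0 = pairwise-disjoint
backgrounds). `simulate_single_cell` draws gamma–Poisson
(negative-binomial) counts with gene-level dispersion, multiplies the
ligand mean in sender cells and receptor mean in receiver cells by the
fold-up, applies per-condition fold-changes for marker-test truth, and
gives module genes a shared log-normal latent factor
exp(λf − λ²/2) (mean-preserving) within the module cell type.

Default study conditions: 3 cohorts × 2 regions × 30 samples/arm, 500
genes (50 glycogenes), ten DE glycogenes and thirty other DE genes at
SMD 0.8; four cell types × 200 cells, 300 genes, ligand/receptor
fold-up 5, module loading 0.8. These are desk-scale stand-ins for
cohort studies with hundreds of samples and single-cell atlases with
10⁵ cells; rates measured on them (recovery, calibration) demonstrate
that the machinery is correct, not that real data of any particular
depth would yield the same power.

Not emulated: normalization artifacts and batch effects, covariate
structure (age, sex, post-mortem interval), neuropathology grading
beyond binary case/control, doublets and ambient RNA, multi-subunit
receptor stoichiometry beyond the geometric mean, and any form of
gene-identifier aliasing. Passing tests therefore say nothing about
robustness to those phenomena.

All generators take one integer seed and are fully deterministic given
it; truth records are plain JSON.

## Numerical choices and degenerate inputs

- Ties: GSEA rankings, top-N extraction, degree ranking and neighbor
  lists all break ties lexicographically, so outputs are stable across
  runs and platforms.
- Zero pooled SD (meta), zero-variance vectors (correlation), zero
  total counts (normalization), empty universes and disjoint sets are
  errors naming the offending entity; structurally empty *results*
  (no pathway contains a DE glycogene, no token match) are warnings
  with empty outputs, since they are legitimate analysis outcomes.
- Permutation p-values are always (1 + hits)/(1 + n) and respect their
  floor of 1/(n+1); BH q-values come from the standard step-up.
- MTX input is 1-based per the MatrixMarket standard and converted
  internally; expression TSVs are genes-in-rows with a `gene` first
  column.
- Problem sizes in the acceptance script (replicate counts of 10–40
  per rate) were chosen so the whole script completes in about a
  minute while keeping binomial noise on reported rates below ~5
  percentage points.

## Known limitations

- The REML fixed-point iteration is reliable for the small strata
  counts this pipeline sees (k ≤ ~20) but is not a general-purpose
  variance-component solver.
- With k = 2 strata, any random-effects τ² estimate is unstable; the
  per-region mode or more strata are preferable when available.
- The ligand–receptor score is a screening statistic, not an estimate
  of signaling flux; Kh sets an arbitrary saturation scale and only
  rank comparisons across pairs are meaningful.
- RWR probabilities depend on the thresholding percentile through the
  degree distribution; the default 90th percentile is inherited from
  common co-expression practice, not optimized per dataset.
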