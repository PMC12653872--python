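# Methods

## The synthetic study conditions

The generator (`tmrnet.synthdata`) emulates the statistical structure a
two-cohort consensus TMR analysis relies on, not any particular dataset.

Each TF has a latent per-sample activity `a ~ N(0,1)`. Active TFs receive a
tumor-only shift (default 2.0, in units of the target noise SD). A target
regulated by TFs *t* with sign `s_t` and strength `w_t ∈ [0.6, 1]` has
log-expression `Σ_t s_t w_t a_t + N(0, σ)` with σ = 0.5 per cohort by
default. TF mRNA is a noisy readout of activity with correlation ρ = 0.95
(see "Why ρ = 0.95" below). Regulons are disjoint blocks of target genes;
defaults: 200 genes, 10 TFs, 18 targets each, 3 active TFs, 30 tumor + 30
normal samples per cohort.

The TF→TF hierarchy lives **among the active TFs**: the cascade source's
centered activity is transmitted to the other active TFs
(`a_dst = s·w·a_src + √(1−w²)·ε`), while the tumor shift stays per-TF. This
makes the downstream regulators consensus-eligible (they are themselves
shifted) and gives the source a detectable MI edge into them, without
letting coupling masquerade as activity. The source's motif consensus is
planted in the downstream TFs' promoters.

Platforms: the counts cohort exponentiates log-expression around per-gene
baselines (`N(5, 1.5)` on log2), draws sequencing depths log-normally
(mean 10⁶, CV 0.15) and counts as negative binomial with dispersion 0.1 —
typical bulk RNA-seq overdispersion. The intensity cohort adds per-gene
baselines `N(7, 1)` and reports log2 values directly. Promoter background
is i.i.d. uniform A/C/G/T so the motif-scan false-positive rate is
analytically predictable; planted sites overwrite the background (reverse
complement on "−"). Motifs are sharp 10-mers (counts 17/1/1/1 per column).

**Why ρ = 0.95.** A TF–TF mRNA correlation is attenuated by ρ twice
(readout on both sides), a TF→target correlation only once. With ρ = 0.8
the TF–TF edge is therefore the structurally weakest edge of every
(TF, TF, shared-target) triangle and DPI deletes it in every run, leaving
the dual-support TMR graph empty by construction. ρ = 0.95 puts the TF–TF
correlation above the TF→target correlations so hierarchy edges can
survive; the knob remains configurable.

What the generator does **not** emulate: batch effects, tumor purity,
probe-level artifacts, realistic library-composition biases, overlapping
regulons, or genome-scale promoter context. Passing tests therefore show
that the machinery is correct and calibrated under the stated generative
model — not that the pipeline would recover the right regulators from any
real cohort pair.

## Preprocessing and differential expression

Counts filtering uses the strict rule *fraction of samples with ≥ 10 reads
> 0.80*. TMM follows the edgeR recipe (reference = sample whose
75th-percentile count fraction is closest to the mean fraction; 30% trim on
M, 5% on A; inverse-asymptotic-variance weights; factors scaled to unit
geometric mean) and is cross-checked against Bioconductor edgeR in the test
suite to 1e-10. CPM uses effective library sizes and a log2 offset of 0.5.

Intensity filtering removes mean log2 ≤ 4, then the bottom 25% by variance
(linear-interpolation quantile, ties at the cut retained).

The moderated t fits `(d₀, s₀²)` by method of moments on the pooled
variances: `E[s²] = s₀²d₀/(d₀−2)`, `Var[s²]/E[s²]² = 2(d+d₀−2)/(d(d₀−4))`;
when the observed relative spread is no larger than the sampling
distribution's, d₀ = ∞ (complete shrinkage, z-like statistic). p-values use
the t distribution with d₀ + d df; SE = |logFC/t| feeds the downstream IVW
meta-analysis. The contract this statistic is tested against is
planted-effect recovery and the SE·t = logFC identity, not bit-parity with
any other moderated-t implementation.

## Mutual information and network consolidation

The estimator copula-transforms both vectors (rank/(n+1); ties broken by a
seeded random jitter, which matters for bootstrap resamples) and
recursively splits the unit square at cell midpoints. A cell is split while
its occupancy χ² against uniformity exceeds 7.815 (df 3, α 0.05) and it
holds ≥ 8 points, **except the first level, which splits unconditionally**:
the copula margins are fixed, so the root 2×2 table has ~1 effective df and
the χ² rule would fire with probability ≈ 0.005 under independence,
collapsing the null onto an atom at MI = 0 and making quantile calibration
impossible. With the forced first split the null is continuous and the
hold-out false-positive rate at a calibrated p = 0.01 threshold measures
0.009–0.010.

Thresholds come from ≥ 10⁴ permuted rank pairs: the empirical (1−p)
quantile when `p·n_null ≥ 10`, otherwise extrapolation from an exponential
fit (`ln survival ≈ a − b·MI`) to the top 1% of the null.

DPI evaluates every fully connected triple on the pre-pruning graph and
removes the strictly smallest edge when it falls below (1 − τ) times the
second-smallest, with τ = 0.15 by default. τ = 0 is available but brittle:
when a TF pair shares targets the three triangle edges are nearly equal,
and at n = 60 estimator noise makes the TF–TF edge the unique minimum of at
least one of its triangles in essentially every run, deleting every
TMR–TMR edge. τ = 0.15 keeps near-equilateral triangles intact while still
removing genuinely indirect edges (in an X→Y→Z latent chain the X–Z edge
trails by ~45% and is removed in ≥ 96% of seeds).

Consolidation: each bootstrap run resamples samples with replacement (run
*i* seeded `base + i`), computes all TF–gene MI, thresholds, applies DPI;
an edge is kept when a one-sided binomial test of its support against the
mean per-run edge-retention probability passes BH FDR < 0.05, with MI
averaged over supporting runs. A known specificity limit: gene pairs with
chance in-sample dependence (empirical p ≈ 3·10⁻³ at n = 60) recur across
bootstrap resamples of the *same* sample and pass the support test; at
target noise 0.5 they contribute ~6% of reported edges, at noise 0.3 ~4%.
Only more samples, not a stricter threshold, removes them.

## Regulon activity

Modes are Spearman correlations between regulator and target expression
(clipped to [−1, 1]); weights are edge MI scaled to max 1 within the
regulon; regulons below 10 targets are dropped. The signature statistic is
the moderated t (it carries precision), rank-transformed to normal
quantiles `q = Φ⁻¹(rank/(G+1))`; the raw score is the weighted mode-aligned
mean `S = Σ w m q / Σ w`.

Two permutation nulls are provided:

* **Random gene sets** (same size, same weights and modes): appropriate for
  arbitrary sets, and NES is N(0,1)-calibrated for random regulons. For
  *real* regulons it is anti-conservative — co-regulated targets share the
  TF's activity sampling noise, sign-aligned with the modes, so S is
  over-dispersed under the global null (measured: 66% of inactive TFs
  called at FDR 0.05).
* **Tumor/normal label permutation** with full signature recomputation:
  preserves the co-expression structure and restores calibration (null
  consensus rate ≤ 2%). This null is used for all consensus-level results.
  Its p-value is the empirical two-sided tail with the 1/(n_perm+1) floor,
  not the normal tail of the z-score: a random relabeling reproduces at
  most ~|2k/n₁ − 1| of the effect, so the z-scale NES saturates (≈ 2.8 at
  n = 30+30) and a normal tail would be severely conservative exactly when
  the effect is strong. NES is still reported as the z-score.

At these sample sizes the rank transform also saturates (with ~half the
genes shifted, the observed ordering resembles moderately mixed
permutations), leaving per-cohort p at 0.01–0.1 for genuinely active TFs —
consensus calls are therefore conservative at desk scale, while the
*ranking* (planted actives as the top 3 by combined FDR) is stable.

## Meta-analysis, hierarchy, enrichment

Fisher's method (χ² = −2Σ ln pᵢ, 2k df; zero p clamped to the smallest
positive double with a warning) with BH FDR < 0.05 defines consensus;
regulators scored in only one cohort are excluded; mean NES, sign
concordance and an |mean NES| > 1 flag are reported, never filtered on.
Fixed-effect IVW pools log fold-changes with wᵢ = 1/SEᵢ²; two-cohort
heterogeneity statistics are deliberately absent.

PWMs: JASPAR-text PFMs (Biopython parser), probabilities
`(count + 0.8·bg)/(colsum + 0.8)`, log2-odds against the background; one
motif per TF by source priority (manual > automatic > secondary) then
latest version. Windows are 0-based half-open `[TSS−2000, TSS+200)` on "+"
and `[TSS−200, TSS+2000)` on "−" (width 2200, transcription-oriented
sequence). Both orientations are scanned (binding is double-stranded);
`N` scores its background expectation; hits need relative score
`(raw−min)/(max−min) ≥ 0.85`. A TMR→TMR edge requires a motif hit in the
target's promoter **and** an MI edge between the pair (undirected — MI is
symmetric) in ≥ 1 cohort. Hubs: out-degree ≥ Q3 and in-degree ≤ Q1
(linear-interpolation quantiles over all nodes, inclusive bounds; both
choices configurable). With degenerate degree distributions the inclusive
bounds saturate and a warning is emitted.

ORA uses the upper-tail hypergeometric p against the cohort's post-filter
expressed-gene universe, min overlap 1. The meta-regulon report retains a
set only when per-cohort p < α in both cohorts *and* meta-FDR < α;
per-regulon reports use meta-FDR alone.

## Sensitivity harness

The sweep re-runs networks → activity → consensus per grid cell with
cell-derived seeds and reports pairwise Jaccard over consensus sets,
pairwise Spearman over shared mean-NES vectors, and per-regulator
persistence. The desk-scale default grid is 2×2 (p ∈ {10⁻², 10⁻⁴}, 20/50
bootstraps); deeper grids are a configuration away.

## Problem sizes and numerical choices

Default analyses run 200 genes × 60 samples per cohort, 50 bootstraps,
10⁵-pair null calibration, 1000 permutations — a full pipeline completes in
well under a minute and the whole test battery in a few minutes. Seeds are
threaded explicitly everywhere (bootstrap run *i* uses `base + i`; cohorts,
stages and grid cells use fixed offsets), making every output
bit-reproducible; the determinism checks compare artifacts byte-for-byte.
Degenerate inputs have defined behavior: empty filter results, zero library
sizes, all-zero variances, p = 0 inputs, regulons absent from the
signature, empty consensus sets and empty TMR graphs all either raise a
typed error or produce an explicitly empty artifact with a warning.

## Limitations

Consensus power at n = 30+30 is conservative (see the saturation notes
above); the generator's independence assumptions make network recovery
easier than in real cohorts; motif coverage is one representative motif per
TF; and the enrichment layer tests set over-representation only, not ranked
enrichment. The pipeline's defaults are study conditions for the synthetic
model, not recommendations for real data — on real cohorts the network
p-cutoff should scale with cohort size (stricter for hundreds of samples),
and regulon sizes, permutation depths and bootstrap counts should grow
accordingly.
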