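# Methods

This note documents the models, defaults, and numerical choices behind
`abxtol`, and what the synthetic benchmarks do and do not demonstrate.

## Phenotype model

Low-biomass 16S samples are dominated by background DNA. We model each fecal
sample as a mixture of bacterial 16S copies *B* and a constant pool of
organelle-derived contaminant copies *C* (host mitochondria, dietary
chloroplasts), so the expected organelle read fraction is

    f = C / (B + C).

A healthy gut (B ≈ 10⁹ copies, C ≈ 10⁵) gives f ≈ 10⁻⁴; a 3.5-order biomass
collapse gives f ≈ 0.24. The classifier calls a treated mouse a **responder**
iff its maximum f over during-treatment samples is ≥ 0.10 (inclusive
boundary), otherwise **non-responder**; untreated mice are always controls.
The maximum — rather than, say, the mean — is used because a single
excursion to 10% already evidences a collapse; per-sample calls are emitted
alongside so within-treatment phenotype switching remains visible.
Organelle membership is token-based on SILVA-132 lineages ("Mitochondria"
under Rickettsiales/Proteobacteria, "Chloroplast" under Cyanobacteria),
case-sensitive, at any rank, and f is computed on unrarefied counts because
the fraction is scale-free — rarefying first would only add noise.

## Count model

Counts for taxon *i* at depth *M* are beta-binomial with mean proportion μᵢ
and intra-class correlation φᵢ (α = μ(1−φ)/φ, β = (1−μ)(1−φ)/φ), so
Var W = M·μ(1−μ)(1+(M−1)φ) and φ = 0 is exactly binomial. Two samplers are
provided and used deliberately:

* **compositional** — latent Beta proportions per taxon, closed to sum 1,
  then one multinomial draw: every sample sums exactly to the design depth
  and marginals are approximately beta-binomial. Used wherever whole
  communities are needed (the experiment simulator, distance-based power).
* **independent** — exact beta-binomial draws per taxon at the nominal
  depth, with no closure. Used for differential-abundance benchmarking,
  because there null taxa must be *exactly* null in both groups for
  TPR/FDR bookkeeping to be meaningful.

## Synthetic study defaults

100 bacterial taxa with μ log-uniform in [0.001, 0.1], renormalized to a
bacterial mass of 0.95 with a floor at 0.001 (every taxon stays above the
abundance prefilter); φ uniform in [0.005, 0.05], a range typical of fitted
mouse 16S overdispersion; depth 10,000 reads; baseline biomass 10⁹ copies,
contaminants 10⁵; responder collapse 3.5 orders (non-responders 0). qPCR
follows Ct = 38 − 3.3·log₁₀(copies) + N(0, 0.5) — the standard ~−3.3
cycles/decade slope. Sample-level biomass additionally varies log-normally
(sd 0.3 orders of magnitude): fecal bacterial load genuinely fluctuates
between days and mice, and this term is what produces the continuous inverse
relation between the biomass proxy 1/Ct and the organelle fraction
(Spearman ρ ≈ −0.89 over during-treatment samples at the defaults) rather
than a two-cluster caricature. Absolute copy numbers and the Ct calibration
are plausibility choices — only their ratios and slopes matter downstream.

All randomness flows from one master seed through named substreams
(community, effects, per-mouse counts, qPCR), so dropping or adding a mouse
never shifts another mouse's draws, and factorial sweeps are bit-reproducible.

## Effect injection

`inject_effects` multiplies the μ of ⌊frac·n⌋ randomly chosen bacterial taxa
by a fold drawn uniform in the requested range, alternating enrichment and
depletion so the composition stays roughly balanced. For compositional use
the untouched taxa are rescaled proportionally (keeping injected folds
exact); if the injected mass alone exceeds the bacterial budget the whole
block is closed instead. For independent-sampler benchmarks,
`inject_effects_independent` applies folds with no closure at all, so
unselected taxa keep exactly their group-A law.

## Ecology statistics

Shannon diversity uses natural log. Bray–Curtis is computed on rarefied
counts (rarefaction is seeded hypergeometric subsampling; samples below the
target depth are dropped, not errors, with retention at depth ≥ target
inclusive). PCoA is classical scaling — double-center −½d², eigendecompose —
with negative eigenvalues dropped and explained variance taken over the
positive spectrum only (no Cailliez correction). PERMANOVA is the one-way
pseudo-F computed from the squared-distance sums of squares, with a seeded
label permutation null, 999 permutations by default, and the +1 convention
so the smallest attainable p is 1/(n_perm+1). ASV turnover marks a taxon
present at ≥ 1 read in the rarefied table; gained/lost/persistent fractions
are relative to final/first/first time-point richness respectively. The
presence criterion is a declared choice, not inferred from any reference.

## Differential abundance

The beta-binomial LRT is the two-group special case of beta-binomial
regression: the null shares one (μ, φ), the alternative allows
group-specific μ with a shared φ, and Λ = 2(ℓ₁ − ℓ₀) is referred to χ²₁.
Full covariate modelling of both μ and φ is deliberately out of scope — the
group contrast is the only one the pipeline tests. Fits maximize the exact
log-likelihood on (logit μ, logit φ) by Nelder–Mead from a moment start plus
two ±1 logit perturbations; a φ estimate below 10⁻⁷ is reported as 0
(binomial boundary), and non-converged fits propagate p = NaN, which the
Benjamini–Hochberg step excludes from its denominator. Taxa whose pooled
fitted μ is ≤ 0.001 are removed before testing. Mann–Whitney U reports the
rank-sum-form U of the first sample, exact by enumeration when
n₁+n₂ ≤ 12 without ties, otherwise normal with tie and continuity
corrections. Under the simulated null the LRT's type-I error sits at or
slightly below nominal (≈3.5–5% at α = 0.05).

## Power analysis

`da_power_scan` simulates two groups per replicate (independent sampler),
injects effects into 50% of taxa by default, runs the chosen test with BH at
q ≤ 0.05, and averages TPR (detected injected / all injected) and FDR
(false discoveries / max(1, discoveries)) over replicates. Default 100
replicates per cell; grids are bit-reproducible for a fixed seed.

For PERMANOVA the effect axis is R², but the *sample* R² of a two-group
PERMANOVA has null expectation (k−1)/(N−1) — at 5 samples per group that is
0.11, far above small population effects, so conditioning on a small
realized R² at small N would select exactly the noise-deflated,
non-significant replicates. Cells are therefore indexed by a **population
R²**: the bias-adjusted R² (the `RsquareAdj` form,
1 − (1−R²)(N−1)/(N−k)) of a 64-per-group calibration draw of the same
effect, which removes that null inflation; each replicate's realized R² is
recorded alongside. Which taxa receive the injection matters far more than
the fold change itself, so `permanova_power_replicates` redraws the
injection every replicate and is the recommended way to map power against
population R². For power in a specific R² window it supports screening:
candidate effects (fold changes log-uniform in 1.1–10) are drawn until the
requested number of them calibrate into the window, and only those run the
small-n experiment. Because the calibration draw is independent of the
experiment draw, screening leaves the conditional rejection rate unchanged
while putting every replicate where the estimate needs it, cutting the
Monte-Carlo standard error of in-bin power roughly fourfold at equal
experiment count.

## Problem sizes

The shipped benchmarks use 100-taxon communities at depth 10,000 with 200
replicates for the PERMANOVA claim (n = 5/group, 999 permutations), 100
replicates for FDR control (n = 32/group), and 25 replicates per cell for
the fold-change grid; test-suite property checks run on smaller communities
(30–60 taxa) and reduced designs. These sizes give Monte-Carlo standard
errors of a few percent on power/FDR estimates.

## What the synthetic benchmarks do not show

The generator reproduces the count *structure* of a real study — not any
particular mouse cohort. Real data add taxon–taxon correlations, phylogenetic
structure, day-to-day autocorrelation within mice, PCR/primer bias, and a
heavier-tailed abundance distribution than log-uniform [0.001, 0.1]. In
particular, the minimum reliably-detectable fold change depends strongly on
the μ/φ spectrum of the reference community: under these declared defaults,
twofold changes at 15 samples/group reach only ~20% BH-adjusted power
(threefold reaches ~50%), with power concentrated in the abundant,
low-dispersion taxa. Passing tests demonstrate internal statistical
correctness (calibration, FDR control, oracle agreement), not field
performance on any particular dataset. UniFrac, constrained ordination,
longitudinal mixed models, multi-factor designs, and zero-inflation
extensions are out of scope.
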