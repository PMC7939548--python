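# Methods

This note records the models implemented, the defaults that matter, what
the synthetic generators do and do not emulate, and the places where the
design was genuinely open.

## Community profiling and absolute abundance

Read counts are modeled per sample as a single multinomial draw whose
class probabilities are proportional to true cell number × informative
genome size; dividing counts by genome size therefore recovers cell-share
estimates. Absolute abundance anchors shares to the spike-in:
abs = (relab/relab_spike) × cells_added/mass. The equation is exact for
any positive spike-in share; the *A. acidiphilus* spike-in (30 µL ×
2.22 × 10⁸ cells/mL = 6.66 × 10⁶ cells) is the quantitative anchor and
*A. radiobacter* (30 µL × 9.93 × 10⁸) is carried as a QC column only.

The responsiveness model is a Gaussian linear mixed model of untransformed
absolute abundance on diet arm × sampling day with a random intercept per
animal, fitted per strain on post-switch samples (a log10 option exists
but is off by default). Pairwise arm contrasts are built from
estimated marginal means (cell means averaged over days); their p-values
come from the studentized range distribution (Tukey HSD, k = number of
arms, residual df = n − rank − 1), then BH adjustment is applied across
strains separately within each of the six comparisons. Marginal means are
expressed as ratios over the pooled pre-switch (dpg 2) mean of all mice. A
strain is responsive when ≥ 3 of 6 comparisons pass p < 0.01 (adjusted)
and some supplemented arm's ratio exceeds 1.5. Strains whose fit is
singular are flagged `testable = False`, never dropped. Numerical note:
the response is rescaled to unit mean before optimization (contrasts and
p-values are scale-invariant; raw 10¹⁰-scale responses break the
likelihood optimizer), and a Powell fallback handles rare line-search
failures.

Specific activity divides the mouse-averaged summed gain of responsive
strains between dpg 2 and the post-supplement day by the arm's dose
(default 0.5 g/day, config-exposed; requesting the zero-dose control arm
is an error by definition).

## INSeq fitness

Counts are scaled within species to the median per-sample library total
(counts-per-million is exposed as an alternative), then log2(x + 8); the
pseudocount keeps every value finite and damps low-count noise. The
fitness score subtracts the control-arm mean day-6 − day-2 contrast from
each mouse's contrast, so control mice average exactly zero per gene by
construction. Differential tests regress the per-mouse contrast on diet
arm with a shared design matrix across genes; gene variances s²_g (d_g df)
are shrunk toward a prior s²₀ (d₀ df) estimated by matching the mean and
variance of log s²_g to the scaled-F sampling model (trigamma inversion by
Newton iteration); the moderated t has d₀ + d_g df. With fewer than 10
genes the prior is dropped (d₀ = 0), which reduces exactly to the
ordinary t. Mice lacking either sampling day are excluded with a warning;
the limma-style design is unpaired arm-vs-control (pairing was not
derivable from the study description; a paired variant would need
per-mouse baselines the contrast already consumes).

## Metaproteomics

Only peptides mapping to a single protein contribute; protein abundance is
their sum, log2-transformed. Missingness is treated as purely
detection-limit-driven: per sample, missing values are drawn from
N(mean − 2.2·sd, (0.3·sd)²) of that sample's observed values, restricted
to proteins detected in more than three mice of at least one treatment
group (read strictly: ≥ 4, so groups of ≤ 3 mice contribute no proteins
to the reference distribution). Samples with fewer than 10 filtered
observed proteins raise an error rather than imputing from an
unestimable distribution. Observed values are never overwritten and draws
are seeded.

Cyclic loess iterates over sample pairs (span 0.7, 3 cycles,
limma-compatible defaults): the M = x_a − x_b vs A trend is fitted by
lowess and each sample moves half the fitted trend toward the other, so
the pairwise sum — and hence the grand mean — is preserved exactly.
Species matrices with ≤ 100 proteins are passed through untouched (too few
points to estimate the trend).

The PUL set statistic is Z = (mean member lfc − mean all lfc) /
(sd all lfc / √n_members), two-sided normal p, BH across PULs within
species × arm. The description "unpaired one-sample Z-test" admits two
readings; the member-mean-vs-species-background version is the default and
a vs-zero variant is exposed (`variant="zero"`). The background version is
invariant to adding a constant to all fold changes, which is the behavior
a normalization-robust set test should have.

## Quadrant integration

Only genes with both measurements enter. The "ellipse of the
interquartile range" is read as: centered at the medians, semi-axes
IQR/2 per axis (so the full width equals the IQR; a full-IQR-semi-axis
variant is config-exposed via `semi_axis_iqr_factor`). Boundary points
count as inside (excluded). Zero IQR on an axis makes the ellipse
degenerate: all points are treated as outside, with a warning. The per-PUL
2×2 table (member × lower-right quadrant, among outside-ellipse genes)
uses Pearson chi-square without continuity correction — counts are
moderate and the uncorrected statistic matches the closed form
n(ad−bc)²/(r₁r₂c₁c₂) exactly. Empty margins yield statistic 0, p 1,
flagged. Quadrant boundaries sit at x = 0, y = 0 (fold-change and
fitness-score sign conventions), configurable.

## MFAB quantification

Bead counting: beads = sample events × (counting beads added / counting
bead events). Internal-standard correction scales each vial's areas by
(reference IS area / vial IS area) with the *median* IS response of the
series as the reference: a single drifted vial is restored exactly, and
quantification through a curve corrected the same way is invariant to a
global multiplicative drift shared by analyte and IS areas. Standard
curves are ordinary least squares of corrected area on nominal mass over
≥ 3 twofold dilution points with a free intercept (forcing through the
origin was considered and not adopted; the free intercept lets the fit
absorb derivatization background at the cost of poorer extrapolation
below the lowest standard — masses quantified below zero are clipped and
flagged). Percent remaining divides recovered per-1000-bead mass by the
same-batch input-bead mass; values over 100% are kept but flagged.

Molecules per bead = mass × N_A / Mn with Mn = 1300 Da for maltodextrin;
the released-monosaccharide mass stands in for polymer mass with no
anhydro-residue correction — this is the convention that makes the
printed example arithmetic (4.43 ng → 2.05 × 10⁹ molecules → 9.4% of
2.18 × 10¹⁰ amines) self-consistent.

Mann–Whitney U: for combined n ≤ 16 the two-sided p is exact by full
enumeration of all C(n, n₁) group assignments, P(U′ ≤ U_low) +
P(U′ ≥ n₁n₂ − U_low), which handles ties exactly; larger samples use the
tie-corrected normal approximation without continuity correction. The
synergy model is OLS percent_remaining ~ diet + bead + diet:bead with the
unsupplemented diet as reference; the interaction coefficient estimates
the departure from additivity (negative = supplement-enhanced degradation
of that bead type).

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume —
multinomial sequencing at ≥ 10⁶ reads/sample over cell × genome-size
probabilities, lognormal mouse-level biological variation, planted
multiplicative diet effects, left-censoring at a log2 detection limit,
and multiplicative GC–MS instrument noise with shared vial drift. Default
conditions: 4 diet arms × 4 mice, days 2/6/10, total load 10¹¹ cells/g,
0.05 g feces/sample, 3-fold planted responses on four Bacteroides,
−2 log2 fitness effects and +3 log2 protein effects on one 8-gene PUL,
bead loads of 10 ng/1000 beads for glycan beads and 2 ng/1000 (the bottom
of the observed conjugation range) for acetylated controls, 5%
multiplicative GC–MS noise. INSeq counts are expected-scale values with
multiplicative noise rather than integer reads, so the noise-0 limit is
deterministic and planted effects propagate in closed form.

Not emulated: compositional interactions between strains, PCR/GC bias,
batch effects, peptide-level identification error, chromatographic peak
overlap, bead loss or FACS purity, and any real taxonomic composition.
Passing recovery tests therefore demonstrates the estimators are correct
and calibrated under their own assumptions — not that those assumptions
hold in real fecal samples.

## Problem sizes and tolerances

The packaged test and acceptance workloads use 200 genes, 300 proteins,
4–5 mice/arm, 20 GC–MS replicates per degradation level, and 200-replicate
null suites — sizes at which every planted effect is comfortably
identifiable while the full suite runs in about a minute. Key tolerances:
relative abundances sum to 1 within 1e-9; planted −2 fitness effects are
recovered within ±0.3 at σ = 0.2; degradation truths within ±3 percentage
points at 5% noise (mean of 20 replicates — the sampling error of that
mean is ~1.5–2 points, so occasional seeds approach the bound);
imputation draws reproduce their target mean/sd within ±0.02 at 10⁴
draws; loess removes a planted constant offset to mean |M| < 0.01.

## Known limitations

Responsiveness p-values use a residual-df approximation (n − rank − 1)
rather than Satterthwaite/Kenward–Roger df; with the small balanced
designs used here the difference is immaterial, but very unbalanced
designs would warrant proper df. The quadrant chi-square treats genes as
independent; genes within an operon are not. The exact Mann–Whitney
enumerates up to C(16,8) = 12,870 assignments, which is instant, but the
combined-n threshold is a convention, not a statistical boundary.
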