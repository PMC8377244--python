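# Methods

## Scope and data model

The package analyses a chromatin-accessibility time course: a peak × sample
matrix of fragment counts over T timepoints with replicates, a matched
gene × timepoint expression matrix, per-timepoint transposase-insertion
tracks, a motif library (JASPAR PFM), and a per-timepoint cell-phenotype
fraction. Coordinates are 0-based half-open throughout. All analysis
operates on these containers; readers/writers (`chromdyn.io`) pin one
dialect per format (BED, TSV, FASTA, JASPAR, bedGraph, edge-list/GraphML).

## Differential accessibility

**Normalization.** Median-of-ratios size factors: the reference for each
peak is its geometric mean across samples (peaks containing any zero are
excluded from the reference set); a sample's factor is the median of its
count/reference ratios. This estimator assumes most peaks are not
differential; it is biased when changing peaks form a majority (see the
generator design below). Normalized signal is log2(count/factor + 1).

**Pairwise testing.** For each pair of timepoint categories, a per-peak
Wald test under a negative-binomial model with Var = μ + αμ²: the log2
fold change of normalized group means (pseudocount 1), a pooled
method-of-moments dispersion α̂ = mean over groups of (s² − m̄)/m̄²
(floored at 1e-8), a delta-method standard error of the log2 fold change,
and a two-sided normal p-value with Benjamini–Hochberg FDR within each
comparison. No information is shared across peaks. With two replicates per
group the moment dispersion is noisy and the normal tail is only
approximate; calibration is near-uniform from several replicates per group
upward. At the study's effect sizes (8–64-fold) selection does not depend
on calibrated tails: the |log2 FC| > 5 and FDR gates dominate.

**Intrinsic score.** Per peak, on normalized signal: *between* = variance
across timepoints of the replicate means, *within* = mean across
timepoints of the replicate variance, score = log2((between + ε)/(within +
ε)) with ε = 0.01 guarding zero variances; the score is standardized over
all peaks and thresholded at z > 1. This favours elements reproducibly
variable across timepoints — under an i.i.d. null, ~16 % of peaks exceed
z = 1, matching the normal upper tail.

**Selection.** A peak is differential when it passes all three pairwise
thresholds (P < 0.01, |log2 FC| > 5, FDR < 0.01) in at least one of the
T·(T−1)/2 comparisons, combined with the intrinsic criterion by union
(default; "intersection" available). Both directions of fold change count:
programs both open and close over differentiation.

## Clustering and stages

Differential peaks are row-centered and unit-scaled, clustered by average
linkage on 1 − Pearson correlation; k is chosen by maximum mean silhouette
over k = 2..8. Samples are embedded by PCA of the column vectors
(row-centered) and partitioned by a deterministic PAM k-medoids (greedy
BUILD then full swap search) on the leading two PCs, k again by
silhouette. Stage-specific elements use linear-scale normalized stage
means: an element is stage-specific when its mean in one stage exceeds
1.5× the maximum mean of every other stage; "conservative" elements reach
a minimum stage-mean signal (default: 25th percentile of all
element-stage means) in every stage.

## Motifs, enrichment, footprints

PFM counts become probabilities with a pseudocount of 0.8 split across the
four bases. Scanning scores every window on both strands with
log2((p + 1e-3)/(0.25 + 1e-3)); a window is a hit at ≥ 0.8 of the motif's
maximum score (configurable); windows containing N are skipped; hits are
reported in forward coordinates. Enrichment of a peak set against the peak
universe is the hypergeometric tail on peaks-with-≥1-hit counts, tested in
the direction of the observed deviation, with signed score
±(−log10 p) (positive = enriched, negative = depleted; p floored at
1e-300) and BH FDR across motifs. The module map evaluates each
stage-specific peak set against the universe and orders motif rows by
hierarchical clustering.

Footprints stack per-base insertion counts over all occurrences of a motif
(minus-strand sites reversed), average into a profile of length 2W + L
(W = 100), and quantify occupancy as depth = mean(flank) − mean(core),
flank being the outermost 20 positions per side and core the central L.
Dividing by the flank mean yields a normalized depth comparable across
timepoints with different global accessibility; under the generator's
model its expectation is the protection fraction × TF activity. Tn5
sequence bias and read-shift correction are upstream concerns; tracks are
assumed insertion-resolved.

## Regulatory networks

Promoters are the 2,000 bp upstream of the TSS (strand-aware, clipped at
chromosome edges). Candidate TFs are those whose motif is enriched
(p < 0.05) in an opening/closing peak program and whose gene is expressed
above a cutoff (default: the median of all gene-timepoint values) at ≥ 1
timepoint. Edges A → B require ≥ 1 hit of A's motif in B's promoter,
scanned with the same PWM settings as peaks; direction is always
promoter-defined. Edge sign is the Pearson correlation of the two
expression profiles over the full time course: positive above 0.4,
negative below −0.4, otherwise none — the interval [−0.4, 0.4] is closed,
so a correlation of exactly 0.4 is "none". Each timepoint's network keeps,
by default, only the TFs specifically expressed at that timepoint
(FC > 1.5 against every other timepoint); a non-strict mode adds every
candidate expressed then. Self-loops (a TF's motif in its own promoter)
are kept and flagged. One motif represents one TF; family members sharing
a motif must be expanded explicitly in the TF → gene mapping.

## Chronology

Each signal class (accessibility of the opening program, expression of the
matched gene signature, phenotype fraction) is summarized as a min-max
scaled mean trajectory on the day grid. The onset is the least-squares
single change-point of a two-constant-segment model over all splits; the
grid onset is the first day of the second segment (ties toward the earlier
day). Because the grid is irregular (gaps of 2–7 days), a sub-grid
refinement interpolates the split SSE parabolically over the boundary
midpoints between days, returning a fractional day (clipped to the grid
range; at a boundary split the grid day is returned). Lags are onset
differences in days. On an 8-point grid a planted 2-day lag is recovered
only to grid resolution (≈ 1.5 days at the default design).

## Synthetic study design

The generator emulates the study: 8 timepoints (days 7, 14, 19, 21, 24,
26, 28, 35) × 2 replicates; 640 differential peaks split 158/446/36 into
three programs plus 160 stable and 1,600 flat background peaks; 30 TFs
(10 decoys) with sharp 8–12 bp motifs; 40 planted regulatory edges; a
2-day expression lag; an NK-fraction logistic rising after day 21.

* **Programs.** Opening (cluster II): increasing logistic with midpoint at
  the planted onset (day 14, steepness 1.2 d). Closing (cluster I):
  decreasing logistic (midpoint 16.5 d, steepness 1.2 d) — the early
  program hands over to the late one during the second week. Transient
  (cluster III): flat low mean times a day-effect of amplitude 2 (log2)
  that is 0.8-coherent across its peaks — a shared transient bump
  (orthogonalized against the opening/closing shapes so the three programs
  are mutually distinguishable by correlation) plus peak-specific day
  variation. This is accessibility that varies between timepoints but not
  between replicates: exactly what the intrinsic filter selects.
  Logistic shapes are min-max rescaled on the grid so each peak's realized
  fold equals its drawn fold (log-uniform 8–64×).
* **Counts.** Negative binomial (Var = μ + αμ², α = 0.05) at mean
  = size factor × μ(t + jitter), size factors log-uniform in [0.7, 1.4],
  and a per-sample pseudotime jitter (sd 0.5 d) modelling the asynchrony of
  replicate differentiation cultures. The flat background majority mirrors
  real peak universes, where differential peaks are a few percent of all
  accessible sites, and is what makes median-of-ratios normalization
  identifiable.
* **Sequences and motifs.** Each planted TF's consensus is embedded (both
  strands) in ~50 % of its program's peaks, ≥ 130 bp from peak edges so
  footprint windows stay inside covered signal; each planted edge embeds
  the regulator's consensus in the target's promoter. Decoy motifs are
  never embedded. Planted edges favour same-day TF pairs (60 %) so strict
  per-day networks are non-empty.
* **Expression.** log2-scale: planted TFs are Gaussian bumps (height 3,
  width 2 d) at their assigned day; the NK signature is a logistic with
  midpoint onset + lag (day 16); decoys are low and flat; Gaussian noise
  sd 0.2 (the microarray noise model, chosen for lack of a stated one).
* **Insertion tracks.** Per-base Poisson with rate proportional to the
  peak's accessibility, reduced by factor (1 − 0.4 × activity(t)) inside
  embedded motif cores, activity following the TF's early/late schedule.
* **Truth.** Cluster labels, onset days, lag, per-sample size factors and
  jitter, TF days, decoys, and planted edges (with the PCC class computed
  from the noise-free profiles) are stored for recovery testing.

**What the generator does not emulate:** read-level artifacts (duplicates,
mitochondrial reads, fragment-size structure), Tn5 sequence bias, GC
effects, overlapping/variable-width peaks, motif families with similar
PWMs, trans effects on expression, and biological cell-mixture
heterogeneity beyond the single pseudotime axis. Passing recoveries
therefore demonstrate the correctness of the statistical machinery on data
satisfying its assumptions, not robustness to these real-data artifacts.

## Numerical and design choices

* Dispersion floor 1e-8; intrinsic ε = 0.01; log-odds pseudocount 1e-3;
  enrichment p floor 1e-300 keeps signed scores finite.
* Correlation distance treats zero-variance rows as correlation 0;
  distances are symmetrized and clipped at 0.
* Hierarchical clustering ties break by input order (scipy's convention);
  cluster labels are renumbered contiguously by first appearance.
* k-medoids is exhaustive-swap PAM: deterministic, no random restarts;
  suitable for the ≤ dozens of samples it is applied to.
* Change-point ties break toward the earlier day; the parabolic refinement
  uses boundary midpoints as abscissae, which on irregular grids lets a
  midpoint-on-grid-day logistic be recovered at that day.
* The silhouette decision between 3 and 4 sample groups is intrinsically
  marginal on this design (a boundary day occasionally separates); the
  modal k over seeds is the stable quantity.
* Pipeline manifests contain no timestamps; identical configs and seeds
  give byte-identical manifests and GraphML outputs.

## Known limitations

* The NB Wald test with n = 2 per group is anticonservative in the tails;
  it is adequate at the planted effect sizes but should not be used for
  marginal calls on real data without more replicates or shrinkage.
* The intrinsic z is standardized on the empirical score distribution, so
  its meaning shifts with the differential fraction of the universe.
* Hit calling at 0.8 × max score is not p-value calibrated across motifs
  of different information content.
* Promoter-hit edges are necessary-condition edges: they ignore chromatin
  state at the promoter unless intersected with accessible peaks, and
  cannot distinguish family members with near-identical motifs.
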