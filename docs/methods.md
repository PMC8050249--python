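# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish about behavior on real data.

## Coordinate conventions

All intervals are 0-based half-open (BED dialect), matching the formats
the pipeline reads and writes. The TSS of a minus-strand gene is
`end − 1`. A "TSS ± k" window is realized as `[tss − k, tss + k + 1)`,
so exactly k bases flank the TSS on each side under the half-open
convention. Two peaks merge only on ≥1 bp overlap: `[10,20)` and
`[20,30)` touch but do not merge. Nearest-gene ties (equal gap) resolve
to the leftmost gene start, then the lexicographically smallest gene id,
and the tie is flagged in the result; this replaces the unspecified tie
behavior of the usual closest-feature tools with a deterministic rule.
Chromosome tails shorter than one window are not tiled: the
effective-size formula and the coverage statistic presume full-width
windows.

## Signal matrix

The normalization ladder is fixed: raw → input-subtracted →
scaled-to-10M → log2 → quantile-normalized, and the `SignalMatrix`
object refuses stage regressions. Choices the source pipeline leaves
open:

- **Pseudocount c = 1** (configurable) on the input-subtracted, scaled
  counts before log2. A separate offset of 0.1 applies to RPKM values in
  the expression clustering path, where it is part of the stated
  procedure.
- **Negative subtracted values clamp to 0**: occupancy is enrichment
  over input; a peak with less IP than input signal carries no evidence
  of occupancy.
- **Quantile normalization** maps every column onto the mean of sorted
  columns; the map is idempotent and makes sorted columns identical to
  machine precision (asserted in tests).
- **Hierarchical clustering** defaults to average linkage on
  1 − Pearson distance; both linkage and metric are arguments, since the
  upstream analysis names only a plotting package, not a linkage.
  Columns are canonicalized (sorted) before linkage so the tree is
  invariant to sample order.

Browser-style tracks use 200-bp windows with 20-bp steps, reads per
million; a read counts in every window it overlaps. TSS profiles use
100 bins of 40 bp over TSS ± 2 kb, mirror minus-strand genes so bins
run 5′→3′, and average reads-per-million over the gene set; the profile
is linear in the track.

## Differential testing

The NB is parameterized mean–dispersion, `var = μ + φμ²`, the
convention of the count-based differential-expression literature the
analysis builds on; φ = 0 is the Poisson limit.

- **TMM factors**: reference column = sample whose library-scaled 75th
  percentile is closest to the mean; 30% two-sided trim on M-values, 5%
  on A-values; precision weights from the delta-method binomial
  variance; factors rescaled to geometric mean 1. The weight floor
  (1e−12) keeps degenerate features (count = library) finite.
- **Library-size equalization**: counts are mapped to a common
  (geometric-mean) effective library size by a quantile-to-quantile NB
  map averaging a normal and a gamma continuous approximation, with
  per-group feature proportions as means. This is the standard
  construction for small-sample exact NB testing; it is re-applied once
  with the estimated dispersion (two passes total, which is where the
  estimate stabilizes at these sizes).
- **Common dispersion**: maximizes the conditional log-likelihood of
  within-group counts given group totals (free of the mean under equal
  library sizes), summed over features and groups, over
  δ = φ/(1 + φ) ∈ [1e−6, 0.95] by bounded scalar minimization
  (xatol 1e−6). The lower bound is accepted as φ = 0 when it is at
  least as likely.
- **Exact test**: group sums of pseudocounts are rounded to integers;
  the two-sided p sums, over the conditional support {0..s}, the
  probabilities of splits no more likely than the observed one
  (tolerance 1 + 1e−10 on the log scale), normalized by the total.
  Enumeration is exact — no large-count approximation — which is
  affordable at desk scale (totals ≲ 10⁵).
- **Fold-changes** come from effective-library CPM group means with a
  0.5 pseudocount, so zero-count groups give finite log2FC.
- **Calls** require BH FDR ≤ 0.05 AND fold-change ≥ 3 (expression) or
  ≥ 2 (occupancy); features with zero counts in every library are
  excluded before testing. Distinct RNA-seq protocols (total RNA vs
  mRNA cohorts) are never pooled in one test; the run config carries a
  single cohort label.

## Linkage enrichment

Strict direction matching: a peak up in tumor counts only when its
nearest gene is up in tumor. Peaks with no gene on their chromosome are
excluded from numerator and denominator of their stratum. Enrichment is
undefined (reported as missing, never infinite) when a required
denominator is zero. The chi-square is Pearson's on the 2×2 table with
1 df and no continuity correction (expected counts in realistic strata
are large; a correction flag exists). Eight strata are always emitted:
2 marks × {proximal, distal} × {up in tumor, up in normal}.

## CNA inference

- "Normalized to the average of the median coverage of the normals" is
  read as a **scalar**: per-normal medians across retained windows,
  averaged. The alternative per-window normalization to the normal-panel
  mean is available behind `mode="per_window"`; the scalar reading
  matches the plain grammar of the procedure this reimplements.
- Z-scores standardize each tumor sample's log2 ratios across its own
  retained windows (mean 0, sd 1 by construction, population sd). Using
  the pooled normal variability instead is a deliberate non-default:
  the per-sample reading attaches the computation to the sample.
- Windows are excluded when fully masked by peaks/blacklist or when any
  sample has fewer than `min_reads` (default 100) read pairs, keeping
  one common retained set across samples.
- Thresholds are inclusive: gain ⇔ z ≥ 3, loss ⇔ z ≤ −3 (z = 2 is the
  documented relaxed alternative).
- Because 100-kb windows slide by 10 kb, adjacent calls are correlated;
  `merge_call_segments` collapses runs of overlapping same-state calls
  for segment-level reporting. Recovery metrics define truth windows as
  those **fully inside** an injected segment (sensitivity denominator),
  and do not count calls on partially overlapping windows as false
  positives — a partially covered window genuinely carries intermediate
  copy signal.

## Synthetic cohort

The generator emulates the study design the pipeline assumes: 3 normal
vs 4 tumor samples (the cohort on which differential and linkage
analyses run), a 2 × 10 Mb genome (so ~2,000 sliding 100-kb windows
exercise the CNA machinery at desk scale), 800 genes (~90%
protein-coding), ~600 peaks per mark with mark-appropriate geometry
(80% of H3K4me3 peaks within TSS ± 2 kb; 80% of H3K27ac peaks outside
TSS ± 2.5 kb), NB counts at dispersion 0.1 with library sizes 8–12 M,
mean effects of 8-fold (|log2FC| = 3) for the 20% differential peaks
and 15% DE genes, and coupling 0.6: each differential peak's nearest
gene is forced, with that probability, into the DE set with concordant
direction. Consensus peaks are kept ≥500 bp apart so per-sample ±100 bp
boundary jitter cannot bridge neighbors; per-sample calls detect each
peak with probability 0.9.

Copy-number segments multiply IP and input means identically (input
coverage approximates copy number, and occupancy gains are then partly
CN-driven). The default truth places one 200-kb gain (ratio 2) and one
200-kb loss (ratio 0.5) in **every** tumor sample — CNAs are a hallmark
of the emulated disease, and a per-sample z-score is only calibrated
when its own genome is mostly neutral with focal events. Pooled-input
window counts are deep (mean 2,000 pairs/window) with small dispersion
(0.002) and a mild shared regional propensity (lognormal sd 0.03),
reflecting pooled multi-library input averaged over 100-kb windows.
Partial window overlap scales the mean by the overlap fraction.

What the generator does **not** model: read-level artifacts (FASTQ,
duplicates, fragment-size effects), mappability structure beyond a
smooth propensity, gene-length biases within RPKM, correlated
peak–peak signal, subclonal or allele-specific copy number, and
purity/ploidy. Passing tests therefore establish the correctness and
calibration of the statistics under the assumed NB/group-shift model,
not robustness to alignment- or library-level artifacts of real data.

## Problem sizes in tests

The acceptance suite runs the dispersion/uniformity checks at 2,000
features, FDR control pooled over 10 generator seeds, CNA recovery over
20 seeds, and linkage coupling over 20 seeds per coupling level; these
sizes give stable Monte-Carlo estimates for the thresholds asserted
(e.g. pooled FDR ≤ 1.5× nominal, window-level sensitivity and precision
≥ 0.9) while keeping the default test run in well under a minute per
property. Enrichment at coupling 0 is estimated by pooling stratum
counts across seeds before forming the ratio — the unbiased Monte-Carlo
estimate of a ratio of proportions — because per-seed ratios at desk-
scale counts are small-sample biased upward.

## Known limitations

- The exact test's integer rounding of pseudocount sums makes p-values
  slightly discrete at very low totals; the null KS statistic stays
  below 0.05 at the simulated depths but would grow for very shallow
  libraries.
- `nearest_gene` and `classify_region` are linear scans per peak —
  appropriate at desk scale, quadratic in genome-scale use.
- The CNA caller reports windows and merged runs, not model-based
  segment boundaries; no CBS/HMM segmentation is attempted.
- Trailing sub-width chromosome remainders are excluded from windowing,
  so features near chromosome ends may be assigned to a window whose
  midpoint is tens of kb away.
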