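# Methods

## Pipeline and model

The synoptic stage is a fixed sequence: parse spot files → per-spot
intensity under the selected mode → median aggregation of replicate
spots → peptide × sample matrix → cross-sample normalization →
per-peptide Mann-Whitney U test → Benjamini-Hochberg adjustment →
rank-cutoff subsets → plots. The targeted stage is stateless: it reads
only the synoptic results CSV plus a targeting file, so a targeted run
can be repeated or shared without the raw scanner exports.

### Intensity modes

With spot foreground `f_l`, local background `b_l`, and array-median
background `b_m` (all RFU):

* `foreground` — `f_l`;
* `background_subtract` — `f_l − b_l`, removing local optical bias;
* `background_scale` — `f_l·b_m/b_l − b_m`, additionally dividing both
  terms by the local-to-global background ratio, which cancels smooth
  spatial sensitivity gradients. It equals subtraction wherever
  `b_l = b_m` (to one ulp of the foreground scale — the division rounds
  at machine precision, so tests quantify the "zero difference" as
  `< 1e-9` rather than exact zero).

Local backgrounds are floored at `max(1 RFU, 1e-6·b_m)` in scale mode so
zero-background spots cannot blow up the ratio; 1 RFU is far below any
real scanner background, so the floor is inert on real data. Negative
intensities are kept: clipping would bias quantile normalization, and
the downstream rank test ignores sign anyway.

### Replicate aggregation

Spots are grouped by peptide sequence (fallback: spot ID with a
configurable trailing `.<n>` replicate suffix stripped) and collapsed by
median, which tolerates one bad spot in a triplicate. Replicate count
and coefficient of variation are retained for QC. Whether one should
aggregate replicates or test every spot independently is genuinely open
for this assay; both are exposed (`aggregate=False` keeps spots), and
the default is aggregation because the test's exchangeability unit is
the sample, not the spot.

### Normalization

* **Quantile** assumes all arrays share one reactivity distribution.
  Each sample's sorted values are replaced by the row means of the
  column-sorted matrix. Tied input values receive the mean of the
  reference values at the ranks they span, which makes the result
  independent of tie-breaking order; as a consequence tied inputs map
  to one output value, so the identical-multiset postcondition holds
  exactly on tie-free columns.
* **VSN** assumes each array measures an affine transform of a common
  ground truth with variance growing with the mean. Each sample gets
  `h_i(x) = arsinh((x − a_i)/b_i)`; parameters are fitted by profile
  maximum likelihood under `h_i(x_ij) ~ N(μ_j, σ²)` (μ and σ profiled
  out analytically), with a least-trimmed-squares outer loop: fit, drop
  the `1 − trim` fraction of peptides with the largest across-sample
  residual sums, refit (default `trim = 0.9`, 3 rounds or until the
  retained set stabilizes). Trimming is what makes the fit robust to
  the minority of truly differential peptides — the reason VSN requires
  that most peptides are not differential. Optimization is L-BFGS with
  analytic gradients on `(a_i, log b_i)`; initialization from the 2nd
  percentile (offset) and IQR/1.349 (scale); an iteration-limit stop
  raises an error suggesting quantile normalization instead.
* **None** is the identity with provenance updated.

A note on identifiability, which shaped the recovery test: under data
generated as `x = a_i + b_i·(μ_j·e^η) + ε` with a constant additive
noise SD, the variance-stabilizing scale is `σ_ε/σ_η` for *every*
sample — not `b_i` — and with `ε = 0` the overall scale is pure gauge.
Per-sample calibrations are therefore only recoverable when the data
come from the arsinh-affine model itself; the generator's
`simulate_affine_matrix` draws `x = a_i + b_i·sinh(μ_j + η)` so that
`(a_i, b_i)` are exactly the maximum-likelihood targets. Recovery on
2,000 peptides is then within 10% relative (observed ≤ 8% on scales,
≤ 0.1% on offsets).

### Differential testing

Two-sided Mann-Whitney U per peptide; exact permutation null when the
combined sample count is ≤ 12 and values are tie-free (enumeration is
cheap there), tie- and continuity-corrected normal approximation
otherwise — realistic cohort sizes (10–22 per arm) always use the
approximation. Completely constant data yields p = 1 with a warning,
and group sizes below 3 warn about negligible power. BH adjustment is a
single step-up pass over all peptides. Cohort variances are unbiased
(n − 1); singleton cohorts report variance 0.

p-value calibration is verified on null simulations. Because the U
statistic is discrete at 10+10 samples, uniformity is checked at the
attainable p-value atoms (`|ecdf(atom) − atom|`) rather than with a
plain KS statistic, whose value has a deterministic floor near the
largest atom gap (~0.06 at these sizes). One real, documented artifact:
quantile normalization occasionally assigns two samples the same value
for a peptide (equal within-sample ranks), and the tie-corrected test
then becomes mildly *conservative* at mid-range p (deviations up to
~−0.065 around p ≈ 0.6–1.0). Calibration in the decision-relevant tail
(p ≤ 0.25, the largest FDR level) is unaffected (observed ≤ 0.023), and
deviations are never anticonservative; VSN-normalized data show full
range calibration within 0.014.

### Rank-cutoff subsets

For cutoff k ∈ {20, 50, 100}, direction ∈ {up, down, any}, FDR ∈
{0.01, 0.05, 0.10, 0.25}, three lists are produced: the k lowest
adjusted p-values, the k most extreme effects, and the k most extreme
effects among peptides passing the FDR. Under up/down, the p-ranked
list is restricted to peptides whose delta RFU has the matching sign —
an "up" list containing down-regulated peptides would be misleading;
the unfiltered behavior remains available via `any`. Ties are broken
deterministically: stable sort with |delta RFU| descending, then spot
ID lexicographically. Short lists truncate silently.

### Clustering

Samples are points whose coordinates are peptide intensities.
Dendrograms use the FDR-passing subset (`by_both`, configurable), so
their dimensionality equals the rank cutoff; agglomerative and k-means
clustering for the PCA plots use all peptides with no subset
restriction. UPGMA is scipy's average-linkage on Euclidean distances,
cut at the root into two clusters; scipy's deterministic tie ordering
is accepted as-is (the contract is platform-stable dendrograms, not a
particular tie rule). k-means is Lloyd's with k = 2 and 10 seeded
random restarts keeping the best inertia; results are reproducible from
the recorded seed. PCA is mean-centered; a rank-1 point cloud
zero-fills the second axis. Quality indices use the textbook Euclidean
definitions via scikit-learn; partitions for which an index is
undefined (coincident centroids for Davies-Bouldin, one-cluster
labelings) report NaN instead of raising.

### Visualizations

Every plot is a plain plot-data structure (the test surface, exportable
as JSON) plus a thin matplotlib renderer that never alters values.
Boxplots use Tukey whiskers (1.5·IQR) and linear-interpolation
quartiles; control samples render red, treatment white. Line graphs
put cohort mean ± 1 SD bands over peptide start positions (peptides,
not residues, are the unit of measurement) with a third effect-size
panel equal to the synoptic delta RFU. Strip/swarm dots keep one fixed
global sample order (control block then treatment block) so position n
in every strip is the same sample; jitter is horizontal-only and
seeded. Epitope maps stack overlapping peptides into lanes by greedy
first-fit in start order and color by delta RFU on a diverging scale
symmetric about zero. Intensity heat maps use a sequential colormap;
effect coloring uses a diverging one. SVG output is byte-deterministic
(fixed hash salt, no timestamps).

## Synthetic data

The generator emulates the tiling immunoarray design: a random protein
tiled by 15-mers overlapping by 11 residues (a terminal window is
pinned to the C-terminus when the regular grid stops short), printed in
triplicate on a rectangular grid with replicates in different rows.
Spot foreground is `bias·(signal·e^η + bg) + ε` with per-peptide
baseline reactivity lognormal across peptides (sdlog 0.5 around
1,000 RFU), multiplicative noise η (sd 0.1), additive floor ε (sd
100 RFU), background 150 RFU with a top-to-bottom gradient (default
30%) entering foreground and background alike — which is exactly the
artifact background scaling removes. Differential peptides (default 5%)
are shifted upward in the treatment cohort by `effect_size` (default 4)
times their spot-level noise SD. Optional per-sample affine distortions
exercise VSN. Reference test conditions are 2,000 peptides and 10+10
samples; the real commercial arrays are about twice as large (4,416
peptides) with comparable cohorts, so runtimes scale directly.

Not emulated: antibody biophysics and cross-reactivity structure
(signal is sequence-agnostic), block/print-tip structure and control
spots, saturation and scanner quantization, and correlated noise
between overlapping peptides. Passing tests therefore demonstrate the
statistical machinery under a clean version of the assay's noise
structure, not robustness to every real-array pathology.

## Numerical choices

* Synoptic CSV floats are written with 12 significant digits; write →
  read round trips are lossless well past 1e-9 relative. Per-sample
  columns carry `control:`/`treatment:` prefixes so the stateless
  targeted stage can reconstruct cohort membership from the file alone.
* Targeting coordinates are 1-based inclusive; contiguity requires each
  record's start to be at most one past the running covered end, and
  violations name the exact gap.
* The exact/asymptotic U-test switch is at combined n = 12.
* VSN: `max_iter 500`, `ftol 1e-9`, trim 0.9, 3 LTS rounds.
* k-means: 10 restarts; degenerate inputs (< 2 distinct points) return
  a single cluster with a warning rather than failing.

## Limitations

Two cohorts only; no paired designs, no permutation FDR, no multi-channel
(532/635) GPR support, no `.gal`/image parsing, and no spatial loess
correction beyond the global-median background scaling. The
mid-range conservatism of the U test after quantile normalization is
inherent to rank ties created by that normalization; where exact
mid-range calibration matters, use VSN or no normalization.
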