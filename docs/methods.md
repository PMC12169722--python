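# Methods

This note documents the models, parameter choices and numerical decisions
behind `aavtropism`, and what the synthetic-data tests do and do not show
about real data.

## The measurement model

The imaging pipeline treats a slice section as a four-channel 2-D image
(DAPI, a 633-nm marker, 488-nm GFP, a 546-nm marker) with a known pixel
size in μm. The unit of measurement is the segmented DAPI nucleus: every
downstream call operates on the vector of per-channel mean intensities over
each nucleus mask. Using the mask itself (rather than a dilated or
circumscribed region) is a recorded choice; an optional dilation radius
could be added for sensitivity analysis, but nuclear-localized DAPI plus
the partially nuclear GFP/NeuN signal make the mask mean a stable statistic.

### ROI placement

Vector is applied as a 4-μL droplet to the slice surface, so expression is
frequently eccentric. To compare capsids at their point of highest
effective dose, a fixed circle (default diameter 2,000 μm) is scanned over
the GFP channel and placed at the centre maximizing the *mean* GFP inside
the circular mask. Mean and sum are equivalent objectives while the mask
fits entirely in the image — only centres where it does are scanned, which
keeps the averaging area constant — but the mean stays meaningful in the
degenerate whole-image fallback used when the image is smaller than the
circle. The scan decomposes the circular mask into per-row runs and
evaluates each run from per-row prefix sums; on integer-valued images the
prefix sums are exact in float64, so the scan is bit-identical to a naive
exhaustive scan (this is asserted against an independent direct-correlation
reference). The default grid stride is 8 px followed by a stride-1
refinement in a ±8 px window; ties break toward the smallest row, then
column. Whole-slice analysis (no circle) is a first-class mode and feeds
the identical downstream tabulation.

### Segmentation

Gaussian smoothing (σ = 2 px at the default 1024-px scale) → Otsu threshold
on DAPI → hole filling → distance-transform watershed seeded at local
maxima of the distance map (plateau maxima merged by connected-component
labelling) → area filter (12–2,000 px). The pipeline is fully deterministic;
there is no learned model and no random initialization. On the default
synthetic density (500 nuclei in 1024², nucleus radius 14 ± 2 μm at
4 μm/px) detection F1 against ground truth is ≥ 0.99; at the 4.8× denser
360-px scale used for replicate studies it remains ≥ 0.99 with σ = 1.2 and
a 4-px peak distance. Border-touching nuclei are kept by default
(`exclude_border` available).

### Thresholds and classification

GFP positivity is calibrated per patient: the cutoff is the maximum
per-nucleus mean GFP across all of that patient's PBS-control sections,
and positivity requires *strictly greater* intensity. The strict inequality
makes the control guarantee exact — re-classifying any control table with
its own threshold yields zero positives, with no tolerance involved — and
ties at the cutoff are negative. Controls are pooled per patient by
default. Marker cutoffs default to the mean of the channel's per-nucleus
means, computed per image; for a well-separated bimodal
positive/negative population this sits between the modes (≥ 99% accuracy
on the synthetic bimodal fixture). Nuclei positive for both markers are
labelled "double" and count in both marker denominators, since per-marker
percentages are computed independently; an `exclude_double` option inverts
this.

### Tropism tables and group comparisons

Per (sample, variant), percent transduced is reported for the all-cells
denominator and per marker class; marker rows with fewer than 30 cells are
flagged `included = False` and excluded from group statistics, so
conclusions are never drawn from a handful of cells. Two imaged sections
per sample are averaged by default (one observation = one tissue sample);
pooling counts or keeping sections separate are alternative policies, and
pooling equals recomputation from summed counts by construction.

Variants are compared with the tie-corrected Kruskal-Wallis H (degenerate
all-tied input returns H = 0, p = 1 rather than an error) and Dunn's
pairwise z on pooled mid-ranks with the same tie term. The multiplicity
adjustment defaults to Bonferroni over all pairs — the common reading of
"Dunn's correction" in commercial statistics packages — with Holm and BH
selectable; adjusted p-values are floored at the raw p. Compact letters are
assigned by insert-and-absorb so that groups sharing no letter differ at
the chosen α. The age analysis is a per-variant Spearman correlation of
patient age against per-sample percent; constant inputs are flagged
degenerate (ρ = NaN) rather than silently reported as zero.

## The sequencing model

Barcode features are identified in the features table
(`viral_barcode:<variant>`); a cell is called transduced by a variant when
its barcode count is ≥ 1 UMI (threshold configurable). A cell may be
positive for several variants: it counts once per variant in per-variant
totals and once in the any-viral total, so totals sum to ≥ the any-viral
count with equality iff no multi-variant cells. The cell type × variant
heatmap entry is the percent of annotated type-t cells positive for v;
unannotated cells are excluded with a logged count.

Differential expression is one-vs-rest per cell type: counts are scaled
per cell to a fixed total of 10⁴ over *gene* features only (barcodes are
excluded from both the totals and the gene universe so transduction cannot
distort expression statistics), each gene is tested with the two-sided
Wilcoxon rank-sum normal approximation with tie correction (an exact
enumeration mode exists for small tie-free samples and is checked against
a brute-force oracle), p-values are BH-adjusted across genes within each
type, and log2FC = log2((mean_in + ε)/(mean_out + ε)) with ε = 1e-9 on
normalized means. Genes constant across all cells get p = 1 and log2FC = 0
by definition. Cross-dataset identity preservation is summarized by the
Pearson correlation of log2FC vectors for every (type in A, type in B)
pair over the union of either side's significant genes, restricted to
genes expressed (nonzero mean) in both types; entries with fewer than 3
shared genes are missing (NaN), not zero. Rows are the first dataset's
types and columns the second's; the matrix is not symmetric.

## The synthetic-data generator

The generator is the testbed's definition of "truth", emulating the
statistical structure the analysis assumes:

* **Images.** Nuclei are isotropic Gaussian blobs (σ = radius/2) with
  radius ~ N(14, 2) μm truncated positive, placed by rejection sampling
  with a minimum centre distance of 2.4 mean radii so segmentation is
  well-posed. Default field: 1024 × 1024 px at 4 μm/px (a 4.1-mm field, so
  the 2-mm circle fits); the true pixel size and bit depth of the original
  microscope setup are not public, so these are stated defaults, not
  inferred facts. Cell types (default 35% neurons / 40% astrocytes / 25%
  microglia, the neuron share matching the day-0 composition bookkeeping)
  determine which marker channel lights up; a nucleus at distance d from
  the application hotspot is transduced with probability
  f(type)·exp(−d²/2σ²) with σ = 800 μm by default (droplet spread at the
  mm scale; σ = ∞ gives spatially uniform transduction for recovery
  studies). Channel intensities are background Gaussian noise (mean ≈ 10,
  SD 2) plus per-nucleus foreground blobs (peak ≈ 90–120, 10% jitter),
  quantized to integer grey levels. Controls are drawn from an independent
  substream with transduction forced to zero.
* **Counts.** Gene counts are gamma-Poisson (negative binomial, dispersion
  0.3) around lognormal per-gene abundances scaled to a 2,500-UMI mean
  library; each cell type upregulates its marker genes by a configurable
  fold change (default 4×). Barcode counts are Bernoulli per
  (type, variant) followed by 1 + Poisson(mean − 1) UMIs, so "transduced"
  always implies ≥ 1 transcript and truth labels are never ambiguous. The
  default panel is the 14-capsid library; the 13-variant option drops Sch9
  (the pediatric library lacked it).

What passing synthetic tests shows: the pipeline's logic, exactness
guarantees and statistical calibration are correct, and configured effect
sizes are recovered without bias at the stated densities. What they do not
show: robustness to optical artifacts absent from the model — point-spread
blur, channel bleed-through, autofluorescence gradients, section folds,
debris — or to segmentation regimes (overlapping nuclei in 3-D, anisotropy)
beyond the blob model. Real-data thresholds for the marker channels in
particular may need the fixed-value mode rather than the channel mean.

## Problem sizes and verification conditions

Recovery studies use spatially uniform transduction at the configured
fractions {0.15, 0.30, 0.40, 0.53, 0.55} — the reported overall levels of
AAV5, AAV2, AAV9, PHP.S and PHP.eB. The ±5-point recovery check runs at
the full default image scale with 7 samples per variant; the rank-order
check runs 100 independent replicate studies of 6 samples × 2 sections per
variant (500 nuclei per section) at the 360-px scale, whose per-variant
standard error (≈ 0.65 points) makes the 53-vs-55 ordering resolvable.
Statistical null calibration uses 2,000 exchangeable Kruskal-Wallis
simulations and 12 permuted-label DE runs. These sizes are the package's
own verification conditions and are all seeded and deterministic.

## Known limitations

* The watershed merges nuclei whose centres fall within one peak window;
  at the default densities this affects < 1% of nuclei and is unbiased
  with respect to transduction, but very dense tissue would need smaller
  smoothing and peak distances (exposed as parameters).
* The control-max GFP threshold is an extreme-value statistic: it grows
  with the number of control nuclei, making the classifier conservative
  for large control sets. This is inherent to the calibration rule, not a
  bug; a quantile-based alternative would change the guarantee.
* Dunn's test uses the normal approximation; for very small groups its
  pairwise p-values are approximate even though H itself is exact against
  the rank oracle.
* The DE model tests location shifts on normalized expression; it does not
  model dropout explicitly, and the log2FC pseudocount makes fold changes
  of lowly expressed genes compress toward zero.
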