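# aavtropism

Quantification of AAV capsid tropism in *ex vivo* human brain slice
cultures, from two complementary readouts:

* **Immunofluorescence imaging** — four-channel confocal scans of slice
  sections (DAPI, GFAP-633, GFP-488, NeuN/Iba1-546). The pipeline places a
  standardized 2-mm circular analysis region where mean GFP signal is
  maximal (vector is applied as a droplet, so expression is often
  eccentric), segments every DAPI nucleus, measures the mean of each
  channel over each nucleus mask, calibrates the GFP-positivity threshold
  from untransduced PBS-control sections (cutoff = the brightest control
  nucleus, strictly exceeded), and tabulates per-variant percent
  transduction overall and per marker-defined cell type (NeuN+ neurons,
  GFAP+ astrocytes, Iba1+ microglia). Variants are compared with
  Kruskal-Wallis tests and Dunn post-hoc pairwise comparisons.
* **Barcoded single-nucleus RNA-seq** — each capsid in a pooled library
  carries a unique 25-bp barcode transcript. From a cells-by-features count
  matrix, a cell is called transduced by a variant when it carries at least
  one UMI of that variant's barcode. The pipeline reports per-variant
  transduced-cell totals, the cell type × variant percent-transduction
  heatmap, one-vs-rest Wilcoxon rank-sum differential expression with
  Benjamini-Hochberg correction, and the Pearson correlation of cell-type
  log2 fold-change profiles between datasets (e.g. day 0 vs day 14 in
  culture) to check that cell identities are preserved.

Because patient images and libraries are not publicly available, the
package ships a synthetic-data generator (`aavtropism.simulate`) that
emulates both modalities with known ground truth: Gaussian-blob nuclei of
several cell types, an eccentric transduction hotspot with Gaussian spatial
decay, channel noise, and negative-binomial gene counts with cell-type
marker genes and Bernoulli per-(type, variant) barcode transduction. Every
pipeline stage is tested against this ground truth.

## The statistics at the core

For a section with nuclei $i = 1..N$, per-nucleus mean intensities
$\bar I_i^{(c)}$ are computed over each segmented DAPI mask for every
channel $c$. With a per-patient control-calibrated cutoff
$\tau = \max_{j \in \text{controls}} \bar I_j^{(488)}$, the headline
quantity per capsid variant $v$ is

$$\text{percent transduced} = 100 \cdot \frac{\#\{i : \bar I_i^{(488)} > \tau\}}{N},$$

and analogously per marker class (denominator = marker-positive nuclei,
with a ≥ 30-cell inclusion rule). Group differences across variants use the
tie-corrected Kruskal-Wallis $H$ and Dunn's pairwise
$z_{uv} = (\bar R_u - \bar R_v) / \sqrt{(\tfrac{N(N+1)}{12} - T)(\tfrac1{n_u} + \tfrac1{n_v})}$
on pooled mid-ranks, with family-wise adjusted p-values and compact letter
display. For sequencing, per-variant calls are $x_{iv} \ge 1$ UMI, and
per-type differential expression uses the rank-sum test on library-size
normalized counts with BH correction and
$\log_2\!\big((\mu_{\text{in}} + \epsilon)/(\mu_{\text{out}} + \epsilon)\big)$
fold changes.

## Worked example

Recover known transduction levels with the full imaging pipeline
(simulate → segment → calibrate → classify → tabulate → compare):

```python
import math
from aavtropism import ImageSimConfig
from aavtropism.study import run_synthetic_study
from aavtropism.tropism import kruskal_dunn

fractions = {"AAV5": 0.15, "AAV2": 0.30, "AAV9": 0.40, "PHP.S": 0.53, "PHP.eB": 0.55}
base = ImageSimConfig(width_px=360, height_px=360, n_nuclei=500,
                      hotspot_sigma_um=math.inf)
study = run_synthetic_study(fractions, n_samples=5, n_sections=2, seed=1,
                            base_config=base,
                            segment_kwargs=dict(smooth_sigma=1.2, peak_min_distance=4))
print(study["estimates"].round(1))

agg = study["aggregated"]
all_cells = agg[agg["denominator_class"] == "all_cells"]
samples = {v: list(g["percent"]) for v, g in all_cells.groupby("variant", sort=False)}
result = kruskal_dunn(samples)
print(f"Kruskal-Wallis H = {result.h_statistic:.2f}, p = {result.p_value:.2g}")
print(result.letters)
```

prints

```
variant
AAV5      15.1
AAV2      30.1
AAV9      39.9
PHP.S     53.7
PHP.eB    54.1
Name: percent, dtype: float64
Kruskal-Wallis H = 21.97, p = 0.0002
{'AAV5': 'b', 'AAV2': 'ab', 'AAV9': 'ab', 'PHP.S': 'a', 'PHP.eB': 'a'}
```

Each estimate is the mean percent-GFP+ across 10 independently simulated
sections of 500 nuclei and lands within sampling noise of the configured
ground truth (15 / 30 / 40 / 53 / 55%). The compact letters show which
variants differ at adjusted p < 0.05: the weakest capsid (AAV5) is
separated from the two strongest (PHP.S, PHP.eB).

A command-line interface mirrors the library
(`aavtropism simulate image`, `roi`, `quantify`, `classify`, `summarize`,
`sn-tropism`); see `aavtropism --help`.

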