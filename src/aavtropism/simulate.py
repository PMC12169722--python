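"""Synthetic fluorescence images and barcoded single-nucleus count matrices.

These generators emulate the statistical structure of the real experiment —
AAV vectors applied as a droplet to the centre of a living human brain slice,
imaged two weeks later — so that every downstream analysis stage can be
exercised against known ground truth:

* :func:`simulate_image` draws Gaussian-blob nuclei of several cell types on
  a noisy background. Each nucleus is transduced with a probability that
  decays with distance from an (optionally eccentric) application hotspot,
  and transduced nuclei carry GFP foreground signal. Marker channels light
  up according to cell type.
* :func:`simulate_control_image` is the PBS-only control: identical tissue
  structure, zero transduction, GFP channel pure background.
* :func:`simulate_counts` draws a sparse cells-by-features matrix in which
  most features are negative-binomial genes (with cell-type marker genes
  upregulated by a configurable fold change) and 13-14 features are viral
  barcode transcripts following per-(cell type, variant) Bernoulli
  transduction.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .image import DEFAULT_CHANNEL_ROLES, ImageStack

#: The capsid panel: eight natural serotypes and six engineered variants.
VARIANT_NAMES = (
    "AAV1", "AAV2", "AAV5", "AAV6", "AAV7", "AAV8", "AAV9", "rh10",
    "DJ8", "DJ", "AAV2-retro", "PHP.S", "PHP.eB", "Sch9",
)

DEFAULT_CELL_TYPE_FRACTIONS = {"neuron": 0.35, "astrocyte": 0.40, "microglia": 0.25}

#: Which immunofluorescence channel labels which simulated cell type.
#: Astrocytes are GFAP+ (633 channel, role marker_a); neurons NeuN+
#: (546 channel, role marker_b); microglia carry no marker in the default
#: two-marker staining scheme.
DEFAULT_MARKER_ASSIGNMENT = {"astrocyte": "marker_a", "neuron": "marker_b", "microglia": None}

#: Per-channel intensity model: additive Gaussian background noise plus a
#: per-nucleus Gaussian blob whose peak amplitude is itself jittered.
DEFAULT_INTENSITY_PARAMS = {
    "dapi": {"background_mean": 12.0, "background_sd": 2.0,
             "foreground_mean": 120.0, "foreground_sd": 10.0},
    "gfp": {"background_mean": 10.0, "background_sd": 2.0,
            "foreground_mean": 90.0, "foreground_sd": 9.0},
    "marker_a": {"background_mean": 10.0, "background_sd": 2.0,
                 "foreground_mean": 90.0, "foreground_sd": 9.0},
    "marker_b": {"background_mean": 10.0, "background_sd": 2.0,
                 "foreground_mean": 90.0, "foreground_sd": 9.0},
}


def _validate_fractions(fractions: dict[str, float]) -> None:
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"cell_type_fractions must sum to 1, got {total}")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("cell_type_fractions must be non-negative")


@dataclass
class ImageSimConfig:
    """Configuration for one simulated slice section.

    ``hotspot_sigma_um`` is the spatial scale of the droplet's spread: a
    nucleus at distance *d* (um) from the hotspot is transduced with
    probability ``transduction_fraction[type] * exp(-d^2 / (2 sigma^2))``.
    Set it to ``math.inf`` for spatially uniform transduction.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 4.0
    n_nuclei: int = 500
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPE_FRACTIONS)
    )
    transduction_fraction: dict[str, float] | float = 0.40
    hotspot_center_px: tuple[int, int] | str = "random"
    hotspot_sigma_um: float = 800.0
    intensity_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_PARAMS.items()}
    )
    marker_assignment: dict[str, str | None] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_ASSIGNMENT)
    )
    nucleus_radius_mean_um: float = 14.0
    nucleus_radius_sd_um: float = 2.0
    min_separation_factor: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        _validate_fractions(self.cell_type_fractions)
        for p in self._transduction_map().values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transduction probability {p} outside [0, 1]")
        if self.hotspot_sigma_um <= 0:
            raise ValueError("hotspot_sigma_um must be positive (use math.inf for uniform)")

    def _transduction_map(self) -> dict[str, float]:
        if isinstance(self.transduction_fraction, dict):
            return {t: float(self.transduction_fraction.get(t, 0.0))
                    for t in self.cell_type_fractions}
        return {t: float(self.transduction_fraction) for t in self.cell_type_fractions}


def _place_nuclei(rng: np.random.Generator, cfg: ImageSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample centres (row, col) with a minimum pairwise distance.

    Returns (centres float array (n, 2), radii_px (n,)).
    """
    n = cfg.n_nuclei
    r_px_mean = cfg.nucleus_radius_mean_um / cfg.pixel_size_um
    min_dist = cfg.min_separation_factor * r_px_mean
    # truncated-positive normal radii (redraw non-positive values)
    radii = rng.normal(cfg.nucleus_radius_mean_um, cfg.nucleus_radius_sd_um, size=n)
    while np.any(radii <= 0.5):
        bad = radii <= 0.5
        radii[bad] = rng.normal(cfg.nucleus_radius_mean_um, cfg.nucleus_radius_sd_um,
                                size=int(bad.sum()))
    radii = radii / cfg.pixel_size_um
    margin = (radii.max() if n else r_px_mean) + 1.0
    if cfg.height_px <= 2 * margin or cfg.width_px <= 2 * margin:
        raise ValueError("image too small for the configured nucleus radius")
    # occupancy grid (cell edge = min_dist) limits the neighbour search to 3x3
    centres = np.empty((n, 2))
    grid: dict[tuple[int, int], list[int]] = {}
    min_sq = min_dist * min_dist
    placed = 0
    attempts = 0
    max_attempts = 500 * max(n, 1)
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} nuclei at min separation {min_dist:.1f}px; "
                "reduce density or min_separation_factor"
            )
        cr = rng.uniform(margin, cfg.height_px - margin)
        cc = rng.uniform(margin, cfg.width_px - margin)
        attempts += 1
        gr, gc = int(cr / min_dist), int(cc / min_dist)
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for j in grid.get((gr + dr, gc + dc), ()):
                    if (centres[j, 0] - cr) ** 2 + (centres[j, 1] - cc) ** 2 < min_sq:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        centres[placed] = (cr, cc)
        grid.setdefault((gr, gc), []).append(placed)
        placed += 1
    return centres, radii


def _add_blobs(channel: np.ndarray, centres: np.ndarray, radii: np.ndarray,
               amplitudes: np.ndarray) -> None:
    """Add isotropic Gaussian blobs (sigma = radius / 2) in place."""
    h, w = channel.shape
    for (cr, cc), r, amp in zip(centres, radii, amplitudes):
        if amp == 0.0:
            continue
        ext = int(np.ceil(2.5 * r))
        r0, r1 = max(0, int(cr) - ext), min(h, int(cr) + ext + 1)
        c0, c1 = max(0, int(cc) - ext), min(w, int(cc) + ext + 1)
        inv = 1.0 / (2.0 * (r / 2.0) ** 2)
        # the isotropic Gaussian factorises into a row and a column profile
        prow = np.exp(-((np.arange(r0, r1) - cr) ** 2) * inv)
        pcol = np.exp(-((np.arange(c0, c1) - cc) ** 2) * inv)
        channel[r0:r1, c0:c1] += amp * np.outer(prow, pcol)


def simulate_image(config: ImageSimConfig, *, _force_untransduced: bool = False,
                   _stream: int = 0) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate one four-channel slice section.

    Returns
    -------
    (ImageStack, GroundTruth)
        The ground-truth table has one row per nucleus with columns
        ``nucleus_id, row, col, radius_px, cell_type, transduced``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), _stream]))
    types = list(cfg.cell_type_fractions)
    probs = np.array([cfg.cell_type_fractions[t] for t in types], dtype=float)
    probs = probs / probs.sum()

    centres, radii = _place_nuclei(rng, cfg)
    type_idx = rng.choice(len(types), size=cfg.n_nuclei, p=probs)
    cell_types = np.array(types, dtype=object)[type_idx]

    # transduction probability decays with distance from the hotspot
    if cfg.hotspot_center_px == "random":
        hotspot = np.array([rng.uniform(0, cfg.height_px), rng.uniform(0, cfg.width_px)])
    else:
        hotspot = np.asarray(cfg.hotspot_center_px, dtype=float)
    tmap = cfg._transduction_map()
    base_p = np.array([tmap[t] for t in cell_types])
    if math.isinf(cfg.hotspot_sigma_um):
        spatial = np.ones(cfg.n_nuclei)
    else:
        d_um = np.sqrt(np.sum((centres - hotspot) ** 2, axis=1)) * cfg.pixel_size_um
        spatial = np.exp(-(d_um**2) / (2 * cfg.hotspot_sigma_um**2))
    p = base_p * spatial
    transduced = rng.random(cfg.n_nuclei) < p
    if _force_untransduced:
        transduced[:] = False

    roles = dict(DEFAULT_CHANNEL_ROLES)
    pixels = np.empty((4, cfg.height_px, cfg.width_px))
    for role, ch in roles.items():
        ip = cfg.intensity_params[role]
        pixels[ch] = rng.normal(ip["background_mean"], ip["background_sd"],
                                size=(cfg.height_px, cfg.width_px))

    def amplitudes(role: str, mask: np.ndarray) -> np.ndarray:
        ip = cfg.intensity_params[role]
        amps = np.zeros(cfg.n_nuclei)
        n_on = int(mask.sum())
        if n_on:
            amps[mask] = rng.normal(ip["foreground_mean"], ip["foreground_sd"], size=n_on)
        return amps

    all_on = np.ones(cfg.n_nuclei, dtype=bool)
    _add_blobs(pixels[roles["dapi"]], centres, radii, amplitudes("dapi", all_on))
    _add_blobs(pixels[roles["gfp"]], centres, radii, amplitudes("gfp", transduced))
    for role in ("marker_a", "marker_b"):
        mask = np.array([cfg.marker_assignment.get(t) == role for t in cell_types])
        _add_blobs(pixels[roles[role]], centres, radii, amplitudes(role, mask))

    # quantize to integer grey levels, as a camera would
    np.rint(pixels, out=pixels)
    np.clip(pixels, 0, 65535, out=pixels)
    pixels = pixels.astype(np.uint16)

    truth = pd.DataFrame({
        "nucleus_id": np.arange(cfg.n_nuclei),
        "row": centres[:, 0],
        "col": centres[:, 1],
        "radius_px": radii,
        "cell_type": cell_types,
        "transduced": transduced,
    })
    stack = ImageStack(pixels=pixels, channel_roles=roles,
                       pixel_size_um=cfg.pixel_size_um,
                       image_id=f"sim-{cfg.seed}" + ("-ctrl" if _force_untransduced else ""))
    return stack, truth


def simulate_control_image(config: ImageSimConfig) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate a PBS-only control section: same tissue model, no transduction.

    Drawn from an independent random substream of the same seed, so a control
    is a different slice of the same simulated tissue, not a pixel-identical
    copy of the vector-treated section.
    """
    return simulate_image(config, _force_untransduced=True, _stream=1)


@dataclass
class CountSimConfig:
    """Configuration for a simulated barcoded single-nucleus count matrix.

    ``transduction_prob`` may be a scalar (uniform across types and
    variants), a per-variant dict, or a dict keyed by ``(cell_type,
    variant)``. ``barcode_umi_mean`` is the expected UMI count of a barcode
    in a transduced cell; counts are drawn as ``1 + Poisson(mean - 1)`` so a
    transduced cell always has at least one viral transcript.
    """

    n_cells: int = 5000
    n_genes: int = 1000
    n_variants: int = 14
    cell_type_fractions: dict[str, float] = field(default_factory=lambda: {
        "Glutamatergic neuron": 0.35, "Astrocyte": 0.30,
        "Oligodendrocyte": 0.20, "Microglia": 0.15,
    })
    transduction_prob: dict | float = 0.01
    barcode_umi_mean: float = 1.5
    nb_dispersion: float = 0.3
    library_size_mean: float = 2500.0
    n_marker_genes_per_type: int = 20
    marker_fold_change: float = 4.0
    sample_id: str = "sample1"
    day: int = 14
    condition: str = "vector"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes <= 0:
            raise ValueError("n_cells must be >= 0 and n_genes positive")
        if self.n_variants < 1 or self.n_variants > len(VARIANT_NAMES):
            raise ValueError(f"n_variants must be in [1, {len(VARIANT_NAMES)}]")
        _validate_fractions(self.cell_type_fractions)
        n_types = len(self.cell_type_fractions)
        if self.n_marker_genes_per_type * n_types > self.n_genes:
            raise ValueError("not enough genes for the requested marker genes per type")
        if self.barcode_umi_mean < 1.0:
            raise ValueError("barcode_umi_mean must be >= 1")
        if self.marker_fold_change <= 0:
            raise ValueError("marker_fold_change must be positive")
        for t in self.cell_type_fractions:
            for v in self.variant_names:
                p = self._prob(t, v)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"transduction_prob[{t}, {v}] = {p} outside [0, 1]")

    @property
    def variant_names(self) -> list[str]:
        if self.n_variants == 13:
            # the pediatric library lacked Sch9
            return [v for v in VARIANT_NAMES if v != "Sch9"]
        return list(VARIANT_NAMES[: self.n_variants])

    def _prob(self, cell_type: str, variant: str) -> float:
        tp = self.transduction_prob
        if isinstance(tp, dict):
            if (cell_type, variant) in tp:
                return float(tp[(cell_type, variant)])
            if variant in tp:
                return float(tp[variant])
            return float(tp.get(cell_type, 0.0))
        return float(tp)


@dataclass
class CountTruth:
    """Ground truth for a simulated count matrix."""

    cells: pd.DataFrame  # cell_id, cell_type + one bool column per variant
    marker_genes: dict[str, list[str]]  # cell type -> marker gene names


def simulate_counts(config: CountSimConfig) -> tuple["BarcodeMatrix", CountTruth]:
    """Simulate a sparse cells x (genes + viral barcodes) count matrix."""
    from .barcodes import BarcodeMatrix, random_barcode_sequences

    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    types = list(cfg.cell_type_fractions)
    probs = np.array([cfg.cell_type_fractions[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    type_idx = rng.choice(len(types), size=cfg.n_cells, p=probs)
    cell_types = np.array(types, dtype=object)[type_idx]

    gene_names = [f"gene{g:05d}" for g in range(cfg.n_genes)]
    marker_genes: dict[str, list[str]] = {}
    fold = np.ones((len(types), cfg.n_genes))
    g = 0
    for ti, t in enumerate(types):
        idx = np.arange(g, g + cfg.n_marker_genes_per_type)
        marker_genes[t] = [gene_names[i] for i in idx]
        fold[ti, idx] = cfg.marker_fold_change
        g += cfg.n_marker_genes_per_type

    # per-gene relative abundance (lognormal), scaled to the mean library size
    gene_weight = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    gene_weight /= gene_weight.sum()
    base_mean = cfg.library_size_mean * gene_weight  # (n_genes,)
    mean = base_mean[None, :] * fold[type_idx, :]  # (n_cells, n_genes)

    # negative binomial via gamma-Poisson mixture
    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mean * cfg.nb_dispersion)
    else:
        lam = mean
    genes = rng.poisson(lam)

    variants = cfg.variant_names
    pmat = np.array([[cfg._prob(t, v) for v in variants] for t in types])
    cell_p = pmat[type_idx, :]  # (n_cells, n_variants)
    transduced = rng.random(cell_p.shape) < cell_p
    bc_counts = np.zeros(cell_p.shape, dtype=np.int64)
    n_pos = int(transduced.sum())
    if n_pos:
        bc_counts[transduced] = 1 + rng.poisson(cfg.barcode_umi_mean - 1.0, size=n_pos)

    counts = sparse.hstack(
        [sparse.csr_matrix(genes), sparse.csr_matrix(bc_counts)], format="csr"
    ).astype(np.int64)

    bc_seqs = random_barcode_sequences(len(variants), rng=rng)
    features = pd.DataFrame({
        "feature_id": gene_names + [f"bc-{v}" for v in variants],
        "name": gene_names + list(variants),
        "kind": ["gene"] * cfg.n_genes + ["viral_barcode"] * len(variants),
        "variant": [""] * cfg.n_genes + list(variants),
        "sequence": [""] * cfg.n_genes + bc_seqs,
    })
    cell_ids = [f"{cfg.sample_id}-cell{c:05d}" for c in range(cfg.n_cells)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": cfg.sample_id,
        "day": cfg.day,
        "condition": cfg.condition,
    })
    truth_cells = pd.DataFrame({"cell_id": cell_ids, "cell_type": cell_types})
    for vi, v in enumerate(variants):
        truth_cells[v] = transduced[:, vi]

    matrix = BarcodeMatrix(counts=counts, features=features, cells=cells)
    return matrix, CountTruth(cells=truth_cells, marker_genes=marker_genes)


def control_count_config(config: CountSimConfig, **overrides) -> CountSimConfig:
    """A copy of *config* with transduction zeroed (PBS control library)."""
    return replace(config, transduction_prob=0.0, condition="control", **overrides)
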