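"""Viral-barcode transduction scoring on single-nucleus count matrices.

Each AAV capsid variant in the pooled library carries a unique 25-bp barcode
in its cargo, so the barcode transcript features of a cells-by-features count
matrix record which variants transduced which nuclei. This module provides:

* CellRanger-style Matrix Market triplet I/O with barcode features flagged
  in the features table;
* transduction calls (a cell is transduced by a variant if it has at least
  ``threshold_umis`` UMIs of that variant's barcode; default 1);
* per-variant transduced-cell totals and the cell type x variant
  percent-transduction heatmap;
* one-vs-rest Wilcoxon rank-sum differential expression per cell type with
  Benjamini-Hochberg correction, and the Pearson correlation of cell-type
  log2 fold-change profiles between two datasets (e.g. day 0 vs day 14),
  used to check that cell identities are preserved in culture;
* per-day cell-type composition bookkeeping (e.g. the loss of neurons over
  two weeks ex vivo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def random_barcode_sequences(n: int, length: int = 25,
                             rng: np.random.Generator | None = None) -> list[str]:
    """Distinct random DNA barcodes of the given length (default 25 bp)."""
    rng = np.random.default_rng(0) if rng is None else rng
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = "".join(rng.choice(_BASES, size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


@dataclass
class BarcodeMatrix:
    """Sparse cells x features counts with a designated viral-barcode subset.

    ``features`` columns: feature_id, name, kind ("gene" or "viral_barcode"),
    variant (capsid name, barcodes only), sequence (25-bp barcode, optional).
    ``cells`` columns: cell_id plus optional sample_id, day, condition.
    """

    counts: sparse.csr_matrix
    features: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        kinds = set(self.features["kind"])
        unknown = kinds - {"gene", "viral_barcode"}
        if unknown:
            raise ValueError(f"unknown feature kinds: {unknown}")
        bc = self.features[self.features["kind"] == "viral_barcode"]
        if len(bc) == 0:
            logger.warning("no viral_barcode features found in matrix")
        elif bc["variant"].duplicated().any():
            raise ValueError("viral_barcode features must have unique variant names")

    @property
    def barcode_idx(self) -> np.ndarray:
        return np.flatnonzero((self.features["kind"] == "viral_barcode").to_numpy())

    @property
    def gene_idx(self) -> np.ndarray:
        return np.flatnonzero((self.features["kind"] == "gene").to_numpy())

    @property
    def variant_names(self) -> list[str]:
        return list(self.features["variant"].iloc[self.barcode_idx])

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def write_barcode_matrix(matrix: BarcodeMatrix, out_dir) -> None:
    """Write the CellRanger-style triplet: matrix.mtx, features.tsv, barcodes.tsv.

    The MTX is written features x cells (CellRanger orientation). The
    features table has columns id, name, kind where kind is ``gene`` or
    ``viral_barcode:<variant>``; barcodes.tsv carries cell_id plus any
    sample metadata columns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(matrix.counts.T))
    feats = matrix.features.copy()
    kind = np.where(feats["kind"] == "viral_barcode",
                    "viral_barcode:" + feats["variant"].astype(str), "gene")
    pd.DataFrame({"id": feats["feature_id"], "name": feats["name"], "kind": kind}
                 ).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    matrix.cells.to_csv(out / "barcodes.tsv", sep="\t", header=True, index=False)


def read_barcode_matrix(mtx_path, features_path, cells_path) -> BarcodeMatrix:
    """Read a Matrix Market triplet into a :class:`BarcodeMatrix`.

    Accepts either orientation (features x cells, as CellRanger writes, or
    cells x features); the orientation is inferred from the table lengths.
    The 1-based MTX coordinate convention is handled by the reader.
    """
    raw = sparse.csr_matrix(mmread(str(mtx_path)))
    feats = pd.read_csv(features_path, sep="\t", header=None,
                        names=["feature_id", "name", "kind"])
    cells = pd.read_csv(cells_path, sep="\t")
    if "cell_id" not in cells.columns:  # headerless barcode list
        cells = pd.read_csv(cells_path, sep="\t", header=None, names=["cell_id"])
    n_feat, n_cell = len(feats), len(cells)
    if raw.shape == (n_feat, n_cell) and raw.shape != (n_cell, n_feat):
        raw = sparse.csr_matrix(raw.T)
    elif raw.shape != (n_cell, n_feat):
        raise ValueError(
            f"matrix shape {raw.shape} matches neither {n_feat} features x "
            f"{n_cell} cells nor its transpose"
        )
    kind_col = feats["kind"].astype(str)
    is_bc = kind_col.str.startswith("viral_barcode")
    feats["variant"] = np.where(is_bc, kind_col.str.partition(":")[2], "")
    feats["kind"] = np.where(is_bc, "viral_barcode", "gene")
    feats["sequence"] = ""
    return BarcodeMatrix(counts=raw, features=feats, cells=cells)


@dataclass
class TransductionCalls:
    """Per-cell transduction calls.

    ``per_variant`` is a boolean DataFrame indexed by cell_id with one
    column per variant; ``any_viral`` is its row-wise OR (at least one viral
    transcript across all barcodes).
    """

    per_variant: pd.DataFrame
    threshold_umis: int = 1
    cells: pd.DataFrame | None = None

    @property
    def any_viral(self) -> pd.Series:
        return self.per_variant.any(axis=1)


def call_transduced(matrix: BarcodeMatrix, threshold_umis: int = 1) -> TransductionCalls:
    """Call each cell transduced by each variant it has >= threshold UMIs of."""
    if threshold_umis < 1:
        raise ValueError("threshold_umis must be >= 1")
    idx = matrix.barcode_idx
    if idx.size == 0:
        raise ValueError("matrix has no viral_barcode features")
    bc = matrix.counts[:, idx].toarray()
    flags = pd.DataFrame(bc >= threshold_umis, columns=matrix.variant_names,
                         index=pd.Index(matrix.cells["cell_id"], name="cell_id"))
    return TransductionCalls(per_variant=flags, threshold_umis=threshold_umis,
                             cells=matrix.cells.copy())


def variant_totals(calls: TransductionCalls, by_sample: bool = False) -> pd.DataFrame:
    """Transduced-cell count per variant (a multi-variant cell counts once
    per variant it carries, so the totals can sum to more than the number of
    cells with any viral transcript)."""
    if not by_sample:
        tot = calls.per_variant.sum(axis=0).astype(int)
        return tot.rename("n_transduced").rename_axis("variant").reset_index()
    if calls.cells is None or "sample_id" not in calls.cells.columns:
        raise ValueError("per-sample totals require a cells table with sample_id")
    sample = calls.cells.set_index("cell_id").loc[calls.per_variant.index, "sample_id"]
    out = calls.per_variant.groupby(sample.to_numpy()).sum().astype(int)
    out.index.name = "sample_id"
    return out.reset_index().melt(id_vars="sample_id", var_name="variant",
                                  value_name="n_transduced")


def celltype_transduction_heatmap(calls: TransductionCalls,
                                  annotation: pd.Series) -> pd.DataFrame:
    """Percent of each annotated cell type transduced by each variant.

    ``annotation`` maps cell_id -> cell type. Called cells without an
    annotation are excluded (their number is logged). Entry (t, v) =
    100 * |type-t cells positive for v| / |type-t cells|.
    """
    ann = annotation.reindex(calls.per_variant.index)
    n_missing = int(ann.isna().sum())
    if n_missing:
        logger.info("excluding %d unannotated cells from heatmap", n_missing)
    keep = ann.notna()
    if not keep.any():
        raise ValueError("no annotated cells left after exclusions")
    flags = calls.per_variant[keep]
    ann = ann[keep]
    pos = flags.groupby(ann.to_numpy()).sum()
    denom = ann.groupby(ann.to_numpy()).size()
    pct = 100.0 * pos.div(denom, axis=0)
    pct.index.name = "cell_type"
    return pct


def normalize_expression(matrix: BarcodeMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell library-size normalization over gene features only.

    Each cell's gene counts are scaled to ``target_sum`` total. Viral
    barcode features are excluded both from the totals and from the output
    so transduction does not distort expression statistics. Returns a dense
    cells x genes array on the linear (not log) scale.
    """
    genes = matrix.counts[:, matrix.gene_idx].toarray().astype(np.float64)
    totals = genes.sum(axis=1)
    totals[totals == 0] = 1.0
    return genes * (target_sum / totals)[:, None]


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray, exact: bool = False) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    The asymptotic normal approximation with tie correction is the default
    (the convention of standard single-cell DE tooling); ``exact=True``
    enumerates the exact null for small tie-free samples.
    """
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method, use_continuity=False).pvalue)


@dataclass
class DEResult:
    """One-vs-rest differential expression per cell type.

    ``table`` columns: cell_type, gene, log2fc, mean_in, mean_out, p,
    p_adjusted (BH within cell type). ``significant(alpha)`` returns the
    per-type significant gene sets.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    pseudocount: float = 1e-9
    skipped_types: list[str] = field(default_factory=list)

    def significant(self, alpha: float | None = None) -> dict[str, list[str]]:
        a = self.alpha if alpha is None else alpha
        sig = self.table[self.table["p_adjusted"] < a]
        return {t: list(g["gene"]) for t, g in sig.groupby("cell_type", sort=False)}

    def log2fc_vector(self, cell_type: str) -> pd.Series:
        sub = self.table[self.table["cell_type"] == cell_type]
        return sub.set_index("gene")["log2fc"]


def per_type_differential_expression(matrix: BarcodeMatrix, annotation: pd.Series,
                                     alpha: float = 0.05,
                                     pseudocount: float = 1e-9,
                                     min_cells: int = 2) -> DEResult:
    """One-vs-rest Wilcoxon rank-sum DE for every annotated cell type.

    Expression is library-size normalized (genes only; see
    :func:`normalize_expression`). For each cell type with at least
    ``min_cells`` cells (and at least ``min_cells`` in the rest), each
    gene's normalized expression is compared type-vs-rest with the rank-sum
    test, p-values are BH-adjusted across genes within the type, and
    log2FC = log2((mean_in + pc) / (mean_out + pc)) on normalized means.
    """
    ann = annotation.reindex(matrix.cells["cell_id"]).to_numpy()
    keep = pd.notna(ann)
    norm = normalize_expression(matrix)[keep]
    ann = ann[keep]
    gene_names = matrix.features["name"].iloc[matrix.gene_idx].to_numpy()
    types = pd.unique(ann)
    if len(types) < 2:
        raise ValueError("need at least two annotated cell types")
    recs = []
    skipped = []
    for t in types:
        in_mask = ann == t
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < min_cells or n_out < min_cells:
            logger.warning("skipping cell type %r with %d cells", t, n_in)
            skipped.append(str(t))
            continue
        x, y = norm[in_mask], norm[~in_mask]
        p = stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False,
                               axis=0).pvalue
        # identical samples give 0/0 in the tie-corrected normal statistic
        constant = (x.max(axis=0) == x.min(axis=0)) & (y.max(axis=0) == y.min(axis=0)) \
            & (x.max(axis=0) == y.max(axis=0))
        p = np.where(constant, 1.0, p)
        mean_in, mean_out = x.mean(axis=0), y.mean(axis=0)
        lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        lfc = np.where(constant, 0.0, lfc)
        p_adj = multipletests(p, method="fdr_bh")[1]
        recs.append(pd.DataFrame({
            "cell_type": t, "gene": gene_names, "log2fc": lfc,
            "mean_in": mean_in, "mean_out": mean_out,
            "p": p, "p_adjusted": p_adj,
        }))
    table = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame(
        columns=["cell_type", "gene", "log2fc", "mean_in", "mean_out", "p", "p_adjusted"])
    return DEResult(table=table, alpha=alpha, pseudocount=pseudocount,
                    skipped_types=skipped)


@dataclass
class CellTypeCorrelationMatrix:
    """Pearson r of log2FC profiles between cell types of two datasets.

    Rows are the first dataset's types, columns the second's; ``n_genes``
    holds the shared-gene count behind each entry. Entries with fewer than
    the minimum shared genes are NaN (missing, not zero).
    """

    r: pd.DataFrame
    n_genes: pd.DataFrame

    def diagonal(self) -> pd.Series:
        common = [t for t in self.r.index if t in self.r.columns]
        return pd.Series({t: self.r.loc[t, t] for t in common})


def log2fc_correlation(de_a: DEResult, de_b: DEResult,
                       min_genes: int = 3) -> CellTypeCorrelationMatrix:
    """Correlate per-type log2FC vectors between two DE results.

    For each (type in A, type in B): genes differentially expressed in
    either type (BH-adjusted p < alpha of its own result) are pooled, genes
    not present (zero mean expression) in one of the two types are
    discarded, and Pearson r of the remaining log2FC pairs is stored.
    """
    types_a = list(pd.unique(de_a.table["cell_type"]))
    types_b = list(pd.unique(de_b.table["cell_type"]))
    sig_a, sig_b = de_a.significant(), de_b.significant()
    r = pd.DataFrame(np.nan, index=types_a, columns=types_b, dtype=float)
    n = pd.DataFrame(0, index=types_a, columns=types_b, dtype=int)
    for ta in types_a:
        sub_a = de_a.table[de_a.table["cell_type"] == ta].set_index("gene")
        for tb in types_b:
            sub_b = de_b.table[de_b.table["cell_type"] == tb].set_index("gene")
            genes = set(sig_a.get(ta, [])) | set(sig_b.get(tb, []))
            genes &= set(sub_a.index[sub_a["mean_in"] > 0])
            genes &= set(sub_b.index[sub_b["mean_in"] > 0])
            genes = sorted(genes)
            n.loc[ta, tb] = len(genes)
            if len(genes) < min_genes:
                continue
            va = sub_a.loc[genes, "log2fc"].to_numpy()
            vb = sub_b.loc[genes, "log2fc"].to_numpy()
            if np.all(va == va[0]) or np.all(vb == vb[0]):
                continue  # zero-variance vector: correlation undefined
            r.loc[ta, tb] = float(stats.pearsonr(va, vb)[0])
    r.index.name = n.index.name = "cell_type_a"
    r.columns.name = n.columns.name = "cell_type_b"
    return CellTypeCorrelationMatrix(r=r, n_genes=n)


def composition_by_day(cells: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Fraction of cells per type for each day (rows sum to 1).

    Tracks, e.g., the depletion of neurons between day 0 and day 14 in
    culture. ``cells`` must carry cell_id and day columns.
    """
    if "day" not in cells.columns:
        raise ValueError("cells table must have a 'day' column")
    ann = annotation.reindex(cells["cell_id"]).to_numpy()
    df = pd.DataFrame({"day": cells["day"].to_numpy(), "cell_type": ann})
    df = df[pd.notna(df["cell_type"])]
    counts = df.groupby(["day", "cell_type"], sort=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
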