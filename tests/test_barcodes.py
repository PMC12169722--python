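"""Barcode matrix I/O, transduction calls, heatmaps, rank-sum DE and the
cross-dataset log2FC correlation, with exact-enumeration and closed-form
oracles for the statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from aavtropism.barcodes import (
    BarcodeMatrix,
    call_transduced,
    celltype_transduction_heatmap,
    composition_by_day,
    log2fc_correlation,
    per_type_differential_expression,
    read_barcode_matrix,
    variant_totals,
    wilcoxon_rank_sum,
    write_barcode_matrix,
)
from aavtropism.simulate import CountSimConfig, simulate_counts


def tiny_matrix(counts, variants=("V1", "V2"), n_genes=None, cells_extra=None):
    """Build a BarcodeMatrix from a dense array; last len(variants) columns
    are the viral barcodes."""
    counts = np.asarray(counts)
    n_cells, n_feat = counts.shape
    n_genes = n_feat - len(variants) if n_genes is None else n_genes
    features = pd.DataFrame({
        "feature_id": [f"g{i}" for i in range(n_genes)] + [f"bc-{v}" for v in variants],
        "name": [f"g{i}" for i in range(n_genes)] + list(variants),
        "kind": ["gene"] * n_genes + ["viral_barcode"] * len(variants),
        "variant": [""] * n_genes + list(variants),
        "sequence": "",
    })
    cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)]})
    if cells_extra:
        for k, v in cells_extra.items():
            cells[k] = v
    return BarcodeMatrix(counts=sparse.csr_matrix(counts), features=features, cells=cells)


class TestIO:
    def test_round_trip_preserves_counts_and_metadata(self, tmp_path):
        cfg = CountSimConfig(n_cells=50, n_genes=30, n_marker_genes_per_type=5,
                             transduction_prob=0.2, seed=14)
        mat, _ = simulate_counts(cfg)
        write_barcode_matrix(mat, tmp_path)
        back = read_barcode_matrix(tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                                   tmp_path / "barcodes.tsv")
        assert (back.counts != mat.counts).nnz == 0
        assert list(back.features["kind"]) == list(mat.features["kind"])
        assert back.variant_names == mat.variant_names
        assert list(back.cells["cell_id"]) == list(mat.cells["cell_id"])

    def test_explicit_zero_entries_match_dense(self, tmp_path):
        """An MTX that stores explicit zeros must read back equal to dense."""
        mtx = tmp_path / "m.mtx"
        mtx.write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "4 5 4\n"   # features x cells, 1-based
            "1 1 3\n"
            "2 2 0\n"
            "3 4 7\n"
            "4 5 1\n"
        )
        (tmp_path / "f.tsv").write_text(
            "g1\tg1\tgene\ng2\tg2\tgene\ng3\tg3\tgene\nbcV\tV\tviral_barcode:V\n")
        (tmp_path / "c.tsv").write_text("cell_id\nc1\nc2\nc3\nc4\nc5\n")
        mat = read_barcode_matrix(mtx, tmp_path / "f.tsv", tmp_path / "c.tsv")
        dense = np.zeros((5, 4))
        dense[0, 0] = 3
        dense[3, 2] = 7
        dense[4, 3] = 1
        assert np.array_equal(mat.counts.toarray(), dense)

    def test_empty_matrix_valid(self):
        mat = tiny_matrix(np.zeros((0, 3)), variants=("V1",))
        assert mat.n_cells == 0
        assert mat.variant_names == ["V1"]

    def test_dimension_mismatch_rejected(self, tmp_path):
        cfg = CountSimConfig(n_cells=5, n_genes=10, n_marker_genes_per_type=2, seed=1)
        mat, _ = simulate_counts(cfg)
        write_barcode_matrix(mat, tmp_path)
        (tmp_path / "c.tsv").write_text("cell_id\nc1\nc2\n")
        with pytest.raises(ValueError):
            read_barcode_matrix(tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                                tmp_path / "c.tsv")


class TestTransductionCalls:
    def test_all_zero_barcodes_no_calls(self):
        mat = tiny_matrix([[5, 0, 0], [3, 0, 0]], variants=("V1", "V2"))
        calls = call_transduced(mat)
        assert calls.any_viral.sum() == 0

    def test_multi_variant_cell_counted_per_variant(self):
        mat = tiny_matrix([[0, 2, 1]], variants=("V1", "V2"))
        calls = call_transduced(mat, threshold_umis=1)
        assert calls.per_variant.iloc[0].tolist() == [True, True]
        assert calls.any_viral.sum() == 1
        totals = variant_totals(calls).set_index("variant")["n_transduced"]
        assert totals.sum() == 2

    def test_threshold_respected(self):
        mat = tiny_matrix([[0, 2, 1]], variants=("V1", "V2"))
        calls = call_transduced(mat, threshold_umis=2)
        assert calls.per_variant.iloc[0].tolist() == [True, False]

    def test_threshold_below_one_rejected(self):
        mat = tiny_matrix([[0, 1, 0]], variants=("V1", "V2"))
        with pytest.raises(ValueError):
            call_transduced(mat, threshold_umis=0)

    def test_totals_match_simulation_truth_exactly(self):
        cfg = CountSimConfig(n_cells=1000, n_genes=50, n_marker_genes_per_type=5,
                             transduction_prob=0.05, seed=15)
        mat, truth = simulate_counts(cfg)
        totals = variant_totals(call_transduced(mat)).set_index("variant")["n_transduced"]
        for v in mat.variant_names:
            assert totals[v] == truth.cells[v].sum()

    def test_per_sample_totals(self):
        mat = tiny_matrix([[0, 1, 0], [0, 0, 1], [0, 1, 1]], variants=("V1", "V2"),
                          cells_extra={"sample_id": ["s1", "s2", "s2"]})
        out = variant_totals(call_transduced(mat), by_sample=True)
        lut = out.set_index(["sample_id", "variant"])["n_transduced"]
        assert lut[("s1", "V1")] == 1 and lut[("s2", "V1")] == 1
        assert lut[("s1", "V2")] == 0 and lut[("s2", "V2")] == 2


class TestHeatmap:
    def test_simple_percentage(self):
        counts = np.zeros((10, 3))
        counts[:3, 1] = 1  # 3 of 10 cells positive for V1
        mat = tiny_matrix(counts, variants=("V1", "V2"))
        ann = pd.Series("T", index=pd.Index([f"c{i}" for i in range(10)], name="cell_id"))
        heat = celltype_transduction_heatmap(call_transduced(mat), ann)
        assert heat.loc["T", "V1"] == 30.0
        assert heat.loc["T", "V2"] == 0.0

    def test_unannotated_cells_excluded(self):
        counts = np.zeros((4, 2))
        counts[0, 1] = 1
        mat = tiny_matrix(counts, variants=("V1",))
        ann = pd.Series(["T", "T"], index=pd.Index(["c0", "c1"], name="cell_id"))
        heat = celltype_transduction_heatmap(call_transduced(mat), ann)
        assert heat.loc["T", "V1"] == 50.0

    def test_no_annotated_cells_rejected(self):
        mat = tiny_matrix(np.zeros((2, 2)), variants=("V1",))
        ann = pd.Series(dtype=object)
        with pytest.raises(ValueError):
            celltype_transduction_heatmap(call_transduced(mat), ann)

    def test_entries_bounded_by_any_viral_rate(self):
        """Union bound: per-variant rate within a type <= any-viral rate."""
        cfg = CountSimConfig(n_cells=2000, n_genes=30, n_marker_genes_per_type=5,
                             transduction_prob=0.08, seed=16)
        mat, truth = simulate_counts(cfg)
        calls = call_transduced(mat)
        ann = truth.cells.set_index("cell_id")["cell_type"]
        heat = celltype_transduction_heatmap(calls, ann)
        any_rate = calls.any_viral.groupby(ann.reindex(calls.per_variant.index).to_numpy()).mean()
        for t in heat.index:
            assert (heat.loc[t] <= 100 * any_rate[t] + 1e-9).all()


class TestRankSum:
    def test_exact_p_matches_enumeration(self):
        """Exact rank-sum p equals enumeration over all group assignments."""
        rng = np.random.default_rng(41)
        for nx, ny in [(3, 4), (5, 5), (8, 6)]:
            x = rng.normal(0.5, 1, nx)
            y = rng.normal(0, 1, ny)
            p = wilcoxon_rank_sum(x, y, exact=True)
            # enumeration oracle: distribution of the rank sum under the null
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            obs = ranks[:nx].sum()
            sums = np.array([sum(c) for c in itertools.combinations(ranks, nx)])
            mu = sums.mean()
            p_oracle = np.mean(np.abs(sums - mu) >= np.abs(obs - mu) - 1e-9)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_asymptotic_close_to_exact_moderate_n(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            wilcoxon_rank_sum(x, y, exact=True), abs=0.02)


class TestDifferentialExpression:
    def test_constant_gene_null_result(self):
        counts = np.ones((6, 4))
        counts[:, 2:] = 0  # two barcode columns
        counts[:3, 1] = 5  # gene g1 differs; g0 constant
        mat = tiny_matrix(counts, variants=("V1", "V2"))
        ann = pd.Series(["A"] * 3 + ["B"] * 3,
                        index=pd.Index([f"c{i}" for i in range(6)], name="cell_id"))
        de = per_type_differential_expression(mat, ann)
        g0 = de.table[de.table["gene"] == "g0"]
        # g0 is constant in raw counts but normalization makes it vary;
        # a gene constant after normalization gets p = 1 and log2fc = 0
        counts2 = np.ones((6, 4))
        counts2[:, 2:] = 0
        mat2 = tiny_matrix(counts2, variants=("V1", "V2"))
        de2 = per_type_differential_expression(mat2, ann)
        assert (de2.table["p"] == 1.0).all()
        assert (de2.table["log2fc"] == 0.0).all()
        assert len(g0) == 2  # one row per type, still reported

    def test_marker_genes_recovered(self):
        cfg = CountSimConfig(n_cells=600, n_genes=200, n_marker_genes_per_type=10,
                             marker_fold_change=6.0, transduction_prob=0.0, seed=18)
        mat, truth = simulate_counts(cfg)
        ann = truth.cells.set_index("cell_id")["cell_type"]
        de = per_type_differential_expression(mat, ann)
        sig = de.significant()
        for t, markers in truth.marker_genes.items():
            recovered = set(markers) & set(sig.get(t, []))
            assert len(recovered) >= 8  # at least 8 of 10 markers

    def test_small_type_skipped_with_warning(self):
        counts = np.random.default_rng(19).poisson(5, size=(8, 6)).astype(float)
        counts[:, 4:] = 0
        mat = tiny_matrix(counts, variants=("V1", "V2"))
        ann = pd.Series(["A"] * 4 + ["B"] + ["C"] * 3,
                        index=pd.Index([f"c{i}" for i in range(8)], name="cell_id"))
        de = per_type_differential_expression(mat, ann, min_cells=2)
        assert de.skipped_types == ["B"]
        assert set(de.table["cell_type"]) == {"A", "C"}

    def test_barcode_features_excluded_from_gene_universe(self):
        cfg = CountSimConfig(n_cells=200, n_genes=50, n_marker_genes_per_type=5,
                             transduction_prob=0.5, seed=20)
        mat, truth = simulate_counts(cfg)
        ann = truth.cells.set_index("cell_id")["cell_type"]
        de = per_type_differential_expression(mat, ann)
        assert not set(de.table["gene"]) & set(mat.variant_names)


class TestLog2fcCorrelation:
    def test_self_correlation_diagonal_is_one(self):
        cfg = CountSimConfig(n_cells=400, n_genes=100, n_marker_genes_per_type=10,
                             marker_fold_change=5.0, transduction_prob=0.0, seed=22)
        mat, truth = simulate_counts(cfg)
        ann = truth.cells.set_index("cell_id")["cell_type"]
        de = per_type_differential_expression(mat, ann)
        corr = log2fc_correlation(de, de)
        diag = corr.diagonal()
        assert len(diag) >= 2
        assert np.allclose(diag, 1.0, atol=1e-12)

    def test_hand_computed_five_gene_pearson(self):
        """r on a fixed 5-gene log2FC pair equals the closed-form value."""
        from aavtropism.barcodes import DEResult

        lfc_a = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        lfc_b = np.array([0.8, -0.2, 1.5, 0.0, -1.0])
        genes = [f"g{i}" for i in range(5)]

        def mk(lfc):
            return DEResult(table=pd.DataFrame({
                "cell_type": "T", "gene": genes, "log2fc": lfc,
                "mean_in": 1.0, "mean_out": 1.0, "p": 1e-6, "p_adjusted": 1e-5,
            }))

        corr = log2fc_correlation(mk(lfc_a), mk(lfc_b))
        ca, cb = lfc_a - lfc_a.mean(), lfc_b - lfc_b.mean()
        r_closed = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        assert corr.r.loc["T", "T"] == pytest.approx(r_closed, abs=1e-12)
        assert corr.n_genes.loc["T", "T"] == 5

    def test_too_few_shared_genes_is_missing_not_zero(self):
        from aavtropism.barcodes import DEResult

        def mk(present):
            return DEResult(table=pd.DataFrame({
                "cell_type": "T", "gene": ["g0", "g1", "g2"],
                "log2fc": [1.0, 2.0, 3.0],
                "mean_in": present, "mean_out": 1.0,
                "p": 1e-6, "p_adjusted": 1e-5,
            }))

        corr = log2fc_correlation(mk([1.0, 1.0, 0.0]), mk([1.0, 0.0, 0.0]))
        assert np.isnan(corr.r.loc["T", "T"])
        assert corr.n_genes.loc["T", "T"] == 1


class TestComposition:
    def test_fractions_sum_to_one_per_day(self):
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(8)],
                              "day": [0, 0, 0, 0, 14, 14, 14, 14]})
        ann = pd.Series(["N", "N", "A", "O", "A", "A", "O", "A"],
                        index=pd.Index(cells["cell_id"], name="cell_id"))
        comp = composition_by_day(cells, ann)
        assert np.allclose(comp.sum(axis=1), 1.0)
        assert comp.loc[0, "N"] == 0.5
        assert comp.loc[14].get("N", 0.0) == 0.0

    def test_single_type_fraction_one(self):
        cells = pd.DataFrame({"cell_id": ["c0", "c1"], "day": [0, 0]})
        ann = pd.Series(["A", "A"], index=pd.Index(cells["cell_id"], name="cell_id"))
        comp = composition_by_day(cells, ann)
        assert comp.loc[0, "A"] == 1.0

    def test_neuron_depletion_recovered(self):
        """Day-14 neuron loss configured in the generator shows up in the
        composition table (day 0: 35% neurons; day 14: strong depletion)."""
        day0 = CountSimConfig(n_cells=2000, n_genes=30, n_marker_genes_per_type=5,
                              transduction_prob=0.0, day=0, sample_id="d0", seed=24)
        frac14 = {"Glutamatergic neuron": 0.04, "Astrocyte": 0.46,
                  "Oligodendrocyte": 0.30, "Microglia": 0.20}
        day14 = CountSimConfig(n_cells=2000, n_genes=30, n_marker_genes_per_type=5,
                               transduction_prob=0.0,
                               cell_type_fractions=frac14, day=14,
                               sample_id="d14", seed=25)
        m0, t0 = simulate_counts(day0)
        m14, t14 = simulate_counts(day14)
        cells = pd.concat([m0.cells, m14.cells], ignore_index=True)
        ann = pd.concat([t0.cells, t14.cells]).set_index("cell_id")["cell_type"]
        comp = composition_by_day(cells, ann)
        assert comp.loc[0, "Glutamatergic neuron"] == pytest.approx(0.35, abs=0.03)
        assert comp.loc[14, "Glutamatergic neuron"] == pytest.approx(0.04, abs=0.02)

    def test_missing_day_column_rejected(self):
        with pytest.raises(ValueError):
            composition_by_day(pd.DataFrame({"cell_id": ["c0"]}), pd.Series(dtype=object))
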