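"""QC cascade: filters, normalizations and doublet scoring."""

import numpy as np
import pandas as pd
import pytest

from mopatlas import synth
from mopatlas.qc import (
    CellByGeneMatrix,
    batch_normalize,
    doublet_scores,
    filter_by_volume,
    normalize_by_volume,
    quantile_count_filter,
    remove_doublets,
    run_qc,
    sequential_artifact_filter,
    subtract_channel_background,
)


def cells_frame(volumes, batches=None):
    n = len(volumes)
    return pd.DataFrame({
        "x": np.zeros(n), "y": np.zeros(n),
        "volume": volumes,
        "slice_id": np.zeros(n, int),
        "batch_id": batches if batches is not None else np.zeros(n, int),
    }, index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))


def flagged(cells, reason=None):
    if reason is None:
        return [i for i, f in cells["qc_flags"].items() if f]
    return [i for i, f in cells["qc_flags"].items() if reason in f]


class TestVolumeFilter:
    def test_hand_evaluated_rule(self):
        cells = filter_by_volume(cells_frame([50, 120, 150, 200, 1000]))
        # median 150 -> cutoffs (100, 450); 50 and 1000 flagged
        assert flagged(cells, "volume") == ["c0", "c4"]

    def test_equal_volumes_pass(self):
        cells = filter_by_volume(cells_frame([300.0] * 5))
        assert flagged(cells) == []

    def test_boundary_volume_100_is_kept(self):
        cells = filter_by_volume(cells_frame([100, 150, 150, 150, 200]))
        assert flagged(cells) == []


class TestNormalization:
    def test_counts_to_density(self):
        mat = CellByGeneMatrix(pd.DataFrame({"g": [500.0]}, index=["c0"]))
        cells = cells_frame([250.0])
        out = normalize_by_volume(mat, cells)
        assert out.values.loc["c0", "g"] == pytest.approx(2.0)
        assert out.state == "volume_normalized"

    def test_volume_homogeneity(self):
        vals = pd.DataFrame({"g1": [10.0, 10.0], "g2": [4.0, 4.0]},
                            index=["c0", "c1"])
        cells = cells_frame([100.0, 200.0])
        out = normalize_by_volume(CellByGeneMatrix(vals), cells)
        assert np.allclose(out.values.loc["c0"], 2 * out.values.loc["c1"])

    def test_zero_volume_rejected(self):
        mat = CellByGeneMatrix(pd.DataFrame({"g": [1.0]}, index=["c0"]))
        with pytest.raises(ValueError):
            normalize_by_volume(mat, cells_frame([0.0]))

    def test_batch_means_hit_the_target_and_within_batch_ratios_survive(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.poisson(5.0, size=(200, 10)).astype(float),
                            index=[f"c{i}" for i in range(200)])
        batches = np.array([0] * 100 + [1] * 100)
        vals.iloc[100:] *= 1.3          # ~30% batch effect
        cells = cells_frame(np.full(200, 300.0), batches)
        mat = CellByGeneMatrix(vals.copy(), state="volume_normalized")
        out = batch_normalize(mat, cells, target_mean=250.0)
        totals = out.values.sum(axis=1)
        for b in (0, 1):
            assert totals[batches == b].mean() == pytest.approx(250.0)
        r_before = vals.iloc[0] / vals.iloc[1].replace(0, np.nan)
        r_after = out.values.iloc[0] / out.values.iloc[1].replace(0, np.nan)
        assert np.allclose(r_before.dropna(), r_after.dropna())


class TestSequentialFilters:
    def test_planted_artifact_cells_flagged_exactly(self):
        rng = np.random.default_rng(2)
        sig = pd.DataFrame(rng.lognormal(0, 0.3, size=(100, 16)),
                           index=[f"c{i}" for i in range(100)])
        bad = ["c5", "c42", "c77"]
        thr_vals = sig.quantile(0.90)
        for b in bad:
            cols = rng.choice(16, size=13, replace=False)
            sig.loc[b, sig.columns[cols]] = thr_vals.iloc[cols].values * 3
        cells = cells_frame(np.full(100, 300.0))
        cells = sequential_artifact_filter(cells, sig)
        assert sorted(flagged(cells, "sequential_artifact")) == sorted(bad)

    def test_cell_above_in_11_of_16_channels_is_kept(self):
        sig = pd.DataFrame(np.ones((50, 16)),
                           index=[f"c{i}" for i in range(50)])
        sig.iloc[0, :11] = 100.0
        cells = sequential_artifact_filter(cells_frame(np.full(50, 300.0)), sig)
        assert flagged(cells) == []

    def test_background_subtraction_hand_computed(self):
        sig = pd.DataFrame({"a1": [5.0, 2.0], "a2": [3.0, 2.0],
                            "b1": [10.0, 0.0], "b2": [7.0, 4.0]},
                           index=["c0", "c1"])
        out = subtract_channel_background(sig, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out.loc["c0"].tolist() == [2.0, 0.0, 3.0, 0.0]
        assert out.loc["c1"].tolist() == [0.0, 0.0, 0.0, 4.0]

    def test_constant_group_zeroes_and_all_zero_passthrough(self):
        sig = pd.DataFrame(np.full((3, 2), 9.0), columns=["a", "b"])
        out = subtract_channel_background(sig, {"G": ["a", "b"]})
        assert (out.values == 0).all()
        zero = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        assert (subtract_channel_background(zero, {"G": ["a", "b"]}).values == 0).all()


class TestQuantileFilter:
    def test_distinct_totals_flag_two_each_side(self):
        vals = pd.DataFrame({"g": np.arange(100, dtype=float) + 1},
                            index=[f"c{i}" for i in range(100)])
        mat = CellByGeneMatrix(vals, state="batch_normalized")
        cells = quantile_count_filter(mat, cells_frame(np.full(100, 300.0)))
        assert sorted(flagged(cells, "count_quantile")) == ["c0", "c1", "c98", "c99"]

    def test_equal_totals_and_degenerate_bounds_flag_nothing(self):
        vals = pd.DataFrame({"g": np.full(50, 7.0)},
                            index=[f"c{i}" for i in range(50)])
        mat = CellByGeneMatrix(vals, state="batch_normalized")
        assert flagged(quantile_count_filter(mat, cells_frame(np.full(50, 300.0)))) == []
        vals2 = pd.DataFrame({"g": np.arange(50, dtype=float)},
                             index=[f"c{i}" for i in range(50)])
        mat2 = CellByGeneMatrix(vals2, state="batch_normalized")
        cells = quantile_count_filter(mat2, cells_frame(np.full(50, 300.0)),
                                      low=0.0, high=1.0)
        assert flagged(cells) == []


class TestDoubletScoring:
    def two_blob_matrix(self, seed, n=400, n_doublets=40):
        rng = np.random.default_rng(seed)
        a = rng.poisson(20.0, size=(n // 2, 20)).astype(float)
        b = rng.poisson(20.0, size=(n // 2, 20)).astype(float)
        a[:, :10] *= 5
        b[:, 10:] *= 5
        singlets = np.vstack([a, b])
        pairs = rng.integers(0, n // 2, size=(n_doublets, 2))
        doublets = a[pairs[:, 0]] + b[pairs[:, 1]]
        X = np.vstack([singlets, doublets])
        idx = [f"c{i}" for i in range(len(X))]
        truth = np.array([False] * n + [True] * n_doublets)
        return CellByGeneMatrix(pd.DataFrame(X, index=idx)), truth

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_doublets_score_above_singlets_across_seeds(self, seed):
        mat, truth = self.two_blob_matrix(seed)
        s = doublet_scores(mat, expected_rate=0.1, seed=seed)
        assert np.median(s[truth]) > np.median(s[~truth])

    def test_scores_bounded_and_deterministic(self):
        mat, _ = self.two_blob_matrix(3)
        s1 = doublet_scores(mat, seed=11)
        s2 = doublet_scores(mat, seed=11)
        assert ((s1 >= 0) & (s1 <= 1)).all()
        assert np.allclose(s1.values, s2.values)

    def test_identical_cells_get_flat_scores(self):
        mat = CellByGeneMatrix(pd.DataFrame(np.full((100, 10), 9.0),
                                            index=[f"c{i}" for i in range(100)]))
        s = doublet_scores(mat, seed=0)
        assert s.std() < 0.1

    def test_threshold_semantics(self):
        scores = pd.Series([0.05, 0.18, 0.30], index=["a", "b", "c"])
        cells = cells_frame(np.full(3, 300.0))
        cells.index = ["a", "b", "c"]
        out = remove_doublets(cells, scores, threshold=0.18)
        assert flagged(out, "doublet") == ["c"]           # strict inequality
        out2 = remove_doublets(cells, scores, threshold=1.0)
        assert flagged(out2, "doublet") == []


class TestFullCascade:
    def test_report_reconciles_and_order_invariance(self, atlas6k, channel_groups):
        mat, cells, report = run_qc(atlas6k.matrix, atlas6k.cells, atlas6k.sequential,
                                    channel_groups=channel_groups,
                                    dropped_genes=synth.DROPPED_SEQ_GENES, seed=3)
        assert report.n_input == len(atlas6k.cells)
        assert report.n_kept == len(mat.cell_ids)
        assert report.n_input - report.n_kept == report.total_removed
        n_flagged = sum(bool(f) for f in cells["qc_flags"])
        assert n_flagged == report.total_removed
        # dropped genes are gone, state is batch-normalized
        assert not set(synth.DROPPED_SEQ_GENES) & set(mat.gene_names)
        assert mat.state == "batch_normalized"
        # cell order does not change what the deterministic stages remove
        # (the doublet stage samples simulated pairs, so it is seed- but not
        # order-stable; its flags are excluded from the comparison)
        perm = np.random.default_rng(0).permutation(len(atlas6k.cells))
        mat2, cells2, report2 = run_qc(
            CellByGeneMatrix(atlas6k.matrix.values.iloc[perm]),
            atlas6k.cells.iloc[perm], atlas6k.sequential.iloc[perm],
            channel_groups=channel_groups,
            dropped_genes=synth.DROPPED_SEQ_GENES, seed=3)

        def det_flagged(c):
            return {i for i, f in c["qc_flags"].items() if f - {"doublet"}}

        assert det_flagged(cells2) == det_flagged(cells)

    def test_batch_means_equal_250_after_batch_stage(self, atlas6k):
        # a ~30% between-batch difference in raw mean totals disappears
        raw_totals = atlas6k.matrix.totals()
        raw_means = raw_totals.groupby(atlas6k.cells["batch_id"]).mean()
        assert raw_means.max() / raw_means.min() > 1.2
        vnorm = normalize_by_volume(atlas6k.matrix, atlas6k.cells)
        bnorm = batch_normalize(vnorm, atlas6k.cells, target_mean=250.0)
        means = bnorm.totals().groupby(atlas6k.cells["batch_id"]).mean()
        assert np.allclose(means.values, 250.0)
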