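"""Marker-panel selection and probe design."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mopatlas.panel import (
    ReferenceExpression,
    binary_mutual_information,
    de_genes_for_pair,
    design_encoding_probes,
    greedy_marker_cover,
    mutual_information_ranking,
    probe_capacity,
    screen_for_sequential,
)


def make_ref(matrix, labels, class_of=None):
    df = pd.DataFrame(matrix, columns=[f"g{i}" for i in range(np.shape(matrix)[1])])
    labels = pd.Series(labels, index=df.index)
    if class_of is None:
        class_of = {c: "excitatory" for c in labels.unique()}
    return ReferenceExpression(matrix=df, labels=labels, class_of=class_of)


class TestMutualInformation:
    def test_deterministic_binary_channel_gives_one_bit(self):
        on = np.array([1] * 50 + [0] * 50, dtype=bool)
        labels = np.array(["A"] * 50 + ["B"] * 50)
        assert binary_mutual_information(on, labels) == pytest.approx(1.0)

    def test_independent_gene_gives_zero_bits(self):
        on = np.tile([True, False], 50)
        labels = np.array(["A", "A", "B", "B"] * 25)
        assert binary_mutual_information(on, labels) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value_p08_p02_equal_priors(self):
        # I(X;Y) = H(X) - H(X|Y) = 1 - H2(0.8) = 0.27807 bits (frozen closed form)
        on = np.array([True] * 80 + [False] * 20 + [True] * 20 + [False] * 80)
        labels = np.array(["A"] * 100 + ["B"] * 100)
        assert binary_mutual_information(on, labels) == pytest.approx(0.2781, abs=1e-4)

    def test_ranking_invariant_to_cell_order_and_monotone_transform(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(1.0, size=(120, 8))
        labels = np.array(["A", "B"] * 60)
        ref = make_ref(mat, labels)
        ranked = mutual_information_ranking(ref, "excitatory", top_n=8)
        perm = rng.permutation(120)
        ref2 = make_ref(mat[perm], labels[perm])
        assert mutual_information_ranking(ref2, "excitatory", top_n=8) == ranked
        ref3 = make_ref(mat ** 2 * 7, labels)  # monotone, zero-preserving
        assert mutual_information_ranking(ref3, "excitatory", top_n=8) == ranked

    def test_single_cluster_group_rejected(self):
        ref = make_ref(np.ones((10, 3)), ["A"] * 10)
        with pytest.raises(ValueError):
            mutual_information_ranking(ref, "excitatory", 3)


class TestDifferentialExpression:
    def build_toy(self):
        # 10 cells/cluster, 6 genes engineered against the four criteria:
        # g0 passes all; g1 fold-change 1.5 only; g2 low fg fraction;
        # g3 enrichment ratio <= 3; g4 flat; g5 passes all.
        fg = np.zeros((10, 6))
        bg = np.zeros((10, 6))
        fg[:, 0] = [10, 12, 9, 11, 10, 13, 9, 10, 12, 10]
        bg[:, 0] = [1, 0, 2, 0, 0, 0, 0, 1, 0, 0]   # expressing 3/10 -> ratio 3.3
        fg[:, 1] = 3.0
        bg[:, 1] = [2] * 10
        fg[:, 2] = [20, 18, 0, 0, 0, 0, 0, 0, 0, 0]   # fg fraction 0.2
        bg[:, 2] = 0.0
        fg[:, 3] = [5] * 10                            # expressing 10/10
        bg[:, 3] = [1, 1, 1, 1, 0, 0, 2, 1, 1, 1]      # expressing 9/10 -> ratio 1.1
        fg[:, 4] = 1.0
        bg[:, 4] = 1.0
        fg[:, 5] = [8, 7, 9, 8, 7, 9, 8, 8, 7, 9]
        bg[:, 5] = [0, 1, 0, 0, 1, 0, 0, 0, 1, 0]
        mat = np.vstack([fg, bg])
        labels = ["FG"] * 10 + ["BG"] * 10
        return make_ref(mat, labels)

    def test_toy_pair_passes_exactly_the_hand_checked_genes(self):
        ref = self.build_toy()
        got = de_genes_for_pair(ref, "FG", "BG", top_n=10)
        assert set(got) == {"g0", "g5"}

    def test_removing_any_criterion_grows_or_preserves_the_list(self):
        ref = self.build_toy()
        base = set(de_genes_for_pair(ref, "FG", "BG", top_n=10))
        assert base <= set(de_genes_for_pair(ref, "FG", "BG", 10, fold=0.0))
        assert base <= set(de_genes_for_pair(ref, "FG", "BG", 10, p_max=1.1))
        assert base <= set(de_genes_for_pair(ref, "FG", "BG", 10, min_fg_fraction=0.0))
        assert base <= set(de_genes_for_pair(ref, "FG", "BG", 10, min_enrichment=0.0))

    def test_zero_background_expression_counts_as_infinite_enrichment(self):
        ref = self.build_toy()
        got = de_genes_for_pair(ref, "FG", "BG", top_n=10)
        assert "g0" in got  # bg fraction < 1 but fg/bg mean and fraction rules hold

    def test_tiny_cluster_rejected(self):
        ref = make_ref(np.ones((3, 2)), ["A", "B", "B"])
        with pytest.raises(ValueError):
            de_genes_for_pair(ref, "A", "B", 5)


class TestGreedyCover:
    def test_already_covered_seed_adds_nothing(self):
        cands = {("A", "B"): ["m1", "m2"], ("B", "A"): ["m1", "m2"]}
        sel = greedy_marker_cover(cands, seed_panel=["m1", "m2"], min_per_direction=2)
        assert sel.de_selected == []
        assert sel.uncoverable == []

    def test_greedy_matches_bruteforce_minimum_on_toy_instance(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        cands = {
            ("A", "B"): ["g1", "g4"], ("B", "A"): ["g2", "g5"],
            ("A", "C"): ["g1", "g3"], ("C", "A"): ["g2"],
            ("B", "C"): ["g1"], ("C", "B"): ["g2", "g4"],
        }
        sel = greedy_marker_cover(cands, seed_panel=[], min_per_direction=1)
        # brute force: smallest subset covering every ordered pair once
        best = None
        for r in range(1, len(genes) + 1):
            for sub in itertools.combinations(genes, r):
                if all(any(g in cands[p] for g in sub) for p in cands):
                    best = sub
                    break
            if best:
                break
        assert len(sel.de_selected) == len(best)
        assert sel.uncoverable == []

    def test_empty_direction_is_flagged_uncoverable(self):
        cands = {("A", "B"): ["g1"], ("B", "A"): []}
        sel = greedy_marker_cover(cands, seed_panel=[], min_per_direction=1)
        assert ("B", "A") in sel.uncoverable
        assert ("A", "B") not in sel.uncoverable

    def test_output_panel_contains_the_seed(self):
        cands = {("A", "B"): ["g1"], ("B", "A"): ["g2"]}
        sel = greedy_marker_cover(cands, seed_panel=["m"], min_per_direction=1)
        assert "m" in sel.final_panel


class TestSequentialScreen:
    def test_rules_split_a_constructed_panel(self):
        rng = np.random.default_rng(1)
        labels = ["A"] * 20 + ["B"] * 20
        mat = rng.poisson(5.0, size=(40, 4)).astype(float)
        mat[:20, 2] = 260.0                     # cluster-mean rule fires
        ref = make_ref(mat, labels)
        transcripts = {"g0": "A" * 4000, "g1": "A" * 300,   # capacity 28 < 48
                       "g2": "A" * 4000, "g3": "A" * 500}   # capacity 48, mean low
        comb, seq = screen_for_sequential(ref, ["g0", "g1", "g2", "g3"], transcripts)
        assert comb == ["g0", "g3"]
        assert seq == ["g1", "g2"]

    def test_missing_transcript_raises(self):
        ref = make_ref(np.ones((4, 1)), ["A", "A", "B", "B"])
        with pytest.raises(KeyError):
            screen_for_sequential(ref, ["g0"], {})


class TestProbeDesign:
    def test_capacity_formula(self):
        assert probe_capacity(1000, 30, 20) == 98
        assert probe_capacity(500, 30, 20) == 48
        assert probe_capacity(30, 30, 20) == 1
        assert probe_capacity(29, 30, 20) == 0

    @pytest.mark.parametrize("L,n_expected", [(4000, 92), (1000, 92), (500, 48), (30, 1)])
    def test_probe_counts_follow_capacity(self, L, n_expected):
        barcode = np.zeros(22, dtype=int)
        barcode[[1, 5, 9, 13]] = 1
        ps = design_encoding_probes("ACGT" * (L // 4 + 1), "combinatorial",
                                    n_probes=92, barcode=barcode, seed=0)
        # trim transcript length exactly
        ps = design_encoding_probes("A" * L, "combinatorial", 92, barcode=barcode, seed=0)
        assert len(ps.probes) == n_expected

    def test_targets_stay_inside_transcript_and_overlap_bounded(self):
        barcode = np.zeros(22, dtype=int)
        barcode[[0, 1, 2, 3]] = 1
        L = 700
        ps = design_encoding_probes("A" * L, "combinatorial", 92, barcode=barcode, seed=3)
        starts = sorted(p.target_start for p in ps.probes)
        assert all(0 <= s <= L - 30 for s in starts)
        overlaps = [30 - (b - a) for a, b in zip(starts, starts[1:])]
        assert max(overlaps) <= 20

    def test_combinatorial_probes_carry_two_onbit_readouts_balanced(self):
        barcode = np.zeros(22, dtype=int)
        on = [2, 7, 11, 19]
        barcode[on] = 1
        ps = design_encoding_probes("A" * 4000, "combinatorial", 92, barcode=barcode, seed=0)
        used = [r for p in ps.probes for r in p.readout_ids]
        assert all(len(p.readout_ids) == 2 for p in ps.probes)
        assert set(used) == set(on)
        counts = pd.Series(used).value_counts()
        assert counts.max() - counts.min() <= 2  # near-equal usage

    def test_all_onbits_covered_with_at_least_four_probes(self):
        barcode = np.zeros(8, dtype=int)
        barcode[[0, 2, 4, 6]] = 1
        ps = design_encoding_probes("A" * 200, "combinatorial", 4, barcode=barcode, seed=5)
        assert set(r for p in ps.probes for r in p.readout_ids) == {0, 2, 4, 6}

    def test_sequential_probes_carry_one_gene_readout(self):
        ps = design_encoding_probes("A" * 2000, "sequential", 48, readout_id=25, seed=0)
        assert len(ps.probes) == 48
        assert all(p.readout_ids == (25,) for p in ps.probes)

    def test_too_short_transcript_raises(self):
        with pytest.raises(ValueError):
            design_encoding_probes("A" * 10, "sequential", 5, readout_id=1)
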