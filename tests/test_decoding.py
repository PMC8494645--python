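"""Pixel decoding, misidentification filtering and segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from mopatlas import synth
from mopatlas.codebook import build_codebook
from mopatlas.decoding import (
    DecodedMolecule,
    ImageStack,
    adaptive_misid_filter,
    assign_molecules,
    combined_quality,
    counts_from_molecules,
    estimate_misid_rate,
    pixel_decode,
    preprocess_stack,
    segment_cells,
)


@pytest.fixture(scope="module")
def cb(codebook22):
    return codebook22


def match_stats(mols, gt, pixel_size, tol_px=3.0):
    """Fraction of molecules matching ground truth, and of truth recovered."""
    if not mols or not gt:
        return 0.0, 0.0
    gt_xy = np.array([(x, y) for x, y, _ in gt])
    gt_nm = [n for _, _, n in gt]
    mol_xy = np.array([(m.x, m.y) for m in mols])
    mol_nm = [m.entry for m in mols]
    t_gt, t_mol = cKDTree(gt_xy), cKDTree(mol_xy)
    tol = tol_px * pixel_size
    prec = np.mean([t_gt.query([m.x, m.y])[0] < tol
                    and gt_nm[t_gt.query([m.x, m.y])[1]] == m.entry for m in mols])
    rec = np.mean([t_mol.query([x, y])[0] < tol
                   and mol_nm[t_mol.query([x, y])[1]] == n for x, y, n in gt])
    return float(prec), float(rec)


class TestPreprocess:
    def test_flat_image_zeroed_by_highpass(self):
        stack = ImageStack(pixels=np.full((3, 32, 32), 7.0))
        out = preprocess_stack(stack, highpass_sigma=3, lr_iterations=0, lowpass_sigma=0)
        assert np.allclose(out.pixels, 0.0)

    def test_identity_when_all_steps_disabled(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(pixels=rng.random((2, 16, 16)))
        out = preprocess_stack(stack, highpass_sigma=0, lr_iterations=0, lowpass_sigma=0)
        assert np.allclose(out.pixels, stack.pixels)

    def test_gaussian_spot_centroid_preserved(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.exp(-((xx - 30.3) ** 2 + (yy - 33.7) ** 2) / (2 * 1.5 ** 2))
        stack = ImageStack(pixels=img[None, :, :])
        out = preprocess_stack(stack, highpass_sigma=5, lr_iterations=20, lowpass_sigma=1)
        cy, cx = ndi.center_of_mass(out.pixels[0])
        assert abs(cx - 30.3) < 0.5 and abs(cy - 33.7) < 0.5

    def test_negative_parameters_rejected(self):
        stack = ImageStack(pixels=np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            preprocess_stack(stack, highpass_sigma=-1)


class TestPixelDecode:
    def test_noiseless_field_fully_recovered(self, cb):
        stack = synth.generate_spot_stack(cb, n_molecules=200, size=160, seed=3,
                                          entries=cb.gene_names)
        mols = pixel_decode(stack, cb)
        prec, rec = match_stats(mols, stack.ground_truth, stack.pixel_size)
        assert prec == 1.0 and rec == 1.0
        assert sum(m.entry.startswith("Blank") for m in mols) == 0

    def test_dropped_bit_recovered_by_error_correction(self, cb):
        stack = synth.generate_spot_stack(cb, n_molecules=40, size=96, seed=5,
                                          entries=cb.gene_names[:1], bit_dropout=0.0)
        gene = cb.gene_names[0]
        # zero out one on-bit round entirely
        on_bits = np.flatnonzero(cb.barcode_of(gene))
        stack.pixels[on_bits[0]] = 0.0
        mols = pixel_decode(stack, cb)
        assert mols and all(m.entry == gene and m.n_corrected == 1 for m in mols)

    def test_empty_stack_gives_empty_list(self, cb):
        stack = ImageStack(pixels=np.zeros((22, 32, 32)))
        assert pixel_decode(stack, cb) == []

    def test_round_count_mismatch_raises(self, cb):
        stack = ImageStack(pixels=np.zeros((10, 8, 8)))
        with pytest.raises(ValueError):
            pixel_decode(stack, cb)

    def test_invariant_to_global_intensity_scaling(self, cb):
        stack = synth.generate_spot_stack(cb, n_molecules=50, size=96, seed=8,
                                          entries=cb.gene_names)
        mols1 = pixel_decode(stack, cb)
        scaled = ImageStack(pixels=stack.pixels * 37.0, pixel_size=stack.pixel_size)
        mols2 = pixel_decode(scaled, cb)
        assert sorted(m.entry for m in mols1) == sorted(m.entry for m in mols2)

    def test_single_pixel_candidates_dropped(self, cb):
        gene = cb.gene_names[0]
        pixels = np.zeros((22, 16, 16))
        for b in np.flatnonzero(cb.barcode_of(gene)):
            pixels[b, 5, 5] = 1.0       # one bright pixel only
        mols = pixel_decode(ImageStack(pixels=pixels), cb, min_pixels=2)
        assert mols == []


class TestMisidRate:
    def make_mols(self, blank_calls, gene_calls, cb):
        mols = []
        for i in range(blank_calls):
            mols.append(DecodedMolecule(cb.blank_names[i % 10], 0, 0, 2, 1.0, 0.1, 0))
        for i in range(gene_calls):
            mols.append(DecodedMolecule(cb.gene_names[i % 242], 0, 0, 2, 1.0, 0.1, 0))
        return mols

    def test_worked_rate_arithmetic(self, cb):
        # 20 blank calls over 10 blanks vs 9680 gene calls over 242 genes -> 0.05
        mols = self.make_mols(20, 9680, cb)
        assert estimate_misid_rate(mols, cb) == pytest.approx(0.05)

    def test_zero_blank_calls_give_zero(self, cb):
        assert estimate_misid_rate(self.make_mols(0, 1000, cb), cb) == 0.0

    def test_uniform_calls_give_one(self, cb):
        mols = self.make_mols(10 * 3, 242 * 3, cb)
        assert estimate_misid_rate(mols, cb) == pytest.approx(1.0)

    def test_no_coding_calls_is_undefined(self, cb):
        with pytest.raises(ZeroDivisionError):
            estimate_misid_rate(self.make_mols(5, 0, cb), cb)

    def test_no_blank_entries_is_an_error(self):
        cb0 = build_codebook(8, 4, 4, 9, 0)
        with pytest.raises(ValueError):
            estimate_misid_rate([], cb0)


class TestAdaptiveFilter:
    @pytest.fixture(scope="class")
    def noisy_candidates(self, cb):
        stack = synth.generate_spot_stack(
            cb, n_molecules=600, size=300, seed=4, entries=cb.gene_names,
            amplitude_jitter=0.35, bit_dropout=0.08, background_sigma=0.05,
            ghost_spots=500)
        return pixel_decode(stack, cb)

    def test_filter_hits_target_rate_from_above(self, cb, noisy_candidates):
        before = estimate_misid_rate(noisy_candidates, cb)
        kept = adaptive_misid_filter(noisy_candidates, cb, target_rate=0.05)
        after = estimate_misid_rate(kept, cb)
        assert before > 0.05
        assert after <= 0.05
        # within one blank call of the target (the filter's resolution)
        one_call = (1 / 10) / (sum(not m.entry.startswith("Blank") for m in kept) / 242)
        assert 0.05 - after <= one_call + 1e-9

    def test_chosen_threshold_matches_sweep_oracle(self, cb, noisy_candidates):
        # oracle: sweep every quality cutoff; the retained set must be the
        # largest whose blank-derived rate stays at or below target
        kept = adaptive_misid_filter(noisy_candidates, cb, target_rate=0.05)
        q = combined_quality(noisy_candidates)
        order = np.argsort(-q)
        best_n = 0
        for n in range(1, len(order) + 1):
            sub = [noisy_candidates[i] for i in order[:n]]
            genes = sum(not m.entry.startswith("Blank") for m in sub)
            if genes == 0:
                continue
            if estimate_misid_rate(sub, cb) <= 0.05:
                best_n = n
        assert len(kept) == best_n

    def test_filter_never_increases_the_rate(self, cb, noisy_candidates):
        kept = adaptive_misid_filter(noisy_candidates, cb, target_rate=0.05)
        assert estimate_misid_rate(kept, cb) <= estimate_misid_rate(noisy_candidates, cb)

    def test_clean_set_passes_untouched(self, cb):
        mols = [DecodedMolecule(cb.gene_names[i % 242], 0, 0, 2, 1.0, 0.1, 0)
                for i in range(100)]
        kept = adaptive_misid_filter(mols, cb, target_rate=0.05)
        assert len(kept) == 100


class TestSegmentation:
    @staticmethod
    def scene(centers, nucleus_r=4, cell_r=10, size=96):
        yy, xx = np.mgrid[0:size, 0:size]
        nuc = np.zeros((size, size))
        poly = np.zeros((size, size))
        for cx, cy in centers:
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            nuc += np.exp(-d2 / (2 * nucleus_r ** 2))
            poly += np.exp(-d2 / (2 * cell_r ** 2))
        return nuc, poly

    def test_two_separated_nuclei_give_two_cells(self):
        nuc, poly = self.scene([(25, 30), (70, 60)])
        cells = segment_cells(nuc, poly)
        assert len(cells) == 2
        masks = [c.mask for c in cells]
        assert not (masks[0] & masks[1]).any()

    def test_touching_blobs_are_split_by_the_watershed(self):
        nuc, poly = self.scene([(40, 48), (56, 48)])
        cells = segment_cells(nuc, poly)
        assert len(cells) == 2
        assert not (cells[0].mask & cells[1].mask).any()
        # each mask contains its own nucleus peak
        for c, (cx, cy) in zip(sorted(cells, key=lambda c: c.centroid[0]),
                               [(40, 48), (56, 48)]):
            assert c.mask[cy, cx]

    def test_blank_image_gives_no_cells(self):
        assert segment_cells(np.zeros((32, 32)), np.zeros((32, 32))) == []

    def test_border_cells_are_flagged(self):
        nuc, poly = self.scene([(3, 48), (48, 48)], size=96)
        cells = segment_cells(nuc, poly)
        by_x = sorted(cells, key=lambda c: c.centroid[0])
        assert by_x[0].touches_border
        assert not by_x[-1].touches_border


class TestAssignment:
    def test_toy_assignment_and_count_matrix(self):
        ps = 1.0
        mask_a = np.zeros((20, 20), bool)
        mask_a[2:8, 2:8] = True
        mask_b = np.zeros((20, 20), bool)
        mask_b[12:18, 12:18] = True
        from mopatlas.decoding import SegmentedCell
        cells = [SegmentedCell(1, mask_a, (5, 5), 360.0),
                 SegmentedCell(2, mask_b, (15, 15), 360.0)]
        mols = [DecodedMolecule("g1", 4, 4, 2, 1, 0.1, 0),
                DecodedMolecule("g1", 5, 6, 2, 1, 0.1, 0),
                DecodedMolecule("g2", 14, 14, 2, 1, 0.1, 0),
                DecodedMolecule("g1", 15, 16, 2, 1, 0.1, 0),
                DecodedMolecule("g2", 10, 1, 2, 1, 0.1, 0)]   # outside both
        assigned = assign_molecules(mols, cells, pixel_size=ps)
        assert [m.cell_id for m in assigned] == [1, 1, 2, 2, None]
        counts = counts_from_molecules(assigned, ["g1", "g2"])
        assert counts.loc[1].tolist() == [2, 0]
        assert counts.loc[2].tolist() == [1, 1]
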