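"""Pixel-based decoding of multi-round image stacks and cell segmentation.

Each imaging round reads out one bit of the barcode; a pixel's intensity
vector across rounds is therefore a noisy rendering of the barcode of the
molecule occupying it.  Decoding proceeds per pixel (bit-calling against the
codebook with single-error correction), adjacent pixels with the same call
merge into molecules, and a quality filter tuned on the blank-barcode call
rate trims the molecule list to a target misidentification rate.  Cells are
segmented with a seeded watershed (nuclei as seeds, total-mRNA signal as the
landscape) and molecules are assigned to the cell whose mask contains them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, restoration, segmentation

from .codebook import Codebook

__all__ = [
    "ImageStack",
    "DecodedMolecule",
    "SegmentedCell",
    "preprocess_stack",
    "pixel_decode",
    "estimate_misid_rate",
    "adaptive_misid_filter",
    "segment_cells",
    "assign_molecules",
    "molecules_to_frame",
    "counts_from_molecules",
]

SLICE_THICKNESS_UM = 10.0   # nominal slice thickness for the 2-D volume reduction


@dataclass
class ImageStack:
    """rounds x height x width intensity stack with optional ground truth."""

    pixels: np.ndarray                      # (rounds, H, W), >= 0
    pixel_size: float = 0.108               # µm per pixel
    ground_truth: Optional[List[Tuple[float, float, str]]] = None  # (x, y, entry)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (rounds, H, W)")
        if (self.pixels < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_rounds(self) -> int:
        return self.pixels.shape[0]


@dataclass
class DecodedMolecule:
    entry: str
    x: float                    # µm
    y: float                    # µm
    n_pixels: int
    mean_intensity: float
    barcode_distance: float     # mean normalized distance to the barcode
    n_corrected: int
    cell_id: Optional[int] = None
    quality: float = np.nan     # combined score filled by the filter


@dataclass
class SegmentedCell:
    cell_id: int
    mask: np.ndarray            # boolean (H, W)
    centroid: Tuple[float, float]  # (x, y) µm
    volume: float               # µm³ = area x slice thickness
    touches_border: bool = False


def preprocess_stack(stack: ImageStack, highpass_sigma: float = 3.0,
                     lr_iterations: int = 20, lowpass_sigma: float = 1.0,
                     psf_sigma: float = 1.3) -> ImageStack:
    """High-pass filter, Lucy-Richardson deconvolve and low-pass smooth each round.

    ``lr_iterations=0`` together with vanishing sigmas is the identity.
    Intensities are clipped at zero after background subtraction.
    """
    if highpass_sigma < 0 or lowpass_sigma < 0 or lr_iterations < 0:
        raise ValueError("sigmas and iteration count must be non-negative")
    out = np.empty_like(stack.pixels)
    psf = None
    if lr_iterations > 0:
        r = int(np.ceil(3 * psf_sigma))
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        psf = np.exp(-(xx ** 2 + yy ** 2) / (2 * psf_sigma ** 2))
        psf /= psf.sum()
    for i in range(stack.n_rounds):
        img = stack.pixels[i]
        if highpass_sigma > 0:
            img = np.clip(img - ndi.gaussian_filter(img, highpass_sigma), 0, None)
        if lr_iterations > 0:
            scale = img.max()
            if scale > 0:
                img = restoration.richardson_lucy(img / scale, psf,
                                                  num_iter=lr_iterations, clip=False)
                img = np.clip(img, 0, None) * scale
        if lowpass_sigma > 0:
            img = ndi.gaussian_filter(img, lowpass_sigma)
        out[i] = img
    return ImageStack(pixels=out, pixel_size=stack.pixel_size,
                      ground_truth=stack.ground_truth)


def _call_bits(vectors: np.ndarray, weight: int) -> np.ndarray:
    """Threshold round-intensity vectors into bits at the midpoint of the two modes.

    For a constant-weight code the ``weight`` brightest rounds of an on-pixel
    form one intensity mode and the remaining rounds the other; the bit
    threshold is the midpoint of the two mode means, per pixel.
    """
    srt = np.sort(vectors, axis=1)[:, ::-1]
    on_mode = srt[:, :weight].mean(axis=1)
    off_mode = srt[:, weight:].mean(axis=1)
    thr = 0.5 * (on_mode + off_mode)
    return (vectors > thr[:, None]).astype(np.int16)


def pixel_decode(stack: ImageStack, codebook: Codebook,
                 min_intensity: Optional[float] = None,
                 min_pixels: int = 2) -> List[DecodedMolecule]:
    """Decode every pixel against the codebook and aggregate molecules.

    Pixels whose unit-normalized intensity vector decodes (with up to one
    corrected bit) to a codebook entry are labelled with that entry;
    4-connected same-entry pixels merge into candidate molecules.  Candidates
    with fewer than ``min_pixels`` pixels are dropped (single-pixel calls are
    dominated by noise).  ``min_intensity`` suppresses background pixels; it
    defaults to 10% of the stack maximum.
    """
    if stack.n_rounds != codebook.n_bits:
        raise ValueError("stack round count does not match codebook n_bits")
    rounds, H, W = stack.pixels.shape
    vec = stack.pixels.reshape(rounds, -1).T        # (H*W, rounds)
    if min_intensity is None:
        min_intensity = 0.10 * float(stack.pixels.max(initial=0.0))
    bright = vec.max(axis=1) > min_intensity
    if not bright.any():
        return []

    cb_mat = codebook.matrix().astype(np.int16)     # (E, B)
    names = codebook.names
    bits = _call_bits(vec[bright], codebook.weight)

    # Hamming distance of every called bit pattern to every codeword
    d = (bits[:, None, :] != cb_mat[None, :, :]).sum(axis=2) if len(bits) < 4096 else None
    if d is None:
        # blockwise to bound memory
        d = np.empty((len(bits), len(cb_mat)), dtype=np.int16)
        for s in range(0, len(bits), 4096):
            blk = bits[s:s + 4096]
            d[s:s + 4096] = (blk[:, None, :] != cb_mat[None, :, :]).sum(axis=2)
    dmin = d.min(axis=1)
    n_hits = (d == dmin[:, None]).sum(axis=1)
    entry_idx = d.argmin(axis=1)
    ok = (dmin <= 1) & (n_hits == 1)

    # per-pixel entry image (-1 = no call)
    entry_img = np.full(H * W, -1, dtype=np.int32)
    bright_idx = np.flatnonzero(bright)
    entry_img[bright_idx[ok]] = entry_idx[ok]
    corrected_img = np.zeros(H * W, dtype=np.int16)
    corrected_img[bright_idx[ok]] = dmin[ok]
    entry_img = entry_img.reshape(H, W)
    corrected_img = corrected_img.reshape(H, W)

    # normalized distance between pixel vector and its codeword, for quality
    norms = np.linalg.norm(vec, axis=1)
    unit = vec / np.maximum(norms, 1e-12)[:, None]
    cb_unit = cb_mat / np.sqrt(codebook.weight)

    mols: List[DecodedMolecule] = []
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    for e in np.unique(entry_img):
        if e < 0:
            continue
        lab, n_lab = ndi.label(entry_img == e, structure=struct)
        for region in measure.regionprops(lab):
            if region.area < min_pixels:
                continue
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            flat = rr * W + cc
            inten = float(np.mean(vec[flat].max(axis=1)))
            dist = float(np.mean(np.linalg.norm(unit[flat] - cb_unit[e][None, :], axis=1)))
            cy, cx = region.centroid
            mols.append(DecodedMolecule(
                entry=names[int(e)],
                x=float(cx) * stack.pixel_size, y=float(cy) * stack.pixel_size,
                n_pixels=int(region.area), mean_intensity=inten,
                barcode_distance=dist,
                n_corrected=int(corrected_img[rr, cc].max())))
    return mols


def estimate_misid_rate(molecules: Sequence[DecodedMolecule], codebook: Codebook) -> float:
    """(mean count per blank entry) / (mean count per coding entry).

    Returns 0 when there are no blank calls; raises when there are no coding
    calls at all (the rate is then undefined).
    """
    n_blank_entries = len(codebook.blank_names)
    n_gene_entries = len(codebook.gene_names)
    if n_blank_entries == 0:
        raise ValueError("codebook has no blank entries; rate inestimable")
    blank_calls = sum(1 for m in molecules if Codebook.is_blank(m.entry))
    gene_calls = sum(1 for m in molecules if not Codebook.is_blank(m.entry))
    if blank_calls == 0:
        return 0.0
    if gene_calls == 0:
        raise ZeroDivisionError("no coding calls; misidentification rate undefined")
    return (blank_calls / n_blank_entries) / (gene_calls / n_gene_entries)


def combined_quality(molecules: Sequence[DecodedMolecule]) -> np.ndarray:
    """Rank-product quality: mean on-bit intensity x (1 - normalized distance).

    Both components are converted to ranks (higher = better) and multiplied,
    giving a monotone, unitless score.
    """
    inten = np.array([m.mean_intensity for m in molecules])
    dist = np.array([m.barcode_distance for m in molecules])
    r_int = stats_rank(inten)
    r_dst = stats_rank(-dist)
    return r_int * r_dst


def stats_rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(x) / len(x)


def adaptive_misid_filter(candidates: Sequence[DecodedMolecule], codebook: Codebook,
                          target_rate: float = 0.05) -> List[DecodedMolecule]:
    """Keep the largest high-quality subset whose blank-derived rate <= target.

    Candidates are ordered by the combined quality score; the retained set is
    the longest quality-ranked prefix whose misidentification rate does not
    exceed ``target_rate``.  If even the unfiltered set is below target, no
    molecule is removed.
    """
    if not len(candidates):
        return []
    if len(codebook.blank_names) == 0:
        raise ValueError("codebook has no blank entries")
    q = combined_quality(candidates)
    order = np.argsort(-q)
    is_blank = np.array([Codebook.is_blank(candidates[i].entry) for i in order])
    cum_blank = np.cumsum(is_blank)
    cum_gene = np.cumsum(~is_blank)
    nb, ng = len(codebook.blank_names), len(codebook.gene_names)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(cum_gene > 0, (cum_blank / nb) / (cum_gene / ng), np.inf)
        rates = np.where(cum_blank == 0, 0.0, rates)
    valid = np.flatnonzero(rates <= target_rate)
    if len(valid) == 0:
        # nothing satisfies the target; retain the top-quality stratum
        cut = 1
    else:
        cut = int(valid.max()) + 1
    kept_idx = order[:cut]
    out = []
    for i in kept_idx:
        m = candidates[i]
        m.quality = float(q[i])
        out.append(m)
    return out


def segment_cells(nuclei_image: np.ndarray, polyA_image: np.ndarray,
                  pixel_size: float = 0.108,
                  nucleus_min_area: int = 20) -> List[SegmentedCell]:
    """Seeded watershed segmentation: nuclei seed, total-mRNA signal bounds.

    Nuclei are detected by Otsu thresholding of the nuclear stain; the
    watershed floods the inverted total-mRNA landscape from the nucleus
    seeds inside the mRNA-positive mask, producing disjoint cell masks.
    """
    nuclei_image = np.asarray(nuclei_image, dtype=float)
    polyA_image = np.asarray(polyA_image, dtype=float)
    if nuclei_image.shape != polyA_image.shape:
        raise ValueError("images must share a shape")
    if nuclei_image.max() <= 0:
        return []
    nuc_mask = nuclei_image > filters.threshold_otsu(nuclei_image)
    nuc_mask = morphology.remove_small_objects(nuc_mask, nucleus_min_area)
    seeds, n_seeds = ndi.label(nuc_mask)
    if n_seeds == 0:
        return []
    if polyA_image.max() > 0:
        cell_mask = polyA_image > filters.threshold_otsu(polyA_image)
    else:
        cell_mask = nuc_mask
    cell_mask |= nuc_mask
    labels = segmentation.watershed(-polyA_image, markers=seeds, mask=cell_mask)

    cells: List[SegmentedCell] = []
    H, W = labels.shape
    for region in measure.regionprops(labels):
        mask = labels == region.label
        cy, cx = region.centroid
        rr, cc = np.nonzero(mask)
        touches = bool((rr.min() == 0) or (cc.min() == 0)
                       or (rr.max() == H - 1) or (cc.max() == W - 1))
        area_um2 = region.area * pixel_size ** 2
        cells.append(SegmentedCell(
            cell_id=int(region.label), mask=mask,
            centroid=(float(cx) * pixel_size, float(cy) * pixel_size),
            volume=float(area_um2 * SLICE_THICKNESS_UM),
            touches_border=touches))
    return cells


def assign_molecules(molecules: Sequence[DecodedMolecule],
                     cells: Sequence[SegmentedCell],
                     pixel_size: float = 0.108) -> List[DecodedMolecule]:
    """Assign each molecule the id of the cell mask containing its centroid."""
    if not cells:
        for m in molecules:
            m.cell_id = None
        return list(molecules)
    H, W = cells[0].mask.shape
    label_img = np.zeros((H, W), dtype=np.int32)
    for c in cells:
        label_img[c.mask] = c.cell_id
    for m in molecules:
        col = int(round(m.x / pixel_size))
        row = int(round(m.y / pixel_size))
        if 0 <= row < H and 0 <= col < W and label_img[row, col] > 0:
            m.cell_id = int(label_img[row, col])
        else:
            m.cell_id = None
    return list(molecules)


def molecules_to_frame(molecules: Sequence[DecodedMolecule]) -> pd.DataFrame:
    return pd.DataFrame(
        {"entry": [m.entry for m in molecules],
         "x": [m.x for m in molecules],
         "y": [m.y for m in molecules],
         "n_pixels": [m.n_pixels for m in molecules],
         "quality": [m.quality for m in molecules],
         "n_corrected": [m.n_corrected for m in molecules],
         "cell_id": [m.cell_id for m in molecules]})


def counts_from_molecules(molecules: Sequence[DecodedMolecule],
                          gene_names: Sequence[str]) -> pd.DataFrame:
    """Aggregate assigned molecules into a cells x genes count matrix."""
    assigned = [m for m in molecules if m.cell_id is not None]
    cell_ids = sorted({m.cell_id for m in assigned})
    counts = pd.DataFrame(0, index=pd.Index(cell_ids, name="cell_id"),
                          columns=list(gene_names))
    for m in assigned:
        if m.entry in counts.columns:
            counts.loc[m.cell_id, m.entry] += 1
    return counts
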