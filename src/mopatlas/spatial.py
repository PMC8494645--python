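"""Laminar depth statistics: soma depth, layer boundaries, overlap measures.

The cortical surface of each slice is traced by the vascular leptomeningeal
cells (VLMCs), which form the outermost cell layer; a cell's soma depth is
its shortest distance to a smooth curve fitted through the VLMC centroids.
Depths are normalized per slice by the median depth of the L6b cells (the
innermost layer), so 0 is the surface and 1 the L6b mid-line, which removes
slice-to-slice variation in cortical thickness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

__all__ = [
    "DepthProfile",
    "LayerBoundaries",
    "fit_surface_and_depth",
    "layer_boundaries",
    "marker_overlap_fraction",
    "density_overlap",
    "neighborhood_complexity",
    "binned_profile",
]


@dataclass
class DepthProfile:
    depth: pd.Series                      # per-cell normalized depth (NaN = excluded slice)
    raw_depth: pd.Series                  # per-cell distance to the surface, µm
    thickness: Dict[object, float]        # per-slice median L6b depth, µm
    surface_coeffs: Dict[object, np.ndarray] = field(default_factory=dict)
    excluded_slices: List[object] = field(default_factory=list)


@dataclass
class LayerBoundaries:
    """Named boundaries in normalized depth; L5's upper boundary is an interval."""

    boundaries: Dict[str, float]
    l5_uncertainty: Tuple[float, float]

    def ordered(self) -> List[Tuple[str, float]]:
        return sorted(self.boundaries.items(), key=lambda t: t[1])


def _distances_to_curve(x: np.ndarray, y: np.ndarray, coeffs: np.ndarray,
                        x_range: Tuple[float, float], n_samples: int = 2000) -> np.ndarray:
    """Shortest Euclidean distance of points to a sampled polynomial curve."""
    lo, hi = x_range
    margin = 0.05 * (hi - lo + 1e-9)
    xs = np.linspace(lo - margin, hi + margin, n_samples)
    ys = np.polyval(coeffs, xs)
    tree = cKDTree(np.column_stack([xs, ys]))
    d, _ = tree.query(np.column_stack([x, y]))
    return d


def fit_surface_and_depth(cells: pd.DataFrame, labels: pd.Series,
                          vlmc_label: str = "VLMC", l6b_prefix: str = "L6b",
                          surface_degree: int = 2) -> DepthProfile:
    """Per-slice surface fit through VLMCs and L6b-normalized soma depths.

    Slices missing VLMC or L6b cells cannot be normalized and are excluded
    with a warning (their cells get NaN depth).
    """
    labels = pd.Series(labels, index=cells.index).astype(str)
    depth = pd.Series(np.nan, index=cells.index, dtype=float)
    raw = pd.Series(np.nan, index=cells.index, dtype=float)
    thickness: Dict[object, float] = {}
    coeffs_by_slice: Dict[object, np.ndarray] = {}
    excluded: List[object] = []

    for slc, idx in cells.groupby("slice_id").groups.items():
        sub = cells.loc[idx]
        is_vlmc = labels.loc[idx].str.startswith(vlmc_label)
        is_l6b = labels.loc[idx].str.startswith(l6b_prefix)
        if is_vlmc.sum() < surface_degree + 1 or is_l6b.sum() == 0:
            excluded.append(slc)
            warnings.warn(f"slice {slc!r} lacks VLMC or L6b cells; excluded from "
                          "depth normalization")
            continue
        vx = sub.loc[is_vlmc, "x"].values
        vy = sub.loc[is_vlmc, "y"].values
        deg = min(surface_degree, max(len(np.unique(vx)) - 1, 0))
        coeffs = np.polyfit(vx, vy, deg)
        coeffs_by_slice[slc] = coeffs
        xr = (float(sub["x"].min()), float(sub["x"].max()))
        d = _distances_to_curve(sub["x"].values, sub["y"].values, coeffs, xr)
        raw.loc[idx] = d
        t = float(np.median(d[is_l6b.values]))
        if t <= 0:
            excluded.append(slc)
            warnings.warn(f"slice {slc!r} has non-positive L6b median depth; excluded")
            raw.loc[idx] = np.nan
            continue
        thickness[slc] = t
        depth.loc[idx] = d / t

    return DepthProfile(depth=depth, raw_depth=raw, thickness=thickness,
                        surface_coeffs=coeffs_by_slice, excluded_slices=excluded)


DEFAULT_BOUNDARY_RULES: Dict[str, Sequence[str]] = {
    # boundary name -> subclass prefixes whose most superficial cluster defines it
    "L2/3": ("L2/3 IT",),
    "L4": ("L4/5 IT",),
    "L6": ("L6 IT", "L6 CT"),
}


def layer_boundaries(depths: pd.Series, clusters: pd.Series,
                     rules: Mapping[str, Sequence[str]] = DEFAULT_BOUNDARY_RULES,
                     l5_upper_cluster: Optional[str] = None,
                     l5_lower_cluster: Optional[str] = None) -> LayerBoundaries:
    """Boundaries from cluster median depths.

    Each named boundary is the median depth of the most superficial cluster
    among the designated subclasses.  L6b is centred at 1 with bounds from
    the interquartile range of the L6b depths.  The upper boundary of L5 is
    reported as an uncertainty interval between the medians of a designated
    upper cluster (deepest L4/5 IT cluster by default) and lower cluster
    (most superficial L5 IT cluster by default).  Raises if the resulting
    boundaries are not monotonically increasing.
    """
    clusters = pd.Series(clusters, index=depths.index)
    ok = depths.notna() & clusters.notna()
    depths, clusters = depths[ok], clusters[ok].astype(str)
    med = depths.groupby(clusters).median()

    def most_superficial(prefixes: Sequence[str]) -> Optional[float]:
        cands = [m for c, m in med.items()
                 if any(c.startswith(p) and not c.startswith("L6 IT Car3") for p in prefixes)]
        return min(cands) if cands else None

    boundaries: Dict[str, float] = {"surface": 0.0}
    for name, prefixes in rules.items():
        m = most_superficial(prefixes)
        if m is None:
            warnings.warn(f"boundary {name!r}: designated clusters missing")
            continue
        boundaries[name] = float(m)

    # L6b band around 1
    l6b_d = depths[clusters.str.startswith("L6b")]
    if len(l6b_d):
        q1, q3 = np.percentile(l6b_d, [25, 75])
        boundaries["L6b"] = float(q1)
        boundaries["L6b lower"] = float(q3)

    # L5 uncertainty interval
    def cluster_median(name: Optional[str], fallback: Optional[float]) -> Optional[float]:
        if name is not None and name in med.index:
            return float(med[name])
        return fallback

    l45 = sorted([(m, c) for c, m in med.items() if c.startswith("L4/5 IT")])
    l5 = sorted([(m, c) for c, m in med.items() if c.startswith("L5 IT")])
    upper = cluster_median(l5_upper_cluster, l45[-1][0] if l45 else None)
    lower = cluster_median(l5_lower_cluster, l5[0][0] if l5 else None)
    if upper is None or lower is None:
        l5_unc = (np.nan, np.nan)
    else:
        l5_unc = (float(min(upper, lower)), float(max(upper, lower)))
        boundaries["L5"] = l5_unc[1]

    vals = [boundaries[k] for k in ("surface", "L2/3", "L4", "L5", "L6", "L6b")
            if k in boundaries]
    if any(b > a for a, b in zip(vals[1:], vals[:-1])):
        raise ValueError(f"layer boundaries are not monotone: {boundaries}")
    return LayerBoundaries(boundaries=boundaries, l5_uncertainty=l5_unc)


def binned_profile(depths: pd.Series, values: pd.Series, n_bins: int = 100,
                   stat: str = "mean") -> pd.DataFrame:
    """Equal-count depth bins with the per-bin mean (or median) of ``values``.

    Returns a frame with bin index, bin depth centre, and the statistic.
    """
    ok = depths.notna()
    d = depths[ok].values
    v = values.loc[depths.index[ok]].values
    order = np.argsort(d, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for b, s in enumerate(splits):
        if len(s) == 0:
            continue
        agg = np.mean(v[s]) if stat == "mean" else np.median(v[s])
        rows.append({"bin": b, "depth": float(np.mean(d[s])), "value": float(agg),
                     "lo": float(d[s].min()), "hi": float(d[s].max())})
    return pd.DataFrame(rows)


def marker_overlap_fraction(cluster_cells: Sequence, marker_gene: str,
                            matrix: pd.DataFrame, depths: pd.Series,
                            n_bins: int = 100, stat: str = "mean") -> float:
    """Fraction of a cluster's cells lying in depth bins where a marker is high.

    All cells are binned into ``n_bins`` equal-count depth bins; bins whose
    binned marker expression exceeds half its maximum define the marker's
    depth band; the returned value is the fraction of the cluster's cells
    whose depth falls inside that band.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cluster_cells = pd.Index(cluster_cells)
    if len(cluster_cells) == 0:
        raise ValueError("empty cluster")
    prof = binned_profile(depths, matrix[marker_gene], n_bins=n_bins, stat=stat)
    half_max = prof["value"].max() / 2.0
    hot = prof[prof["value"] > half_max]
    if hot.empty:
        return 0.0
    inside = np.zeros(len(cluster_cells), dtype=bool)
    cd = depths.loc[cluster_cells].values
    for _, row in hot.iterrows():
        inside |= (cd >= row["lo"]) & (cd <= row["hi"])
    return float(np.mean(inside))


def density_overlap(depths_a: Sequence[float], depths_b: Sequence[float],
                    bandwidth: Optional[float] = None, n_grid: int = 2048) -> float:
    """Overlap coefficient of two kernel density estimates: integral of min(fa, fb).

    ``bandwidth=None`` uses Scott's rule; a fixed bandwidth (in depth units)
    may be supplied for reproducibility.  Symmetric and bounded in [0, 1].
    """
    a = np.asarray(depths_a, dtype=float)
    b = np.asarray(depths_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    bw = bandwidth
    ka = gaussian_kde(a, bw_method=(bw / max(a.std(), 1e-12)) if bw else None)
    kb = gaussian_kde(b, bw_method=(bw / max(b.std(), 1e-12)) if bw else None)
    lo = min(a.min(), b.min()) - 4 * max(ka.factor * a.std(), kb.factor * b.std())
    hi = max(a.max(), b.max()) + 4 * max(ka.factor * a.std(), kb.factor * b.std())
    grid = np.linspace(lo, hi, n_grid)
    fa = ka(grid)
    fb = kb(grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def neighborhood_complexity(cells: pd.DataFrame, clusters: pd.Series,
                            radius: float = 100.0) -> pd.Series:
    """Distinct cluster labels within ``radius`` µm of each cell (same slice).

    The index cell's own cluster is counted, so the minimum value is 1.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    clusters = pd.Series(clusters, index=cells.index).astype(str)
    out = pd.Series(0, index=cells.index, dtype=int)
    for slc, idx in cells.groupby("slice_id").groups.items():
        pts = cells.loc[idx, ["x", "y"]].values
        labs = clusters.loc[idx].values
        tree = cKDTree(pts)
        neigh = tree.query_ball_point(pts, r=radius)
        out.loc[idx] = [len(set(labs[n])) for n in neigh]
    return out
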