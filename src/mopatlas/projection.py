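"""Retrograde-tracer projection labels and composition statistics.

Cells retrogradely labelled by tracer dye injected into a target region
project to that region.  Thresholding the (robustly normalized) per-channel
dye intensity gives each cell an on/off flag per target, from which
single- vs multi-projection status, depth enrichment profiles and
per-target cluster compositions are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ProjectionLabels",
    "normalize_tracer",
    "threshold_tracer",
    "depth_enrichment",
    "projection_composition",
]


@dataclass
class ProjectionLabels:
    flags: pd.DataFrame          # cells x channels, boolean
    status: pd.Series            # "none" | "single:<target>" | "multi"

    @property
    def targets(self) -> List[str]:
        return list(self.flags.columns)

    def positive_cells(self, target: Optional[str] = None) -> pd.Index:
        if target is None:
            return self.flags.index[self.flags.any(axis=1)]
        return self.flags.index[self.flags[target]]

    def single_projecting(self, target: str) -> pd.Index:
        one = self.flags.sum(axis=1) == 1
        return self.flags.index[one & self.flags[target]]


def normalize_tracer(intensities: pd.DataFrame) -> pd.DataFrame:
    """Robust per-channel scaling: (x - median) / MAD.

    The bulk of cells is unlabelled, so the median/MAD describe background
    and labelled cells stand out as large positive deviations.
    """
    med = intensities.median(axis=0)
    mad = (intensities - med).abs().median(axis=0).replace(0, 1.0)
    return (intensities - med) / mad


def threshold_tracer(intensities: pd.DataFrame,
                     thresholds: Mapping[str, float] | float = 10.0,
                     normalize: bool = True) -> ProjectionLabels:
    """Label each cell on/off per channel by thresholding normalized intensity.

    ``thresholds`` is stringent by design (weakly labelled cells stay off);
    a scalar applies to every channel.
    """
    norm = normalize_tracer(intensities) if normalize else intensities
    if np.isscalar(thresholds):
        thresholds = {c: float(thresholds) for c in norm.columns}
    flags = pd.DataFrame({c: norm[c] > thresholds[c] for c in norm.columns},
                         index=norm.index)
    n_on = flags.sum(axis=1)
    status = pd.Series("none", index=flags.index, dtype=object)
    for c in flags.columns:
        status[(n_on == 1) & flags[c]] = f"single:{c}"
    status[n_on > 1] = "multi"
    return ProjectionLabels(flags=flags, status=status)


def depth_enrichment(labels: ProjectionLabels, assignment: pd.DataFrame,
                     depths: pd.Series, target: str, n_bins: int = 20,
                     reference_subclasses: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-depth-bin enrichment of a target's tracer-positive cells.

    Enrichment in a bin = (fraction of the target's positive cells in the
    bin) / (fraction of all reference cells — IT and L6b subclasses by
    default — in the bin).  Bins are equal-count bins of the reference
    population; bins without reference cells are reported as missing.
    """
    sub = assignment["subclass"].astype(str)
    if reference_subclasses is None:
        ref_mask = sub.str.contains("IT") | sub.str.startswith("L6b")
    else:
        ref_mask = sub.isin(reference_subclasses)
    ref_cells = assignment.index[ref_mask]
    ref_d = depths.loc[ref_cells].dropna()
    pos = labels.positive_cells(target)
    pos_d = depths.loc[depths.index.intersection(pos)].dropna()
    if len(pos_d) == 0:
        raise ValueError(f"no tracer-positive cells for target {target!r}")

    edges = np.quantile(ref_d.values, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    ref_counts, _ = np.histogram(ref_d.values, bins=edges)
    pos_counts, _ = np.histogram(pos_d.values, bins=edges)
    ref_frac = ref_counts / ref_counts.sum()
    pos_frac = pos_counts / pos_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(ref_counts > 0, pos_frac / ref_frac, np.nan)
    centres = [float(np.median(ref_d.values[(ref_d.values >= lo) & (ref_d.values <= hi)]))
               if n > 0 else np.nan
               for lo, hi, n in zip(edges[:-1], edges[1:], ref_counts)]
    return pd.DataFrame({"bin": np.arange(n_bins), "depth": centres,
                         "enrichment": enr})


def projection_composition(labels: ProjectionLabels, assignment: pd.DataFrame,
                           n_boot: int = 100, seed: int = 0,
                           level: str = "cluster") -> Dict[str, pd.DataFrame]:
    """Projection-composition statistics over clusters (or subclasses).

    Returns two tables:

    * ``per_cluster``: for each cluster, the fraction of its CTb-positive
      single-projecting cells going to each target (missing when a cluster
      has no single-projecting cells);
    * ``per_target``: for each target, the composition of its positive cells
      over clusters/subclasses (sums to 1), with bootstrap-over-cells
      percentile confidence intervals.
    """
    lab_col = assignment[level].astype(str)
    targets = labels.targets
    rng = np.random.default_rng(seed)

    # per-cluster single-projection fractions
    rows = []
    for cl in sorted(lab_col.dropna().unique()):
        cells = assignment.index[lab_col == cl]
        singles = labels.status.loc[labels.status.index.intersection(cells)]
        singles = singles[singles.str.startswith("single:")]
        row: Dict[str, object] = {"cluster": cl, "n_single": len(singles)}
        for t in targets:
            row[t] = (np.nan if len(singles) == 0
                      else float((singles == f"single:{t}").mean()))
        rows.append(row)
    per_cluster = pd.DataFrame(rows).set_index("cluster")

    # per-target composition over the partition, with bootstrap CIs
    rows = []
    for t in targets:
        pos = labels.positive_cells(t)
        pos = pos.intersection(assignment.index[lab_col.notna()])
        groups = lab_col.loc[pos]
        frac = groups.value_counts(normalize=True)
        boots = {g: [] for g in frac.index}
        gvals = groups.values
        for _ in range(max(n_boot, 1)):
            take = rng.integers(0, len(gvals), size=len(gvals)) if n_boot > 1 \
                else np.arange(len(gvals))
            vc = pd.Series(gvals[take]).value_counts(normalize=True)
            for g in boots:
                boots[g].append(float(vc.get(g, 0.0)))
        for g in frac.index:
            lo, hi = np.percentile(boots[g], [2.5, 97.5])
            rows.append({"target": t, level: g, "fraction": float(frac[g]),
                         "ci_low": float(min(lo, frac[g])),
                         "ci_high": float(max(hi, frac[g])),
                         "n": int((groups == g).sum())})
    per_target = pd.DataFrame(rows)
    return {"per_cluster": per_cluster, "per_target": per_target}
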