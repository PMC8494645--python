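"""Cell-level QC cascade for a cells x genes count matrix.

The stages run in a fixed order: volume filter, volume normalization, batch
normalization, sequential-channel artifact filter, sequential background
subtraction, total-count quantile filter, simulated-doublet removal, and
finally removal of configured dropped genes.  Every stage only *flags* cells
in the cell table; ``run_qc`` applies the flags and reconciles the counts in
a :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CellByGeneMatrix",
    "QCReport",
    "filter_by_volume",
    "normalize_by_volume",
    "batch_normalize",
    "sequential_artifact_filter",
    "subtract_channel_background",
    "quantile_count_filter",
    "doublet_scores",
    "remove_doublets",
    "run_qc",
]


@dataclass
class CellByGeneMatrix:
    """cells x genes values plus a processing-state tag.

    States progress raw -> volume_normalized -> batch_normalized -> log_z.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state in ("raw", "volume_normalized", "batch_normalized"):
            if (self.values.values < 0).any():
                raise ValueError(f"negative values in state {self.state!r}")

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_names(self) -> pd.Index:
        return self.values.columns

    def totals(self) -> pd.Series:
        return self.values.sum(axis=1)


@dataclass
class QCReport:
    stages: List[Tuple[str, int]] = field(default_factory=list)
    thresholds: Dict[str, object] = field(default_factory=dict)
    n_input: int = 0
    n_kept: int = 0

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.stages)

    def fractions(self) -> Dict[str, float]:
        return {s: n / max(self.n_input, 1) for s, n in self.stages}

    def to_dict(self) -> Dict[str, object]:
        return {"n_input": self.n_input, "n_kept": self.n_kept,
                "stages": dict(self.stages), "thresholds": self.thresholds,
                "fractions": self.fractions()}


def _ensure_flags(cells: pd.DataFrame) -> pd.DataFrame:
    cells = cells.copy()
    if "qc_flags" not in cells.columns:
        cells["qc_flags"] = [set() for _ in range(len(cells))]
    else:
        cells["qc_flags"] = [set(f) for f in cells["qc_flags"]]
    return cells


def filter_by_volume(cells: pd.DataFrame, min_volume: float = 100.0,
                     max_multiple: float = 3.0) -> pd.DataFrame:
    """Flag cells with volume < ``min_volume`` or > ``max_multiple`` x median.

    The median is computed over *all* input cells before any removal; both
    cutoffs are strict inequalities (a cell at exactly 100 µm³ survives).
    """
    cells = _ensure_flags(cells)
    med = float(cells["volume"].median())
    bad = (cells["volume"] < min_volume) | (cells["volume"] > max_multiple * med)
    for i in cells.index[bad]:
        cells.at[i, "qc_flags"].add("volume")
    return cells


def normalize_by_volume(matrix: CellByGeneMatrix, cells: pd.DataFrame) -> CellByGeneMatrix:
    """Divide each cell's counts by its imaged volume (counts per µm³)."""
    if matrix.state != "raw":
        raise ValueError("volume normalization expects the raw state")
    vol = cells.loc[matrix.cell_ids, "volume"]
    if (vol <= 0).any():
        raise ValueError("volumes must be positive")
    return CellByGeneMatrix(matrix.values.div(vol, axis=0), state="volume_normalized")


def batch_normalize(matrix: CellByGeneMatrix, cells: pd.DataFrame,
                    target_mean: float = 250.0) -> CellByGeneMatrix:
    """Scale each batch by one scalar so its mean total per cell equals the target.

    A single per-batch scalar leaves within-batch relative expression intact.
    """
    vals = matrix.values.copy()
    batches = cells.loc[matrix.cell_ids, "batch_id"]
    for b, idx in matrix.cell_ids.groupby(batches).items():
        mean_total = float(vals.loc[idx].sum(axis=1).mean())
        if mean_total <= 0:
            raise ValueError(f"batch {b!r} has no counts")
        vals.loc[idx] *= target_mean / mean_total
    return CellByGeneMatrix(vals, state="batch_normalized")


def sequential_artifact_filter(cells: pd.DataFrame, sequential_signals: pd.DataFrame,
                               quantile: float = 0.90, min_channels: int = 12,
                               total_channels: int = 16) -> pd.DataFrame:
    """Flag cells above the per-channel quantile in >= ``min_channels`` channels.

    No real cell co-expresses a majority of the sequential-round marker
    genes; a cell bright in most channels is fluorescence background.
    """
    if sequential_signals.shape[1] != total_channels:
        raise ValueError("channel count mismatch")
    cells = _ensure_flags(cells)
    thr = sequential_signals.quantile(quantile, axis=0)
    n_above = (sequential_signals > thr).sum(axis=1)
    bad = n_above[n_above >= min_channels].index
    for i in bad:
        if i in cells.index:
            cells.at[i, "qc_flags"].add("sequential_artifact")
    return cells


def subtract_channel_background(sequential_signals: pd.DataFrame,
                                channel_groups: Dict[str, Sequence[str]]) -> pd.DataFrame:
    """Per cell and channel group, subtract the cell's minimum within-group signal.

    Groups correspond to detection channels with different background levels
    (e.g. the 650-nm and 750-nm dyes); results are clipped at zero.
    """
    out = sequential_signals.copy().astype(float)
    assigned = [ch for chans in channel_groups.values() for ch in chans]
    if sorted(assigned) != sorted(sequential_signals.columns):
        raise ValueError("each channel must belong to exactly one group")
    for _, chans in channel_groups.items():
        chans = list(chans)
        background = out[chans].min(axis=1)
        out[chans] = (out[chans].sub(background, axis=0)).clip(lower=0)
    return out


def quantile_count_filter(matrix: CellByGeneMatrix, cells: pd.DataFrame,
                          low: float = 0.02, high: float = 0.98) -> pd.DataFrame:
    """Flag cells with totals strictly outside the [low, high] interpolated quantiles."""
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    cells = _ensure_flags(cells)
    totals = matrix.totals()
    lo = np.quantile(totals.values, low)
    hi = np.quantile(totals.values, high)
    bad = totals.index[(totals < lo) | (totals > hi)]
    for i in bad:
        cells.at[i, "qc_flags"].add("count_quantile")
    return cells


def doublet_scores(matrix: CellByGeneMatrix, expected_rate: float = 0.12,
                   k: int = 5, seed: int = 0,
                   sim_ratio: float = 4.0, n_pcs: int = 30) -> pd.Series:
    """Simulated-doublet kNN scoring.

    Artificial doublets are synthesized as sums of random observed cell
    pairs (``sim_ratio`` x the number of observed cells of them), everything
    is total-normalized, log-transformed and embedded by PCA, and each
    observed cell is scored by the fraction ``q`` of simulated doublets among
    its ``k`` nearest neighbours.  The returned score is the posterior
    probability that the cell is a doublet given ``q``::

        score = (q * rho / r) / (q * rho / r + (1 - q) * (1 - rho))

    with ``rho = expected_rate`` and ``r = sim_ratio``, i.e. the neighbour
    fraction corrected for the simulated/observed ratio, so a threshold on
    the score is a threshold on doublet probability.  ``k`` is deliberately
    small (the effective neighbourhood is ``k * (1 + sim_ratio)``): in data
    with many small clusters each doublet species is rare, and a wide
    neighbourhood dilutes its simulated counterparts with parent-cluster
    singlets.  Deterministic given ``seed``.
    """
    X = matrix.values.values.astype(float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two cells")
    rng = np.random.default_rng(seed)
    n_sim = max(int(round(sim_ratio * n)), 1)
    i = rng.integers(0, n, size=n_sim)
    j = rng.integers(0, n, size=n_sim)
    sim = X[i] + X[j]

    def norm_log(M: np.ndarray) -> np.ndarray:
        tot = M.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return np.log1p(M / tot * np.median(X.sum(axis=1)))

    obs_n = norm_log(X)
    sim_n = norm_log(sim)
    n_pcs = min(n_pcs, obs_n.shape[1], max(n - 1, 1))
    pca = PCA(n_components=n_pcs, random_state=int(seed) % (2 ** 31))
    obs_p = pca.fit_transform(obs_n)
    sim_p = pca.transform(sim_n)

    k_adj = int(round(k * (1 + sim_ratio)))
    all_p = np.vstack([obs_p, sim_p])
    nn = NearestNeighbors(n_neighbors=min(k_adj + 1, len(all_p))).fit(all_p)
    _, idx = nn.kneighbors(obs_p)
    idx = idx[:, 1:]                      # drop self
    q = (idx >= n).mean(axis=1)

    rho, r = expected_rate, sim_ratio
    num = q * rho / r
    score = num / (num + (1 - q) * (1 - rho))
    return pd.Series(np.clip(score, 0.0, 1.0), index=matrix.cell_ids)


def remove_doublets(cells: pd.DataFrame, scores: pd.Series,
                    threshold: float = 0.18) -> pd.DataFrame:
    """Flag cells whose doublet score exceeds the threshold."""
    cells = _ensure_flags(cells)
    for i in scores.index[scores > threshold]:
        if i in cells.index:
            cells.at[i, "qc_flags"].add("doublet")
    return cells


def run_qc(matrix: CellByGeneMatrix, cells: pd.DataFrame,
           sequential_signals: Optional[pd.DataFrame] = None,
           channel_groups: Optional[Dict[str, Sequence[str]]] = None,
           dropped_genes: Sequence[str] = (),
           min_volume: float = 100.0, max_volume_multiple: float = 3.0,
           target_mean: float = 250.0, seq_quantile: float = 0.90,
           seq_min_channels: int = 12, count_low: float = 0.02,
           count_high: float = 0.98, doublet_threshold: float = 0.18,
           doublet_expected_rate: float = 0.12, seed: int = 0,
           ) -> Tuple[CellByGeneMatrix, pd.DataFrame, QCReport]:
    """Run the full QC cascade; returns (batch-normalized matrix, cells, report).

    Stage order follows the processing cascade: (1) volume filter,
    (2) volume normalization, (3) batch normalization, (4) sequential
    artifact filter, (5) sequential background subtraction, (6) total-count
    quantile filter (computed after batch normalization), (7) doublet
    removal, (8) dropped-gene removal.  Cells flagged at one stage do not
    enter later stages.
    """
    report = QCReport(n_input=len(cells))
    report.thresholds = {
        "min_volume": min_volume, "max_volume_multiple": max_volume_multiple,
        "target_mean": target_mean, "seq_quantile": seq_quantile,
        "seq_min_channels": seq_min_channels,
        "count_quantiles": (count_low, count_high),
        "doublet_threshold": doublet_threshold,
        "dropped_genes": list(dropped_genes)}

    def n_flagged(c: pd.DataFrame) -> int:
        return int(sum(bool(f) for f in c["qc_flags"]))

    # (1) volume
    cells = filter_by_volume(cells, min_volume, max_volume_multiple)
    removed = n_flagged(cells)
    report.stages.append(("volume", removed))
    keep = cells.index[[not f for f in cells["qc_flags"]]]
    mat = CellByGeneMatrix(matrix.values.loc[keep], state="raw")

    # (2) volume normalization, (3) batch normalization
    mat = normalize_by_volume(mat, cells)
    mat = batch_normalize(mat, cells, target_mean)

    # (4) sequential artifact filter, (5) background subtraction
    if sequential_signals is not None:
        seq = sequential_signals.loc[sequential_signals.index.intersection(keep)]
        before = n_flagged(cells)
        cells = sequential_artifact_filter(cells, seq, seq_quantile,
                                           seq_min_channels, seq.shape[1])
        # cells flagged earlier stay attributed to their earlier stage
        report.stages.append(("sequential_artifact", n_flagged(cells) - before))
        keep = cells.index[[not f for f in cells["qc_flags"]]]
        mat = CellByGeneMatrix(mat.values.loc[keep], state=mat.state)
        if channel_groups is not None:
            sequential_signals = subtract_channel_background(seq.loc[seq.index.intersection(keep)],
                                                             channel_groups)

    # (6) quantile filter on totals of the batch-normalized matrix
    before = n_flagged(cells)
    cells_q = quantile_count_filter(mat, cells.loc[keep], count_low, count_high)
    cells.loc[cells_q.index, "qc_flags"] = cells_q["qc_flags"]
    report.stages.append(("count_quantile", n_flagged(cells) - before))
    keep = cells.index[[not f for f in cells["qc_flags"]]]
    mat = CellByGeneMatrix(mat.values.loc[keep], state=mat.state)

    # (7) doublets
    before = n_flagged(cells)
    scores = doublet_scores(mat, expected_rate=doublet_expected_rate, seed=seed)
    cells = remove_doublets(cells, scores, doublet_threshold)
    report.stages.append(("doublet", n_flagged(cells) - before))
    keep = cells.index[[not f for f in cells["qc_flags"]]]
    mat = CellByGeneMatrix(mat.values.loc[keep], state=mat.state)

    # (8) dropped genes
    genes = [g for g in mat.gene_names if g not in set(dropped_genes)]
    mat = CellByGeneMatrix(mat.values[genes], state=mat.state)

    report.n_kept = len(keep)
    cells = cells.copy()
    cells["doublet_score"] = scores.reindex(cells.index)
    return mat, cells, report
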