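"""End-to-end pipeline drivers shared by the analysis scripts and tests.

Each function wires together the module-level operations with the study's
default parameters: QC cascade -> two-round clustering -> depth statistics,
and the tracer workflow (threshold -> doublet filter -> label transfer).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import pandas as pd

from . import clustering, projection, qc, spatial, synth
from .qc import CellByGeneMatrix, QCReport
from .synth import SyntheticAtlas

__all__ = ["default_channel_groups", "run_default_qc", "cluster_atlas",
           "tracer_transfer"]


def default_channel_groups(sequential: pd.DataFrame) -> Dict[str, list]:
    """Split the 16 sequential channels into the two detection-dye groups."""
    cols = list(sequential.columns)
    return {"650nm": cols[:8], "750nm": cols[8:]}


def run_default_qc(atlas: SyntheticAtlas, seed: int = 0
                   ) -> Tuple[CellByGeneMatrix, pd.DataFrame, QCReport]:
    """The full QC cascade at its default thresholds."""
    return qc.run_qc(
        atlas.matrix, atlas.cells, atlas.sequential,
        channel_groups=default_channel_groups(atlas.sequential),
        dropped_genes=synth.DROPPED_SEQ_GENES, seed=seed)


def cluster_atlas(atlas: SyntheticAtlas, seed: int = 0):
    """QC + two-round clustering; returns (matrix, cells, report, assignment)."""
    mat, cells, report = run_default_qc(atlas, seed=seed)
    assignment = clustering.two_round_cluster(mat, cells, seed=seed)
    return mat, cells, report, assignment


def tracer_transfer(reference: SyntheticAtlas, tracer_atlas: SyntheticAtlas,
                    intensities: pd.DataFrame, threshold: float = 10.0,
                    doublet_threshold: float = 0.18, seed: int = 0):
    """Tracer workflow: threshold channels, drop doublets, transfer labels.

    The tracer-imaged cells pass the same doublet filter as any other
    dataset; cluster identities are transferred from the reference atlas
    (trained on its cluster labels) and mapped to subclasses via the
    reference taxonomy.  Returns (labels, transfer frame indexed by the
    doublet-filtered cells, with ``label``/``subclass``/``confidence``).
    """
    labels = projection.threshold_tracer(intensities, thresholds=threshold)
    scores = qc.doublet_scores(tracer_atlas.matrix, seed=seed)
    keep = scores.index[scores <= doublet_threshold]
    transferred = clustering.label_transfer(
        reference.matrix.values, reference.truth["cluster"],
        tracer_atlas.matrix.values.loc[keep], seed=seed)
    sub_of = {s.name: s.subclass for s in reference.config.taxonomy}
    transferred["subclass"] = transferred["label"].map(sub_of)
    return labels, transferred


def it_l6b_fraction(labels, transferred) -> float:
    """Fraction of tracer-positive, doublet-filtered cells in IT or L6b subclasses."""
    pos = labels.positive_cells().intersection(transferred.index)
    sub = transferred.loc[pos, "subclass"].astype(str)
    return float((sub.str.contains("IT") | sub.str.startswith("L6b")).mean())
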