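"""Plain-text serialization of the pipeline's tables.

Count matrices go to Matrix-Market (sparse) with sidecar cell/gene lists;
cell tables, truth tables and sequential signals go to CSV.  Everything
round-trips losslessly enough for downstream statistics (counts exactly;
floats at full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .qc import CellByGeneMatrix

__all__ = ["save_matrix", "load_matrix", "save_atlas", "load_atlas"]


def save_matrix(matrix: CellByGeneMatrix, prefix: Path) -> None:
    """Write a cells x genes matrix as <prefix>.mtx + .cells.txt + .genes.txt."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(matrix.values.values))
    prefix.with_suffix(".cells.txt").write_text("\n".join(map(str, matrix.cell_ids)) + "\n")
    prefix.with_suffix(".genes.txt").write_text("\n".join(map(str, matrix.gene_names)) + "\n")
    prefix.with_suffix(".state.txt").write_text(matrix.state + "\n")


def load_matrix(prefix: Path) -> CellByGeneMatrix:
    prefix = Path(prefix)
    m = spio.mmread(str(prefix) + ".mtx").toarray()
    cells = prefix.with_suffix(".cells.txt").read_text().splitlines()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    state = prefix.with_suffix(".state.txt").read_text().strip()
    df = pd.DataFrame(m, index=pd.Index(cells, name="cell_id"), columns=genes)
    if state == "raw":
        df = df.astype(np.int64)
    return CellByGeneMatrix(df, state=state)


def save_atlas(atlas, outdir: Path) -> None:
    """Persist a synthetic atlas (counts, cells, sequential signals, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_matrix(atlas.matrix, outdir / "counts")
    atlas.cells.to_csv(outdir / "cells.csv")
    atlas.sequential.to_csv(outdir / "sequential.csv")
    atlas.truth.to_csv(outdir / "truth.csv")
    cfg = {k: v for k, v in vars(atlas.config).items() if k != "taxonomy"}
    cfg["slice_thickness"] = list(cfg["slice_thickness"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1))


def load_atlas(outdir: Path):
    """Reload the tables written by :func:`save_atlas` (truth dtypes restored)."""
    from .synth import AtlasConfig, SyntheticAtlas, build_gene_panel, default_taxonomy

    outdir = Path(outdir)
    matrix = load_matrix(outdir / "counts")
    cells = pd.read_csv(outdir / "cells.csv", index_col=0)
    sequential = pd.read_csv(outdir / "sequential.csv", index_col=0)
    truth = pd.read_csv(outdir / "truth.csv", index_col=0,
                        dtype={"cluster2": str}, keep_default_na=False,
                        na_values=[])
    for col in ("is_doublet", "is_volume_artifact", "is_seq_artifact"):
        truth[col] = truth[col].astype(str).str.lower().isin(("true", "1"))
    for col in ("depth",):
        truth[col] = truth[col].astype(float)
    cfg = json.loads((outdir / "config.json").read_text())
    cfg["slice_thickness"] = tuple(cfg["slice_thickness"])
    config = AtlasConfig(**cfg)
    tax = config.taxonomy
    _, means = build_gene_panel(tax, config.it_marker_strength,
                                config.it_marker_width,
                                config.it_marker_boost)
    return SyntheticAtlas(matrix=matrix, cells=cells, sequential=sequential,
                          truth=truth, cluster_means=means, config=config)
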