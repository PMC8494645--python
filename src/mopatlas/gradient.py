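"""IT-continuum analyses: depth-graded genes, cluster connectivity, pseudotime.

IT (intratelencephalic) neurons span nearly the whole cortical depth and
their expression changes gradually with depth rather than in discrete
jumps.  Three complementary statistics quantify that continuum:

* genes whose binned mean z-score profile varies with depth beyond a range
  threshold, ordered by the depth of their expression peak;
* chance-normalized inter-cluster connectivity in a kNN expression graph
  (weight 1 = as many inter-cluster edges as random endpoint placement
  would give);
* diffusion pseudotime from a root cell in the most superficial cluster,
  correlated against normalized depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .clustering import knn_graph
from .qc import CellByGeneMatrix

__all__ = [
    "ConnectivityGraph",
    "PseudotimeResult",
    "depth_de_genes",
    "cluster_connectivity",
    "diffusion_pseudotime",
]


@dataclass
class ConnectivityGraph:
    nodes: List[str]
    weights: pd.DataFrame        # symmetric clusters x clusters
    n_pcs: int
    k: int
    display_threshold: float = 0.1

    def edges(self, apply_threshold: bool = False) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1:]:
                w = float(self.weights.loc[a, b])
                if apply_threshold and w < self.display_threshold:
                    continue
                rows.append({"a": a, "b": b, "weight": w})
        return pd.DataFrame(rows)


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series
    root_cell: object
    depth_correlation: Optional[float] = None   # Spearman vs normalized depth


def depth_de_genes(z_matrix: CellByGeneMatrix, depths: pd.Series,
                   n_bins: int = 50, min_range: float = 0.5,
                   window: int = 10) -> pd.DataFrame:
    """Genes whose binned mean z-profile spans more than ``min_range``.

    Cells are split evenly (equal-count) into ``n_bins`` depth bins; a gene
    qualifies when max - min of its per-bin mean z-score exceeds
    ``min_range``.  Genes are ordered by the depth bin at which a rolling
    mean (``window`` bins) of the profile peaks, so a heatmap of the
    returned ordering sweeps from superficial to deep.
    """
    d = depths.loc[z_matrix.cell_ids]
    ok = d.notna().values
    if ok.sum() < n_bins:
        raise ValueError("fewer cells than bins")
    X = z_matrix.values.values[ok]
    order = np.argsort(d.values[ok], kind="stable")
    splits = np.array_split(order, n_bins)
    prof = np.vstack([X[s].mean(axis=0) for s in splits])   # bins x genes

    rng_span = prof.max(axis=0) - prof.min(axis=0)
    selected = np.flatnonzero(rng_span > min_range)

    rows = []
    for j in selected:
        roll = np.convolve(prof[:, j], np.ones(window) / window, mode="valid")
        peak_win = int(np.argmax(roll))
        rows.append({"gene": z_matrix.gene_names[j],
                     "peak_bin": peak_win,
                     "range": float(rng_span[j])})
    out = pd.DataFrame(rows, columns=["gene", "peak_bin", "range"])
    return out.sort_values(["peak_bin", "gene"], kind="stable").reset_index(drop=True)


def cluster_connectivity(z_matrix: CellByGeneMatrix, clusters: pd.Series,
                         n_pcs: int = 19, k: int = 12,
                         seed: int = 0) -> ConnectivityGraph:
    """Inter-cluster kNN edge frequency normalized to chance.

    With ``E`` total undirected edges and cluster fractions ``p_a``, the
    expected number of edges between clusters a and b under random endpoint
    placement is ``E * 2 * p_a * p_b``; the connectivity weight is
    observed / expected, so unstructured splits of one population score ~1
    and well-separated clusters score ~0.
    """
    labels = pd.Series(clusters, index=z_matrix.cell_ids).astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = labels.value_counts()
    if (sizes == 1).any():
        import warnings
        warnings.warn("singleton cluster(s) present; their connectivity is noisy")

    X = z_matrix.values.values
    n_pcs = min(n_pcs, X.shape[1], X.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=int(seed) % (2 ** 31)).fit_transform(X)
    g = knn_graph(pcs, k)
    lab_idx = labels.values

    E = g.ecount()
    n = len(labels)
    obs = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in g.get_edgelist():
        la, lb = lab_idx[a], lab_idx[b]
        obs.loc[la, lb] += 1
        if la != lb:
            obs.loc[lb, la] += 1
    p = sizes.reindex(names) / n
    weights = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            expected = E * 2 * p[a] * p[b]
            weights.loc[a, b] = obs.loc[a, b] / expected if expected > 0 else 0.0
    return ConnectivityGraph(nodes=names, weights=weights, n_pcs=n_pcs, k=k)


def diffusion_pseudotime(z_matrix: CellByGeneMatrix, clusters: pd.Series,
                         root_cluster: str, n_pcs: int = 19, k: int = 12,
                         seed: int = 0,
                         depths: Optional[pd.Series] = None) -> PseudotimeResult:
    """Diffusion pseudotime from a root cell of ``root_cluster``.

    A diffusion map is built on the kNN graph in PC space and pseudotime is
    the diffusion distance from the root cell, chosen as the root cluster's
    cell closest to the cluster centroid in PC space (seeded tie-break).
    When ``depths`` is given, the Spearman correlation between pseudotime
    and depth is reported.  Raises on a disconnected kNN graph.
    """
    import scanpy as sc
    from anndata import AnnData

    labels = pd.Series(clusters, index=z_matrix.cell_ids).astype(str)
    members = np.flatnonzero((labels == root_cluster).values)
    if len(members) == 0:
        raise ValueError(f"root cluster {root_cluster!r} is empty")

    X = z_matrix.values.values.astype(np.float64)
    n_pcs = min(n_pcs, X.shape[1], X.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=int(seed) % (2 ** 31)).fit_transform(X)

    g = knn_graph(pcs, k)
    comps = g.connected_components()
    if len(comps) > 1:
        sizes = sorted((len(c) for c in comps), reverse=True)
        raise ValueError(f"kNN graph is disconnected (component sizes {sizes})")

    centroid = pcs[members].mean(axis=0)
    dist = np.linalg.norm(pcs[members] - centroid, axis=1)
    best = dist.min()
    ties = members[np.flatnonzero(dist == best)]
    rng = np.random.default_rng(seed)
    root_idx = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])

    ad = AnnData(X=pcs.astype(np.float32))
    sc.pp.neighbors(ad, n_neighbors=k, use_rep="X", random_state=int(seed) % (2 ** 31))
    sc.tl.diffmap(ad)
    ad.uns["iroot"] = root_idx
    sc.tl.dpt(ad)
    pt = pd.Series(np.asarray(ad.obs["dpt_pseudotime"], dtype=float),
                   index=z_matrix.cell_ids)

    corr = None
    if depths is not None:
        d = depths.loc[z_matrix.cell_ids]
        ok = d.notna() & np.isfinite(pt)
        corr = float(stats.spearmanr(pt[ok], d[ok]).statistic)
    return PseudotimeResult(pseudotime=pt, root_cell=z_matrix.cell_ids[root_idx],
                            depth_correlation=corr)
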