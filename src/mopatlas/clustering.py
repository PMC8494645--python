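"""Two-round graph-based clustering with marker routing and label transfer.

Round 1 clusters all cells coarsely (Louvain communities on a kNN graph in
shuffle-calibrated PC space, k = 10).  The resulting clusters are routed by
marker expression into five groups — IT neurons, non-IT excitatory neurons,
CGE-derived and MGE-derived inhibitory neurons, and non-neuronal cells —
which are then re-clustered separately at group-specific granularity
(k = 40, r = 2 for the two excitatory groups; k = 15, r = 2 for the two
inhibitory groups; k = 20, r = 1 for non-neuronal cells).  Clusters that
co-express incompatible class markers are flagged as doublet clusters and
removed.  Final clusters are named ``<subclass> <index>``.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import igraph
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .qc import CellByGeneMatrix

__all__ = [
    "MarkerConfig",
    "ClusterAssignment",
    "log_z_normalize",
    "select_n_pcs_shuffle",
    "knn_graph",
    "graph_cluster",
    "louvain_labels",
    "bootstrap_stability",
    "two_round_cluster",
    "label_transfer",
    "DEFAULT_MARKERS",
]

GROUP_PARAMS = {            # round-2 (k, resolution) per routed group
    "IT": (40, 2.0),
    "non-IT excitatory": (40, 2.0),
    "CGE": (15, 2.0),
    "MGE": (15, 2.0),
    "non-neuronal": (20, 1.0),
}


@dataclass
class MarkerConfig:
    """Marker rules for routing round-1 clusters and naming subclasses."""

    exc_marker: str = "Slc17a7"
    it_marker: str = "Slc30a3"
    inh_markers: Tuple[str, ...] = ("Gad1", "Gad2")
    cge_markers: Tuple[str, ...] = ("Lamp5", "Sncg", "Vip")
    mge_markers: Tuple[str, ...] = ("Sst", "Pvalb")
    z_threshold: float = 0.5
    # subclass -> scoring markers, organised per routed group
    subclass_markers: Dict[str, Dict[str, List[str]]] = field(default_factory=lambda: {
        "IT": {"L2/3 IT": ["Cux2", "Otof"],
               "L4/5 IT": ["Rspo1", "Rorb"],
               "L5 IT": ["Sulf2"],
               "L6 IT": ["Osr1"],
               "L6 IT Car3": ["Car3"]},
        "non-IT excitatory": {"L5 ET": ["Fam84b"],
                              "L5/6 NP": ["Tshz2"],
                              "L6 CT": ["Foxp2"],
                              "L6b": ["Ctgf"]},
        "CGE": {"Lamp5": ["Lamp5"], "Sncg": ["Sncg"], "Vip": ["Vip"]},
        "MGE": {"Sst": ["Sst"], "Pvalb": ["Pvalb"]},
        "non-neuronal": {"astrocyte": ["Aqp4"],
                         "oligodendrocyte": ["Mog"],
                         "OPC": ["Pdgfra"],
                         "microglia": ["Cx3cr1"],
                         "PVM": ["Mrc1"],
                         "endothelial": ["Flt1"],
                         "SMC": ["Acta2"],
                         "pericyte": ["Kcnj8"],
                         "VLMC": ["Slc6a13"]},
    })
    # marker pairs that no real cell type co-expresses
    incompatible_pairs: List[Tuple[str, str]] = field(default_factory=lambda: [
        ("Slc17a7", "Gad1"), ("Slc17a7", "Sox10"), ("Gad1", "Sox10")])

    def class_of_group(self, group: str) -> str:
        return {"IT": "glutamatergic", "non-IT excitatory": "glutamatergic",
                "CGE": "GABAergic", "MGE": "GABAergic",
                "non-neuronal": "non-neuronal"}[group]


DEFAULT_MARKERS = MarkerConfig()


@dataclass
class ClusterAssignment:
    """Per-cell labels plus the recovered taxonomy tree."""

    table: pd.DataFrame         # index cell_id; group, cluster, subclass, class, flagged
    taxonomy: Dict[str, Dict[str, List[str]]]

    @property
    def clusters(self) -> List[str]:
        return sorted(self.table["cluster"].dropna().unique())

    def cells_of(self, cluster: str) -> pd.Index:
        return self.table.index[self.table["cluster"] == cluster]


# ---------------------------------------------------------------------------
# normalization and dimensionality


def log_z_normalize(matrix: CellByGeneMatrix) -> CellByGeneMatrix:
    """Median-total scaling, log1p, then per-gene z-score.

    Zero-variance genes get z-score 0 everywhere.
    """
    vals = matrix.values.values.astype(float)
    totals = vals.sum(axis=1)
    med = np.median(totals[totals > 0])
    scale = np.where(totals > 0, med / np.maximum(totals, 1e-12), 1.0)
    vals = np.log1p(vals * scale[:, None])
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (vals - mu) / sd_safe
    z[:, sd == 0] = 0.0
    return CellByGeneMatrix(pd.DataFrame(z, index=matrix.cell_ids,
                                         columns=matrix.gene_names), state="log_z")


def select_n_pcs_shuffle(matrix: CellByGeneMatrix, n_shuffles: int = 20,
                         seed: int = 0, max_pcs: int = 100) -> int:
    """Count PCs whose eigenvalue beats column-shuffled data.

    The reference level is the mean (over ``n_shuffles`` shuffles) of the
    first eigenvalue after independently permuting every gene column, which
    destroys gene-gene covariance while keeping marginals.
    """
    X = matrix.values.values.astype(float)
    n, g = X.shape
    rng = np.random.default_rng(seed)
    k = min(max_pcs, n - 1, g)
    pca = PCA(n_components=k, svd_solver="randomized", random_state=int(seed) % (2 ** 31))
    pca.fit(X)
    eig = pca.explained_variance_

    top = np.empty(n_shuffles)
    for s in range(n_shuffles):
        Xs = X.copy()
        for j in range(g):
            Xs[:, j] = Xs[rng.permutation(n), j]
        p1 = PCA(n_components=1, svd_solver="randomized",
                 random_state=int(seed + 1 + s) % (2 ** 31))
        p1.fit(Xs)
        top[s] = p1.explained_variance_[0]
    ref = top.mean()
    return int((eig > ref).sum())


def knn_graph(pcs: np.ndarray, k: int, weighted: bool = True) -> igraph.Graph:
    """Undirected kNN graph (union of directed neighbourhoods).

    With ``weighted=True`` each edge carries the Jaccard similarity of the
    two endpoint neighbourhoods (shared-nearest-neighbour weighting), which
    down-weights stray edges bridging distinct populations and sharpens
    community structure on expression continua.
    """
    n = pcs.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = [set(map(int, row[1:])) for row in idx]
    edges: Dict[Tuple[int, int], float] = {}
    for a in range(n):
        for b in idx[a, 1:]:
            b = int(b)
            key = (a, b) if a < b else (b, a)
            if key not in edges:
                if weighted:
                    inter = len(neigh[a] & neigh[b])
                    edges[key] = inter / (2 * k - inter) if inter else 1e-4
                else:
                    edges[key] = 1.0
    g = igraph.Graph(n=n, edges=list(edges), directed=False)
    g.es["weight"] = list(edges.values())
    return g


def louvain_labels(g: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    """Seeded Louvain community detection (multilevel modularity)."""
    igraph.set_random_number_generator(_random.Random(int(seed) % (2 ** 31)))
    weights = "weight" if "weight" in g.es.attributes() else None
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def graph_cluster(matrix: CellByGeneMatrix, n_pcs: int, k: int = 10,
                  resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """PCA -> kNN graph -> Louvain; integer labels, deterministic given seed."""
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    X = matrix.values.values.astype(float)
    n_pcs = min(n_pcs, X.shape[1], X.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=int(seed) % (2 ** 31)).fit_transform(X)
    g = knn_graph(pcs, k)
    labels = louvain_labels(g, resolution, seed)
    return pd.Series(labels, index=matrix.cell_ids)


def bootstrap_stability(matrix: CellByGeneMatrix, n_pcs: int, k: int = 10,
                        resolution: float = 1.0, n_boot: int = 10,
                        subsample: float = 0.8, seed: int = 0,
                        max_pairs: int = 200) -> pd.Series:
    """Per-cluster co-clustering consistency across subsampled re-clusterings.

    For each reference cluster, pairs of member cells are tracked across
    ``n_boot`` re-clusterings of random ``subsample`` fractions; the score is
    the fraction of co-occurring pairs that stay co-clustered.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    ref = graph_cluster(matrix, n_pcs, k, resolution, seed)
    rng = np.random.default_rng(seed)
    n = len(ref)
    pos = {cid: i for i, cid in enumerate(matrix.cell_ids)}

    pairs: Dict[int, List[Tuple[int, int]]] = {}
    for lab in ref.unique():
        members = np.array([pos[c] for c in ref.index[ref == lab]])
        if len(members) < 2:
            pairs[lab] = []
            continue
        npairs = min(max_pairs, len(members) * (len(members) - 1) // 2)
        a = rng.choice(members, size=npairs)
        b = rng.choice(members, size=npairs)
        pairs[lab] = [(i, j) for i, j in zip(a, b) if i != j]

    agree = {lab: [0, 0] for lab in pairs}
    for b_i in range(n_boot):
        take = rng.choice(n, size=int(round(subsample * n)), replace=False)
        sub = CellByGeneMatrix(matrix.values.iloc[np.sort(take)], state=matrix.state)
        lab_b = graph_cluster(sub, n_pcs, min(k, len(take) - 1), resolution,
                              seed=seed + 1 + b_i)
        lab_map = {pos[c]: l for c, l in lab_b.items()}
        for lab, plist in pairs.items():
            for i, j in plist:
                if i in lab_map and j in lab_map:
                    agree[lab][1] += 1
                    agree[lab][0] += int(lab_map[i] == lab_map[j])
    return pd.Series({lab: (a / t if t else np.nan) for lab, (a, t) in agree.items()})


# ---------------------------------------------------------------------------
# marker routing and the two-round pipeline


def _cluster_marker_z(z: CellByGeneMatrix, labels: pd.Series,
                      markers: Sequence[str]) -> pd.DataFrame:
    """Cluster-mean z-score per marker (missing markers contribute -inf)."""
    cols = [m for m in markers if m in z.gene_names]
    means = z.values[cols].groupby(labels.values).mean() if cols else pd.DataFrame()
    for m in markers:
        if m not in means.columns:
            means[m] = -np.inf
    return means[list(markers)]


def route_clusters(z: CellByGeneMatrix, labels: pd.Series,
                   markers: MarkerConfig = DEFAULT_MARKERS) -> Dict[int, str]:
    """Route each round-1 cluster to one of the five groups (or 'unroutable')."""
    all_markers = ([markers.exc_marker, markers.it_marker]
                   + list(markers.inh_markers) + list(markers.cge_markers)
                   + list(markers.mge_markers))
    mz = _cluster_marker_z(z, labels, all_markers)
    thr = markers.z_threshold
    routes: Dict[int, str] = {}
    for lab, row in mz.iterrows():
        exc = row[markers.exc_marker] > thr
        inh = max(row[m] for m in markers.inh_markers) > thr
        if exc and inh:
            routes[lab] = "unroutable"
        elif exc:
            routes[lab] = "IT" if row[markers.it_marker] > thr else "non-IT excitatory"
        elif inh:
            cge = max(row[m] for m in markers.cge_markers)
            mge = max(row[m] for m in markers.mge_markers)
            routes[lab] = "CGE" if cge >= mge else "MGE"
        else:
            routes[lab] = "non-neuronal"
    return routes


def flag_doublet_clusters(z: CellByGeneMatrix, labels: pd.Series,
                          markers: MarkerConfig = DEFAULT_MARKERS) -> List:
    """Cluster labels co-expressing an incompatible class-marker pair."""
    involved = sorted({m for pair in markers.incompatible_pairs for m in pair})
    mz = _cluster_marker_z(z, labels, involved)
    thr = markers.z_threshold
    flagged = []
    for lab, row in mz.iterrows():
        for a, b in markers.incompatible_pairs:
            if row[a] > thr and row[b] > thr:
                flagged.append(lab)
                break
    return flagged


def _assign_subclasses(z: CellByGeneMatrix, labels: pd.Series, group: str,
                       markers: MarkerConfig) -> Dict[int, str]:
    """Subclass per round-2 cluster: argmax cluster-mean z over subclass markers."""
    rules = markers.subclass_markers[group]
    subclass_of: Dict[int, str] = {}
    scores = {}
    for sub, genes in rules.items():
        mz = _cluster_marker_z(z, labels, genes)
        scores[sub] = mz.mean(axis=1)
    score_df = pd.DataFrame(scores)
    for lab, row in score_df.iterrows():
        subclass_of[lab] = row.idxmax()
    return subclass_of


def two_round_cluster(matrix: CellByGeneMatrix, cells: Optional[pd.DataFrame] = None,
                      markers: MarkerConfig = DEFAULT_MARKERS, seed: int = 0,
                      round1_k: int = 10, round1_resolution: float = 1.0,
                      n_shuffles: int = 20) -> ClusterAssignment:
    """Full two-round clustering with marker routing and doublet-cluster removal.

    ``matrix`` should be batch-normalized; log-z normalization, shuffle-based
    PC selection and clustering run per round (round 2 re-normalizes within
    each routed group).  Cells in unroutable or doublet-like clusters are
    flagged (``flagged`` column) and carry no final cluster name.
    """
    z_all = log_z_normalize(matrix)
    n_pcs = max(select_n_pcs_shuffle(z_all, n_shuffles=n_shuffles, seed=seed), 2)
    r1 = graph_cluster(z_all, n_pcs, k=round1_k, resolution=round1_resolution, seed=seed)

    doubletish = set(flag_doublet_clusters(z_all, r1, markers))
    routes = route_clusters(z_all, r1, markers)

    table = pd.DataFrame(index=matrix.cell_ids)
    table["round1"] = r1
    table["group"] = [routes[l] for l in r1]
    table["flagged"] = [(l in doubletish) or (routes[l] == "unroutable") for l in r1]
    table["cluster"] = None
    table["subclass"] = None
    table["class"] = None

    taxonomy: Dict[str, Dict[str, List[str]]] = {}
    for group, (k2, r2) in GROUP_PARAMS.items():
        sel = table.index[(table["group"] == group) & (~table["flagged"])]
        if len(sel) == 0:
            continue
        sub_mat = CellByGeneMatrix(matrix.values.loc[sel], state=matrix.state)
        z_g = log_z_normalize(sub_mat)
        n_pcs_g = max(select_n_pcs_shuffle(z_g, n_shuffles=n_shuffles, seed=seed + 1), 2)
        k_eff = min(k2, len(sel) - 1)
        lab2 = graph_cluster(z_g, n_pcs_g, k=k_eff, resolution=r2, seed=seed + 1)

        bad2 = set(flag_doublet_clusters(z_g, lab2, markers))
        sub_of = _assign_subclasses(z_g, lab2, group, markers)

        # name clusters: per subclass, index by decreasing size
        sizes = lab2.value_counts()
        names: Dict[int, str] = {}
        per_sub_counter: Dict[str, int] = {}
        for lab in sizes.index:          # largest first
            if lab in bad2:
                continue
            sub = sub_of[lab]
            per_sub_counter[sub] = per_sub_counter.get(sub, 0) + 1
            names[lab] = f"{sub} {per_sub_counter[sub]}"

        cls = markers.class_of_group(group)
        for cid in sel:
            l = lab2[cid]
            if l in bad2:
                table.at[cid, "flagged"] = True
                continue
            table.at[cid, "cluster"] = names[l]
            table.at[cid, "subclass"] = sub_of[l]
            table.at[cid, "class"] = cls
        tax_c = taxonomy.setdefault(cls, {})
        for lab, nm in names.items():
            tax_c.setdefault(sub_of[lab], []).append(nm)

    return ClusterAssignment(table=table, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# label transfer


def _zscore_frame(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0).replace(0, 1.0)
    return (df - mu) / sd


def label_transfer(train_matrix: pd.DataFrame, train_labels: Sequence[str],
                   test_matrix: pd.DataFrame, method: str = "logreg",
                   seed: int = 0) -> pd.DataFrame:
    """Transfer cluster labels via a classifier trained on z-scored profiles.

    ``method`` selects a multinomial maximum-entropy model (``logreg``) or a
    small feed-forward network (``mlp``).  Train and test are z-scored
    independently on their shared gene space.  Returns a frame with
    ``label`` and ``confidence`` per test cell.
    """
    shared = [g for g in train_matrix.columns if g in set(test_matrix.columns)]
    if not shared:
        raise ValueError("empty gene intersection between train and test")
    Xtr = _zscore_frame(train_matrix[shared]).values
    Xte = _zscore_frame(test_matrix[shared]).values
    y = np.asarray(train_labels)
    if method == "logreg":
        clf = LogisticRegression(max_iter=500, C=1.0)
    elif method == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(64,), max_iter=300,
                            random_state=int(seed) % (2 ** 31))
    else:
        raise ValueError(f"unknown method {method!r}")
    clf.fit(Xtr, y)
    proba = clf.predict_proba(Xte)
    pred = clf.classes_[proba.argmax(axis=1)]
    conf = proba.max(axis=1)
    return pd.DataFrame({"label": pred, "confidence": conf}, index=test_matrix.index)
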