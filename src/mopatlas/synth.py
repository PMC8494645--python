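"""Ground-truthed synthetic data with the statistical structure of a cortical atlas.

The generator emulates what the downstream pipeline assumes about
multiplexed-FISH data from the mouse primary motor cortex:

* a hierarchical taxonomy of 95 clusters (39 excitatory, 42 inhibitory,
  14 non-neuronal) in 23 subclasses, each cluster with its own marker
  structure and a laminar (truncated-normal) depth distribution;
* negative-binomial (gamma-Poisson) counts whose totals scale with imaged
  cell volume, ~30% between-batch variation in mean totals, 12% doublets
  (summed profiles of random cell pairs), and planted segmentation /
  fluorescence artifact cells;
* depth-graded expression for IT neurons so that gradient and pseudotime
  statistics have a known ground truth;
* per-cluster retrograde-projection compositions in which IT and L6b
  clusters carry ~90% of the tracer labels, including two molecularly
  close L6 IT clusters with disjoint targets;
* multi-round spot images rendering barcodes as Gaussian spots with
  amplitude jitter, bit dropout and background noise.

Every output is reproducible from the config seed and ships with a truth
table, so parameter-recovery tests can compare pipeline output against what
was generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codebook import Codebook
from .decoding import ImageStack
from .qc import CellByGeneMatrix

__all__ = [
    "ClusterSpec",
    "AtlasConfig",
    "SyntheticAtlas",
    "default_taxonomy",
    "build_gene_panel",
    "generate_atlas",
    "generate_tracer",
    "generate_spot_stack",
    "DEFAULT_TARGET_TABLE",
]

_STRUCT_SEED = 202140  # fixes the default taxonomy/mean structure, independent of data seed

TARGETS = ("MOs", "SSp", "TEa-ECT-PERI")

# sequential-round genes; the first four emulate poorly staining genes that a
# QC config drops after preprocessing
DROPPED_SEQ_GENES = ["Cd52", "Rprml", "Mup5", "Igfbp6"]
SEQ_GENES = DROPPED_SEQ_GENES + [f"seq_{i:02d}" for i in range(1, 13)]

GRADIENT_GENES = [f"gradient_{i:02d}" for i in range(1, 21)]

# IT layer markers change gradually with cortical depth rather than switching
# at layer borders: each follows a broad Gaussian depth profile.
IT_LAYER_PROFILES: Dict[str, float] = {
    "Cux2": 0.18, "Otof": 0.22, "Rspo1": 0.42, "Rorb": 0.46,
    "Sulf2": 0.60, "Osr1": 0.82, "Fezf2": 0.72,
}
IT_LAYER_WIDTH = 0.16
IT_LAYER_AMPLITUDE = 5.0


@dataclass
class ClusterSpec:
    name: str
    subclass: str
    class_: str          # glutamatergic | GABAergic | non-neuronal
    group: str           # IT | non-IT excitatory | CGE | MGE | non-neuronal
    weight: float        # relative abundance
    depth_mean: float
    depth_sd: float


def _laminar(names: Sequence[str], subclass: str, class_: str, group: str,
             lo: float, hi: float, sd: float, weights: Sequence[float]) -> List[ClusterSpec]:
    n = len(names)
    centres = np.linspace(lo, hi, n) if n > 1 else [0.5 * (lo + hi)]
    return [ClusterSpec(nm, subclass, class_, group, w, float(c), sd)
            for nm, c, w in zip(names, centres, weights)]


def default_taxonomy() -> List[ClusterSpec]:
    """The default 95-cluster taxonomy: 39 excitatory / 42 inhibitory / 14 non-neuronal.

    Class composition is 60% excitatory, 15% inhibitory and 25% non-neuronal
    cells, with IT clusters holding 70% of the excitatory cells; within each
    subclass, cluster abundances vary smoothly around equality.  Cluster
    depth centres ladder through the cortical depth the way laminar
    subclasses do, with L6b centred at normalized depth 1 and VLMCs at the
    surface.
    """
    rng = np.random.default_rng(_STRUCT_SEED)

    def wts(n: int) -> np.ndarray:
        return 0.7 + 0.6 * rng.random(n)

    specs: List[ClusterSpec] = []
    g, c = "IT", "glutamatergic"
    specs += _laminar([f"L2/3 IT {i}" for i in range(1, 5)], "L2/3 IT", c, g,
                      0.15, 0.34, 0.055, wts(4))
    specs += _laminar([f"L4/5 IT {i}" for i in range(1, 8)], "L4/5 IT", c, g,
                      0.38, 0.52, 0.05, wts(7))
    specs += _laminar([f"L5 IT {i}" for i in range(1, 6)], "L5 IT", c, g,
                      0.55, 0.67, 0.055, wts(5))
    specs += _laminar([f"L6 IT {i}" for i in range(1, 4)], "L6 IT", c, g,
                      0.72, 0.84, 0.055, wts(3))
    specs += _laminar(["L6 IT Car3 1"], "L6 IT Car3", c, g, 0.80, 0.80, 0.05, wts(1))

    g = "non-IT excitatory"
    specs += _laminar([f"L5 ET {i}" for i in range(1, 6)], "L5 ET", c, g,
                      0.55, 0.68, 0.05, wts(5))
    specs += _laminar([f"L5/6 NP {i}" for i in range(1, 3)], "L5/6 NP", c, g,
                      0.62, 0.74, 0.06, wts(2))
    specs += _laminar([f"L6 CT {i}" for i in range(1, 10)], "L6 CT", c, g,
                      0.76, 0.95, 0.045, wts(9))
    specs += _laminar([f"L6b {i}" for i in range(1, 4)], "L6b", c, g,
                      0.97, 1.03, 0.03, wts(3))

    c = "GABAergic"
    specs += _laminar([f"Lamp5 {i}" for i in range(1, 8)], "Lamp5", c, "CGE",
                      0.10, 0.65, 0.12, wts(7))
    specs += _laminar([f"Sncg {i}" for i in range(1, 5)], "Sncg", c, "CGE",
                      0.15, 0.60, 0.13, wts(4))
    specs += _laminar([f"Vip {i}" for i in range(1, 10)], "Vip", c, "CGE",
                      0.12, 0.70, 0.12, wts(9))
    specs += _laminar([f"Sst {i}" for i in range(1, 13)], "Sst", c, "MGE",
                      0.30, 0.95, 0.12, wts(12))
    specs += _laminar([f"Pvalb {i}" for i in range(1, 11)], "Pvalb", c, "MGE",
                      0.30, 0.90, 0.11, wts(10))

    c, g = "non-neuronal", "non-neuronal"
    specs += _laminar([f"astrocyte {i}" for i in range(1, 4)], "astrocyte", c, g,
                      0.15, 1.05, 0.22, wts(3))
    specs += _laminar([f"oligodendrocyte {i}" for i in range(1, 4)],
                      "oligodendrocyte", c, g, 1.00, 1.10, 0.08, wts(3))
    specs += _laminar(["OPC 1"], "OPC", c, g, 0.55, 0.55, 0.28, wts(1))
    specs += _laminar(["microglia 1"], "microglia", c, g, 0.55, 0.55, 0.28, wts(1))
    specs += _laminar(["PVM 1"], "PVM", c, g, 0.50, 0.50, 0.25, wts(1))
    specs += _laminar([f"endothelial {i}" for i in range(1, 3)], "endothelial", c, g,
                      0.45, 0.65, 0.25, wts(2))
    specs += _laminar(["SMC 1"], "SMC", c, g, 0.40, 0.40, 0.22, wts(1))
    specs += _laminar(["pericyte 1"], "pericyte", c, g, 0.50, 0.50, 0.25, wts(1))
    specs += _laminar(["VLMC 1"], "VLMC", c, g, 0.005, 0.005, 0.012, wts(1))

    # class composition: exc 0.60 (IT 0.70 of exc), inh 0.15, non-neuronal 0.25
    by_group: Dict[str, float] = {"IT": 0.60 * 0.70, "non-IT excitatory": 0.60 * 0.30,
                                  "CGE": 0.15 * 0.45, "MGE": 0.15 * 0.55,
                                  "non-neuronal": 0.25}
    for grp, target in by_group.items():
        members = [s for s in specs if s.group == grp]
        tot = sum(s.weight for s in members)
        for s in members:
            s.weight = s.weight / tot * target
    return specs


def build_gene_panel(taxonomy: Sequence[ClusterSpec],
                     it_marker_strength: float = 1.5,
                     it_marker_width: float = 0.06,
                     it_marker_boost: float = 6.0) -> Tuple[List[str], pd.DataFrame]:
    """Gene names and the clusters x genes mean-expression table.

    258 genes: named class/subclass/layer markers, 20 IT-gradient genes,
    one private marker per cluster, 16 sequential-round genes and random
    low-level fillers.  Values are relative expression rates; rows are later
    scaled to each cell's expected total count.

    IT clusters form a continuum with partial discreteness: their layer
    markers and cluster-defining markers follow Gaussian depth profiles
    (evaluated here at the cluster depth centre, per cell downstream), so
    adjacent IT clusters genuinely overlap in expression the way they
    overlap in space, while an own-cluster additive component
    (``it_marker_boost``) keeps each cluster molecularly identifiable.
    Non-IT populations are discrete with block markers.
    """
    rng = np.random.default_rng(_STRUCT_SEED + 1)
    named = ["Slc17a7", "Slc30a3", "Gad1", "Gad2",
             "Lamp5", "Sncg", "Vip", "Sst", "Pvalb",
             "Cux2", "Otof", "Rspo1", "Rorb", "Sulf2", "Osr1", "Car3", "Fezf2",
             "Fam84b", "Tshz2", "Foxp2", "Ctgf",
             "Aqp4", "Mog", "Pdgfra", "Cx3cr1", "Mrc1", "Flt1", "Acta2",
             "Kcnj8", "Slc6a13", "Sox10"]
    private = [f"mk_{i + 1:03d}" for i in range(len(taxonomy))]
    n_filler = 258 - len(named) - len(GRADIENT_GENES) - len(private) - len(SEQ_GENES)
    fillers = [f"gene_{i + 1:03d}" for i in range(n_filler)]
    genes = named + GRADIENT_GENES + private + SEQ_GENES + fillers

    base = 0.1
    means = pd.DataFrame(base, index=[s.name for s in taxonomy], columns=genes)

    subclass_markers: Dict[str, List[str]] = {
        "L2/3 IT": [], "L4/5 IT": [], "L5 IT": [], "L6 IT": [],
        "L6 IT Car3": ["Car3"],
        "L5 ET": ["Fam84b", "Fezf2"], "L5/6 NP": ["Tshz2"],
        "L6 CT": ["Foxp2", "Fezf2"], "L6b": ["Ctgf"],
        "Lamp5": ["Lamp5"], "Sncg": ["Sncg"], "Vip": ["Vip"],
        "Sst": ["Sst"], "Pvalb": ["Pvalb"],
        "astrocyte": ["Aqp4"], "oligodendrocyte": ["Mog", "Sox10"],
        "OPC": ["Pdgfra", "Sox10"], "microglia": ["Cx3cr1"], "PVM": ["Mrc1"],
        "endothelial": ["Flt1"], "SMC": ["Acta2"], "pericyte": ["Kcnj8"],
        "VLMC": ["Slc6a13"],
    }

    for i, s in enumerate(taxonomy):
        if s.class_ == "glutamatergic":
            means.loc[s.name, "Slc17a7"] = 6.0
            if s.group == "IT":
                means.loc[s.name, "Slc30a3"] = 4.0
        elif s.class_ == "GABAergic":
            means.loc[s.name, "Gad1"] = 6.0
            means.loc[s.name, "Gad2"] = 5.0
        for m in subclass_markers[s.subclass]:
            means.loc[s.name, m] = 5.0
        if s.group == "IT":
            for m, centre in IT_LAYER_PROFILES.items():
                means.loc[s.name, m] = 0.1 + _gradient_profile(
                    np.array([s.depth_mean]), centre, IT_LAYER_WIDTH,
                    IT_LAYER_AMPLITUDE)[0]
            for j, other in enumerate(taxonomy):
                if other.group == "IT":
                    means.loc[s.name, private[j]] = 0.1 + _gradient_profile(
                        np.array([s.depth_mean]), other.depth_mean,
                        it_marker_width, it_marker_strength)[0]
            means.loc[s.name, private[i]] += it_marker_boost
        else:
            means.loc[s.name, private[i]] = 8.0

    # each sequential gene is a strong marker of a few clusters
    cluster_names = [s.name for s in taxonomy]
    for j, g in enumerate(SEQ_GENES):
        own = rng.choice(len(cluster_names), size=3, replace=False)
        for ci in own:
            means.loc[cluster_names[ci], g] = 10.0

    # fillers: mild cluster-specific variation
    means.loc[:, fillers] = rng.lognormal(np.log(0.25), 0.4,
                                          size=(len(taxonomy), len(fillers)))
    return genes, means


def _gradient_profile(depth: np.ndarray, centre: float, width: float = 0.18,
                      amplitude: float = 4.0) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((depth - centre) / width) ** 2)


@dataclass
class AtlasConfig:
    """Study conditions of the synthetic atlas."""

    n_cells: int = 30000
    seed: int = 0
    taxonomy: List[ClusterSpec] = field(default_factory=default_taxonomy)
    n_batches: int = 2
    batch_effect: float = 0.30       # relative difference of mean totals between batches
    doublet_rate: float = 0.12
    artifact_volume_rate: float = 0.01    # segmentation artifacts (tiny volumes)
    artifact_seq_rate: float = 0.005      # fluorescence-background artifacts
    nb_dispersion: float = 8.0       # gamma shape; larger = closer to Poisson
    mean_total: float = 300.0        # expected raw counts of a 300 µm³ cell, batch scale 1
    volume_median: float = 300.0     # µm³
    volume_sigma: float = 0.30       # lognormal sd of volumes
    n_slices: int = 3
    slice_thickness: Tuple[float, ...] = (850.0, 900.0, 950.0)
    slice_width: float = 1200.0      # µm along x
    surface_curvature: float = 4e-5  # quadratic surface bow, µm^-1
    gradient_amplitude: float = 4.0
    gradient_width: float = 0.18
    it_marker_strength: float = 1.5   # depth-graded component of IT cluster markers
    it_marker_width: float = 0.06     # depth width of IT cluster-marker profiles
    it_marker_boost: float = 6.0      # own-cluster additive component (discreteness)
    depth_max: float = 1.15

    def validate(self) -> None:
        for r in (self.doublet_rate, self.artifact_volume_rate, self.artifact_seq_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if len(self.taxonomy) < 1:
            raise ValueError("taxonomy must contain at least one cluster")
        if len(self.slice_thickness) < self.n_slices:
            raise ValueError("need a thickness per slice")


@dataclass
class SyntheticAtlas:
    matrix: CellByGeneMatrix          # raw counts, cells x genes
    cells: pd.DataFrame               # centroid, volume, slice, batch
    sequential: pd.DataFrame          # cells x 16 sequential-channel signals
    truth: pd.DataFrame               # per-cell ground truth
    cluster_means: pd.DataFrame       # clusters x genes rates used
    config: AtlasConfig

    @property
    def gene_names(self) -> pd.Index:
        return self.matrix.gene_names


def generate_atlas(config: Optional[AtlasConfig] = None, **overrides) -> SyntheticAtlas:
    """Sample a ground-truthed synthetic atlas from the configured conditions."""
    if config is None:
        config = AtlasConfig(**overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    tax = config.taxonomy
    genes, means = build_gene_panel(tax, config.it_marker_strength,
                                    config.it_marker_width,
                                    config.it_marker_boost)
    cluster_names = [s.name for s in tax]
    n_clusters = len(tax)

    n_doublets = int(round(config.doublet_rate * config.n_cells))
    n_art_vol = int(round(config.artifact_volume_rate * config.n_cells))
    n_art_seq = int(round(config.artifact_seq_rate * config.n_cells))
    n_singlets = config.n_cells - n_doublets

    weights = np.array([s.weight for s in tax])
    weights = weights / weights.sum()
    # singlets + extra parents for doublets
    n_profiles = n_singlets + 2 * n_doublets
    cl_idx = rng.choice(n_clusters, size=n_profiles, p=weights)

    depth_mu = np.array([s.depth_mean for s in tax])[cl_idx]
    depth_sd = np.array([s.depth_sd for s in tax])[cl_idx]
    depth = np.clip(rng.normal(depth_mu, depth_sd), 0.0, config.depth_max)

    # per-profile expected expression
    M = means.values[cl_idx].astype(float)
    grad_cols = [genes.index(g) for g in GRADIENT_GENES]
    grad_centres = np.linspace(0.05, 1.0, len(GRADIENT_GENES))
    is_it = np.array([tax[i].group == "IT" for i in cl_idx])
    for j, gc in zip(grad_cols, grad_centres):
        M[is_it, j] = 0.1 + _gradient_profile(depth[is_it], gc,
                                              config.gradient_width,
                                              config.gradient_amplitude)
    # IT layer markers and IT cluster markers track the cell's own depth,
    # not a cluster block value: the IT continuum is a property of cells
    for m, centre in IT_LAYER_PROFILES.items():
        j = genes.index(m)
        M[is_it, j] = 0.1 + _gradient_profile(depth[is_it], centre,
                                              IT_LAYER_WIDTH, IT_LAYER_AMPLITUDE)
    for i, s in enumerate(tax):
        if s.group == "IT":
            j = genes.index(f"mk_{i + 1:03d}")
            M[is_it, j] = 0.1 + _gradient_profile(depth[is_it], s.depth_mean,
                                                  config.it_marker_width,
                                                  config.it_marker_strength)
            own = is_it & (cl_idx == i)
            M[own, j] += config.it_marker_boost

    volumes = rng.lognormal(np.log(config.volume_median), config.volume_sigma,
                            size=n_profiles)
    batches = rng.integers(0, config.n_batches, size=n_profiles)
    batch_scales = np.linspace(1.0 + config.batch_effect / 2,
                               1.0 - config.batch_effect / 2, config.n_batches)
    totals = (config.mean_total * volumes / config.volume_median
              * batch_scales[batches])

    row_rate = M / M.sum(axis=1, keepdims=True) * totals[:, None]
    lam = rng.gamma(config.nb_dispersion, row_rate / config.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    # assemble: first n_singlets are real cells; the rest pair up into doublets
    s_counts = counts[:n_singlets]
    s_cl = cl_idx[:n_singlets]
    s_depth = depth[:n_singlets]
    s_vol = volumes[:n_singlets]
    s_batch = batches[:n_singlets]
    pa = counts[n_singlets:n_singlets + n_doublets]
    pb = counts[n_singlets + n_doublets:]
    d_counts = pa + pb
    d_cl = cl_idx[n_singlets:n_singlets + n_doublets]
    d_cl2 = cl_idx[n_singlets + n_doublets:]
    d_depth = depth[n_singlets:n_singlets + n_doublets]
    d_vol = (volumes[n_singlets:n_singlets + n_doublets]
             + 0.6 * volumes[n_singlets + n_doublets:])
    d_batch = batches[n_singlets:n_singlets + n_doublets]

    all_counts = np.vstack([s_counts, d_counts])
    all_cl = np.concatenate([s_cl, d_cl])
    all_cl2 = np.concatenate([np.full(n_singlets, -1), d_cl2])
    all_depth = np.concatenate([s_depth, d_depth])
    all_vol = np.concatenate([s_vol, d_vol])
    all_batch = np.concatenate([s_batch, d_batch])
    is_doublet = np.concatenate([np.zeros(n_singlets, bool), np.ones(n_doublets, bool)])

    n_total = config.n_cells
    # plant segmentation artifacts: overwrite random singlet cells
    art_vol = np.zeros(n_total, bool)
    art_seq = np.zeros(n_total, bool)
    singlet_pos = np.flatnonzero(~is_doublet)
    pick = rng.choice(singlet_pos, size=n_art_vol + n_art_seq, replace=False)
    vol_pick, seq_pick = pick[:n_art_vol], pick[n_art_vol:]
    art_vol[vol_pick] = True
    art_seq[seq_pick] = True
    small_vol = rng.uniform(20.0, 90.0, size=n_art_vol)
    shrink = small_vol / all_vol[vol_pick]
    all_counts[vol_pick] = rng.binomial(all_counts[vol_pick],
                                        np.clip(shrink, 0, 1)[:, None])
    all_vol[vol_pick] = small_vol

    # geometry
    slice_id = rng.integers(0, config.n_slices, size=n_total)
    x = rng.uniform(0.0, config.slice_width, size=n_total)
    thickness = np.asarray(config.slice_thickness)[slice_id]
    y_surface = config.surface_curvature * (x - config.slice_width / 2) ** 2
    y = y_surface + all_depth * thickness

    order = rng.permutation(n_total)
    cell_ids = pd.Index([f"cell_{i:06d}" for i in range(n_total)], name="cell_id")
    matrix = CellByGeneMatrix(pd.DataFrame(all_counts[order], index=cell_ids,
                                           columns=genes), state="raw")
    cells = pd.DataFrame({
        "x": x[order], "y": y[order], "volume": all_vol[order],
        "slice_id": slice_id[order], "batch_id": all_batch[order]}, index=cell_ids)

    tax_by_name = {s.name: s for s in tax}
    cl_names = np.array(cluster_names)
    truth = pd.DataFrame({
        "cluster": cl_names[all_cl][order],
        "cluster2": [cl_names[i] if i >= 0 else "" for i in all_cl2[order]],
        "subclass": [tax_by_name[c].subclass for c in cl_names[all_cl][order]],
        "class": [tax_by_name[c].class_ for c in cl_names[all_cl][order]],
        "group": [tax_by_name[c].group for c in cl_names[all_cl][order]],
        "depth": all_depth[order],
        "is_doublet": is_doublet[order],
        "is_volume_artifact": art_vol[order],
        "is_seq_artifact": art_seq[order],
        "batch_id": all_batch[order],
        "slice_id": slice_id[order],
    }, index=cell_ids)

    sequential = _sequential_signals(matrix, truth, rng)
    return SyntheticAtlas(matrix=matrix, cells=cells, sequential=sequential,
                          truth=truth, cluster_means=means, config=config)


def _sequential_signals(matrix: CellByGeneMatrix, truth: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """cells x 16 sequential-channel fluorescence, with planted artifact cells.

    Channels 1-8 and 9-16 emulate two detection dyes with different
    background levels; signal tracks the underlying gene count.
    """
    n = len(matrix.cell_ids)
    sig = np.empty((n, len(SEQ_GENES)))
    for j, g in enumerate(SEQ_GENES):
        background = 40.0 if j < 8 else 80.0
        counts = matrix.values[g].values.astype(float)
        sig[:, j] = (background * rng.lognormal(0.0, 0.15, size=n)
                     + 25.0 * counts * rng.lognormal(0.0, 0.10, size=n))
    art = truth["is_seq_artifact"].values
    if art.any():
        hi = np.quantile(sig, 0.97, axis=0)
        for i in np.flatnonzero(art):
            chans = rng.choice(len(SEQ_GENES), size=14, replace=False)
            sig[i, chans] = hi[chans] * rng.uniform(1.2, 2.0, size=14)
    return pd.DataFrame(sig, index=matrix.cell_ids,
                        columns=[f"seqch_{j + 1:02d}" for j in range(len(SEQ_GENES))])


# ---------------------------------------------------------------------------
# retrograde tracer


def _default_target_table(taxonomy: Sequence[ClusterSpec]) -> pd.DataFrame:
    """Per-cluster labelling probability per target.

    IT and L6b clusters carry the bulk of the labels (so that ~90% of
    labelled cells are IT or L6b); two molecularly close deep IT clusters
    get disjoint targets (L6 IT 1 -> MOs only, L6 IT 3 -> TEa-ECT-PERI only).
    """
    rows = {}
    for s in taxonomy:
        p = {t: 0.0 for t in TARGETS}
        if s.name == "L6 IT 1":
            p["MOs"] = 0.22
        elif s.name == "L6 IT 3":
            p["TEa-ECT-PERI"] = 0.22
        elif s.name == "L6 IT 2":
            p["MOs"] = 0.05
            p["TEa-ECT-PERI"] = 0.05
        elif s.subclass == "L2/3 IT":
            p.update(MOs=0.12, SSp=0.10)
            p["TEa-ECT-PERI"] = 0.07
        elif s.subclass == "L4/5 IT":
            p.update(MOs=0.10, SSp=0.09)
            p["TEa-ECT-PERI"] = 0.02
        elif s.subclass == "L5 IT":
            p.update(MOs=0.10, SSp=0.08)
            p["TEa-ECT-PERI"] = 0.08
        elif s.subclass == "L6 IT Car3":
            p["TEa-ECT-PERI"] = 0.10
        elif s.subclass == "L6b":
            p.update(MOs=0.04, SSp=0.03)
            p["TEa-ECT-PERI"] = 0.05
        elif s.class_ == "glutamatergic":
            p.update(MOs=0.0176, SSp=0.0147)
            p["TEa-ECT-PERI"] = 0.0147
        elif s.class_ == "GABAergic":
            p.update(MOs=0.0059, SSp=0.0044)
            p["TEa-ECT-PERI"] = 0.0044
        else:
            p.update(MOs=0.0015, SSp=0.0015)
            p["TEa-ECT-PERI"] = 0.0015
        rows[s.name] = p
    return pd.DataFrame(rows).T[list(TARGETS)]


DEFAULT_TARGET_TABLE = _default_target_table(default_taxonomy())


def generate_tracer(atlas: SyntheticAtlas,
                    target_table: Optional[pd.DataFrame] = None,
                    seed: Optional[int] = None,
                    background_intensity: float = 100.0,
                    label_intensity: float = 2000.0) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sample tracer labels and dye intensities for an atlas.

    Each cell is labelled for each target independently with its cluster's
    probability (multi-target labelling allowed); labelled cells receive a
    bright intensity on top of the lognormal background.  Returns
    (intensity table cells x targets, truth flags cells x targets).
    """
    if target_table is None:
        target_table = _default_target_table(atlas.config.taxonomy)
    if (target_table.sum(axis=1) > 1).any():
        raise ValueError("per-cluster target probabilities must sum to <= 1 per target set")
    rng = np.random.default_rng(atlas.config.seed + 7919 if seed is None else seed)
    clusters = atlas.truth["cluster"]
    n = len(clusters)
    flags = pd.DataFrame(False, index=atlas.matrix.cell_ids, columns=list(target_table.columns))
    for t in target_table.columns:
        p = target_table[t].reindex(clusters).values
        flags[t] = rng.random(n) < p

    inten = pd.DataFrame(index=atlas.matrix.cell_ids, columns=target_table.columns,
                         dtype=float)
    for t in target_table.columns:
        bg = background_intensity * rng.lognormal(0.0, 0.25, size=n)
        on = label_intensity * rng.lognormal(0.0, 0.30, size=n)
        inten[t] = bg + np.where(flags[t].values, on, 0.0)
    return inten, flags


# ---------------------------------------------------------------------------
# spot image stacks


def generate_spot_stack(codebook: Codebook, n_molecules: int = 200,
                        size: int = 128, pixel_size: float = 0.108,
                        spot_sigma: float = 1.2, amplitude: float = 1.0,
                        amplitude_jitter: float = 0.0, bit_dropout: float = 0.0,
                        background_sigma: float = 0.0, seed: int = 0,
                        entries: Optional[Sequence[str]] = None,
                        min_separation: float = 5.0, ghost_spots: int = 0,
                        ghost_amplitude: float = 0.45) -> ImageStack:
    """Render molecules as Gaussian spots across imaging rounds.

    Each molecule lights up its barcode's on-bit rounds; per-bit amplitudes
    jitter by ``amplitude_jitter`` (lognormal sd), each on-bit drops out with
    probability ``bit_dropout``, and Gaussian background noise of sd
    ``background_sigma`` is added to every round.  Molecules are placed at
    least ``min_separation`` pixels apart (rejection sampling) so that
    ground-truth identity is well defined per spot.  ``ghost_spots`` adds
    dim background artifacts that light a random weight-4 round pattern —
    the false-positive process that blank barcodes are designed to monitor;
    ghosts carry no ground-truth entry.  Ghost patterns have weight 3, 4 or
    5: one bit short of, equal to, or one bit beyond the code weight, i.e.
    the error patterns single-error correction is exposed to.  Ground-truth
    positions and identities of real molecules ride along in the stack.
    """
    rng = np.random.default_rng(seed)
    density = n_molecules * (6 * spot_sigma) ** 2 / size ** 2
    if density > 0.5:
        import warnings
        warnings.warn("molecule density is high; overlapping spots make "
                      "ground-truth evaluation unreliable")
    names = list(entries) if entries is not None else codebook.names
    pixels = np.zeros((codebook.n_bits, size, size))
    margin = 6.0
    truth: List[Tuple[float, float, str]] = []
    placed: List[Tuple[float, float]] = []
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_molecules):
        name = names[rng.integers(len(names))]
        bc = codebook.entries[name]
        for _attempt in range(200):
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            if min_separation <= 0 or not placed:
                break
            pa = np.asarray(placed)
            if np.min((pa[:, 0] - cx) ** 2 + (pa[:, 1] - cy) ** 2) >= min_separation ** 2:
                break
        placed.append((cx, cy))
        spot = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spot_sigma ** 2))
        for b in np.flatnonzero(bc):
            if bit_dropout > 0 and rng.random() < bit_dropout:
                continue
            amp = amplitude * (rng.lognormal(0.0, amplitude_jitter)
                               if amplitude_jitter > 0 else 1.0)
            pixels[b] += amp * spot
        truth.append((cx * pixel_size, cy * pixel_size, name))
    for _ in range(ghost_spots):
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        spot = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spot_sigma ** 2))
        w = codebook.weight + int(rng.integers(-1, 2))
        rounds = rng.choice(codebook.n_bits, size=w, replace=False)
        for b in rounds:
            amp = ghost_amplitude * rng.lognormal(0.0, amplitude_jitter
                                                  if amplitude_jitter > 0 else 0.25)
            pixels[b] += amp * spot
    if background_sigma > 0:
        pixels += np.abs(rng.normal(0.0, background_sigma, size=pixels.shape))
    return ImageStack(pixels=pixels, pixel_size=pixel_size, ground_truth=truth)
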