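"""Marker-gene panel selection and encoding-probe design.

Panel selection combines three routes, mirroring how combinatorial-FISH
panels are assembled from reference single-cell clustering:

* a manually curated marker list,
* the genes carrying the most mutual information about cluster identity
  (expression binarized at zero counts),
* pairwise differential-expression (DE) genes chosen so that every ordered
  cluster pair is covered by a minimum number of markers in each direction,
  reduced to a small set with a greedy cover.

Genes that are too short to host enough encoding probes, or so highly
expressed that combinatorial imaging would saturate, are routed to
sequential (one gene per round) imaging.  Encoding probes tile the
transcript with 30-mer targets that may overlap up to 20 nt when the
transcript is short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceExpression",
    "PanelSelection",
    "Probe",
    "ProbeSet",
    "mutual_information_ranking",
    "binary_mutual_information",
    "de_genes_for_pair",
    "greedy_marker_cover",
    "screen_for_sequential",
    "design_encoding_probes",
    "probe_capacity",
]


@dataclass
class ReferenceExpression:
    """Reference cells x genes counts with per-cell cluster labels.

    ``class_of`` maps each cluster name to ``excitatory`` / ``inhibitory`` /
    ``other`` so selection can be restricted to one neuronal group.
    """

    matrix: pd.DataFrame           # cells x genes, non-negative counts
    labels: pd.Series              # per-cell cluster name, aligned to matrix.index
    class_of: Mapping[str, str]    # cluster -> excitatory | inhibitory | other

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, index=self.matrix.index)
        if self.labels.isna().any():
            raise ValueError("every cell needs a cluster label")
        if (self.matrix.values < 0).any():
            raise ValueError("counts must be non-negative")

    def clusters_in_group(self, group: str) -> List[str]:
        return [c for c in pd.unique(self.labels) if self.class_of.get(c) == group]


@dataclass
class PanelSelection:
    manual: List[str]
    mi_selected: List[str]
    de_selected: List[str]
    per_pair_coverage: Dict[Tuple[str, str], List[str]] = field(default_factory=dict)
    uncoverable: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def final_panel(self) -> List[str]:
        seen: Dict[str, None] = {}
        for g in list(self.manual) + list(self.mi_selected) + list(self.de_selected):
            seen.setdefault(g)
        return list(seen)


def binary_mutual_information(on: np.ndarray, labels: np.ndarray) -> float:
    """I(X;Y) in bits for a binary variable X against a categorical label Y."""
    on = np.asarray(on, dtype=bool)
    labels = np.asarray(labels)
    n = len(on)
    mi = 0.0
    p_on = on.mean()
    px = np.array([1.0 - p_on, p_on])
    for lab in np.unique(labels):
        sel = labels == lab
        py = sel.mean()
        for x in (0, 1):
            pxy = np.mean(sel & (on == bool(x)))
            if pxy > 0:
                mi += pxy * np.log2(pxy / (px[x] * py))
    return float(max(mi, 0.0))


def mutual_information_ranking(ref: ReferenceExpression, group: str,
                               top_n: int = 50) -> List[str]:
    """Rank genes by mutual information with cluster identity within a group.

    Expression is binarized at zero counts.  Ties are broken by gene-name
    order so the ranking is deterministic.
    """
    clusters = ref.clusters_in_group(group)
    if len(clusters) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 clusters")
    mask = ref.labels.isin(clusters).values
    sub = ref.matrix.loc[mask]
    labs = ref.labels.loc[mask].values
    on = sub.values > 0
    scores = [binary_mutual_information(on[:, j], labs) for j in range(on.shape[1])]
    order = sorted(zip(sub.columns, scores), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in order[:top_n]]


def de_genes_for_pair(ref: ReferenceExpression, fg: str, bg: str,
                      top_n: int = 50, fold: float = 2.0, p_max: float = 0.05,
                      min_fg_fraction: float = 0.40,
                      min_enrichment: float = 3.0) -> List[str]:
    """DE genes for an ordered (foreground, background) cluster pair.

    A gene passes when all four criteria hold: mean fold-change fg/bg >=
    ``fold``; p < ``p_max`` from a two-group one-way test on log1p values
    (two-group ANOVA, evaluated as the equivalent equal-variance t-test);
    fraction of fg cells expressing (count > 0) >= ``min_fg_fraction``; and
    expressing-fraction ratio fg/bg > ``min_enrichment`` (ratio is +inf when
    no bg cell expresses).  Passing genes are ranked by p ascending.
    """
    fg_m = ref.matrix.loc[(ref.labels == fg).values]
    bg_m = ref.matrix.loc[(ref.labels == bg).values]
    if len(fg_m) == 0 or len(bg_m) == 0:
        raise ValueError("both clusters must be non-empty")
    if len(fg_m) < 2 or len(bg_m) < 2:
        raise ValueError("p-value undefined for clusters with < 2 cells")

    mean_fg = fg_m.mean(axis=0)
    mean_bg = bg_m.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_fg / mean_bg
        fc = fc.where(mean_bg > 0, np.inf)
        fc = fc.where(mean_fg > 0, 0.0)

    frac_fg = (fg_m > 0).mean(axis=0)
    frac_bg = (bg_m > 0).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(frac_bg > 0, frac_fg / frac_bg,
                          np.where(frac_fg > 0, np.inf, 0.0))
    enrich = pd.Series(enrich, index=ref.matrix.columns)

    t, p = stats.ttest_ind(np.log1p(fg_m.values), np.log1p(bg_m.values),
                           axis=0, equal_var=True)
    p = pd.Series(np.where(np.isnan(p), 1.0, p), index=ref.matrix.columns)

    passed = (fc >= fold) & (p < p_max) & (frac_fg >= min_fg_fraction) & (enrich > min_enrichment)
    genes = ref.matrix.columns[passed.values]
    ranked = sorted(genes, key=lambda g: (p[g], g))
    return ranked[:top_n]


def greedy_marker_cover(candidates: Mapping[Tuple[str, str], Sequence[str]],
                        seed_panel: Sequence[str],
                        min_per_direction: int = 2) -> PanelSelection:
    """Greedy minimal cover of every ordered (fg, bg) cluster pair.

    Starting from ``seed_panel``, iteratively adds the candidate gene that
    covers the most still-deficient ordered pairs until each pair has
    >= ``min_per_direction`` covered genes or no candidate helps.  Pairs that
    cannot reach the requirement are flagged, never dropped.
    """
    cand = {pair: list(genes) for pair, genes in candidates.items()}
    selected: List[str] = []
    covered: Dict[Tuple[str, str], List[str]] = {pair: [] for pair in cand}

    def update_cover(gene: str) -> None:
        for pair, genes in cand.items():
            if gene in genes and gene not in covered[pair]:
                covered[pair].append(gene)

    for g in seed_panel:
        update_cover(g)

    all_genes = sorted({g for genes in cand.values() for g in genes})
    while True:
        deficient = [p for p in cand if len(covered[p]) < min_per_direction]
        if not deficient:
            break
        best_gene, best_score = None, 0
        chosen = set(seed_panel) | set(selected)
        for g in all_genes:
            if g in chosen:
                continue
            score = sum(1 for p in deficient if g in cand[p] and g not in covered[p])
            if score > best_score:
                best_gene, best_score = g, score
        if best_gene is None:
            break
        selected.append(best_gene)
        update_cover(best_gene)

    uncoverable = [p for p in cand if len(covered[p]) < min_per_direction]
    return PanelSelection(manual=list(seed_panel), mi_selected=[],
                          de_selected=selected, per_pair_coverage=covered,
                          uncoverable=uncoverable)


def probe_capacity(transcript_length: int, target_len: int = 30,
                   max_overlap: int = 20) -> int:
    """Maximum number of targets with adjacent overlap <= ``max_overlap``."""
    if transcript_length < target_len:
        return 0
    return (transcript_length - target_len) // (target_len - max_overlap) + 1


def screen_for_sequential(ref: ReferenceExpression, panel: Sequence[str],
                          transcripts: Mapping[str, str],
                          max_mean_count: float = 200.0,
                          min_probes: int = 48, target_len: int = 30,
                          max_overlap: int = 20) -> Tuple[List[str], List[str]]:
    """Split a panel into combinatorially imaged and sequentially imaged genes.

    A gene goes to the sequential rounds when its transcript cannot host
    ``min_probes`` probes (with maximal overlap) or its mean count in any
    cluster reaches ``max_mean_count``.
    """
    missing = [g for g in panel if g not in transcripts]
    if missing:
        raise KeyError(f"missing transcripts for: {missing}")
    cluster_means = ref.matrix.groupby(ref.labels.values).mean()
    combinatorial, sequential = [], []
    for g in panel:
        cap = probe_capacity(len(transcripts[g]), target_len, max_overlap)
        max_mean = float(cluster_means[g].max()) if g in cluster_means.columns else 0.0
        if cap < min_probes or max_mean >= max_mean_count:
            sequential.append(g)
        else:
            combinatorial.append(g)
    return combinatorial, sequential


@dataclass
class Probe:
    target_start: int           # 0-based transcript offset
    target_seq: str             # 30-mer target
    readout_ids: Tuple[int, ...]


@dataclass
class ProbeSet:
    gene: str
    mode: str                   # "combinatorial" | "sequential"
    probes: List[Probe]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene,
             "start": [p.target_start for p in self.probes],
             "target_seq": [p.target_seq for p in self.probes],
             "readout_ids": [";".join(map(str, p.readout_ids)) for p in self.probes],
             "mode": self.mode})


def _pair_cycle(on_bits: Sequence[int], rng: np.random.Generator) -> Iterable[Tuple[int, int]]:
    """Cycle through all 2-subsets of the on-bits in a seeded order.

    Cycling the full set of pairs uses every on-bit equally often, so readout
    usage stays balanced across the gene's probes.
    """
    import itertools
    pairs = list(itertools.combinations(on_bits, 2))
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    while True:
        for p in pairs:
            yield p


def design_encoding_probes(transcript: str, mode: str, n_probes: int,
                           barcode: Optional[np.ndarray] = None,
                           readout_id: Optional[int] = None,
                           target_len: int = 30, max_overlap: int = 20,
                           seed: int = 0, gene: str = "gene") -> ProbeSet:
    """Place 30-mer targets on a transcript and attach readout identities.

    Non-overlapping placement is preferred; overlapping placement (up to
    ``max_overlap`` nt) is used only when needed to reach ``n_probes``.
    Combinatorial probes carry 2 readout ids drawn from the barcode's on-bits
    with balanced usage; sequential probes carry the single gene readout.
    """
    L = len(transcript)
    if L < target_len:
        raise ValueError(f"transcript length {L} < target length {target_len}")
    cap = probe_capacity(L, target_len, max_overlap)
    n = min(n_probes, cap)
    rng = np.random.default_rng(seed)

    cap_disjoint = L // target_len
    if n <= cap_disjoint:
        # seeded sample of n disjoint slots
        slots = sorted(rng.choice(cap_disjoint, size=n, replace=False))
        starts = [int(s) * target_len for s in slots]
    else:
        # deterministic evenly spaced grid with bounded overlap
        starts = [round(i * (L - target_len) / (n - 1)) for i in range(n)] if n > 1 else [0]

    if mode == "combinatorial":
        if barcode is None:
            raise ValueError("combinatorial mode needs a barcode")
        on_bits = [int(i) for i in np.flatnonzero(np.asarray(barcode))]
        pairs = _pair_cycle(on_bits, rng)
        readouts = [tuple(sorted(next(pairs))) for _ in range(n)]
    elif mode == "sequential":
        if readout_id is None:
            raise ValueError("sequential mode needs a readout id")
        readouts = [(int(readout_id),)] * n
    else:
        raise ValueError(f"unknown mode {mode!r}")

    probes = [Probe(target_start=s, target_seq=transcript[s:s + target_len],
                    readout_ids=r) for s, r in zip(starts, readouts)]
    return ProbeSet(gene=gene, mode=mode, probes=probes)
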