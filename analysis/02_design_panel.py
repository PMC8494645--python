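#!/usr/bin/env python
"""Select a marker panel from reference expression and design encoding probes.

Uses a synthetic clustered reference (standing in for the droplet/plate
single-cell data a real panel is designed from): ranks genes by mutual
information within the excitatory and inhibitory groups, finds pairwise DE
genes for neighbouring inhibitory clusters, reduces them with the greedy
cover (>= 2 genes per direction per pair), screens for genes needing
sequential imaging, and places 30-mer encoding probes.  Writes
results/panel_selection.csv and results/probes.csv.
"""

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from mopatlas import synth
from mopatlas.codebook import build_codebook
from mopatlas.panel import (
    ReferenceExpression,
    de_genes_for_pair,
    design_encoding_probes,
    greedy_marker_cover,
    mutual_information_ranking,
    screen_for_sequential,
)

OUT = Path("results")
MANUAL_MARKERS = ["Slc17a7", "Slc30a3", "Gad1", "Gad2", "Lamp5", "Sncg", "Vip",
                  "Sst", "Pvalb", "Aqp4", "Mog", "Pdgfra", "Cx3cr1", "Mrc1",
                  "Flt1", "Acta2", "Kcnj8", "Slc6a13", "Sox10"]


def main() -> None:
    atlas = synth.generate_atlas(n_cells=8000, seed=21)
    tr = atlas.truth[~atlas.truth.is_doublet]
    class_of = {s.name: {"glutamatergic": "excitatory",
                         "GABAergic": "inhibitory"}.get(s.class_, "other")
                for s in atlas.config.taxonomy}
    ref = ReferenceExpression(matrix=atlas.matrix.values.loc[tr.index],
                              labels=tr["cluster"], class_of=class_of)

    mi_exc = mutual_information_ranking(ref, "excitatory", top_n=50)
    mi_inh = mutual_information_ranking(ref, "inhibitory", top_n=50)
    mi_genes = sorted(set(mi_exc) | set(mi_inh))
    print(f"mutual information: top 50 + top 50 -> {len(mi_genes)} distinct genes")

    # pairwise DE + greedy cover, demonstrated on the inhibitory clusters
    inh = [c for c in ref.clusters_in_group("inhibitory")
           if (tr["cluster"] == c).sum() >= 10]
    cands = {}
    for fg, bg in itertools.permutations(inh, 2):
        cands[(fg, bg)] = de_genes_for_pair(ref, fg, bg, top_n=50)
    sel = greedy_marker_cover(cands, seed_panel=MANUAL_MARKERS, min_per_direction=2)
    print(f"greedy DE cover over {len(cands)} ordered pairs: "
          f"+{len(sel.de_selected)} genes, {len(sel.uncoverable)} uncoverable pairs")

    panel = sorted(set(MANUAL_MARKERS) | set(mi_genes) | set(sel.de_selected))
    rng = np.random.default_rng(2)
    transcripts = {g: "".join(rng.choice(list("ACGT"), size=int(L)))
                   for g, L in zip(panel, rng.integers(400, 4000, len(panel)))}
    comb, seq = screen_for_sequential(ref, panel, transcripts)
    print(f"panel: {len(panel)} genes -> {len(comb)} combinatorial, {len(seq)} sequential")

    cb = build_codebook(22, 4, 4, len(comb), 10, seed=1, gene_names=comb)
    frames = []
    for g in comb:
        ps = design_encoding_probes(transcripts[g], "combinatorial", 92,
                                    barcode=cb.barcode_of(g), seed=3, gene=g)
        frames.append(ps.to_frame())
    for j, g in enumerate(seq):
        ps = design_encoding_probes(transcripts[g], "sequential", 48,
                                    readout_id=22 + j, seed=3, gene=g)
        frames.append(ps.to_frame())
    probes = pd.concat(frames, ignore_index=True)

    OUT.mkdir(exist_ok=True)
    pd.DataFrame({"gene": panel,
                  "manual": [g in MANUAL_MARKERS for g in panel],
                  "mi": [g in mi_genes for g in panel],
                  "de": [g in sel.de_selected for g in panel],
                  "mode": ["sequential" if g in seq else "combinatorial"
                           for g in panel]}).to_csv(OUT / "panel_selection.csv",
                                                    index=False)
    probes.to_csv(OUT / "probes.csv", index=False)
    print(f"designed {len(probes)} probes; wrote {OUT/'panel_selection.csv'}, "
          f"{OUT/'probes.csv'}")


if __name__ == "__main__":
    main()
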