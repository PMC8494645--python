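#!/usr/bin/env python
"""Laminar depth statistics of the synthetic atlas.

Fits the cortical surface through the VLMC layer per slice, normalizes soma
depths by the median L6b depth, derives layer boundaries from the most
superficial designated clusters, and summarizes depth distributions and
neighbourhood complexity (distinct clusters within 100 um).  Writes
results/depths.csv, results/layer_boundaries.csv and a violin figure.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from mopatlas import spatial, synth

OUT = Path("results")
SEED = 1


def main() -> None:
    atlas = synth.generate_atlas(n_cells=30000, seed=SEED)
    tr = atlas.truth[~atlas.truth.is_doublet & ~atlas.truth.is_volume_artifact]
    cells = atlas.cells.loc[tr.index]

    prof = spatial.fit_surface_and_depth(cells, tr["cluster"])
    err = (prof.depth - tr["depth"]).abs()
    print(f"recovered depths: median |error| {err.median():.4f} "
          f"(95th pct {err.quantile(0.95):.4f}) over {prof.depth.notna().sum()} cells")

    lb = spatial.layer_boundaries(prof.depth, tr["cluster"])
    print("layer boundaries (normalized depth):")
    for name, v in lb.ordered():
        print(f"  {name:<10s} {v:.3f}")
    print(f"  L5 upper-boundary uncertainty interval: "
          f"({lb.l5_uncertainty[0]:.3f}, {lb.l5_uncertainty[1]:.3f})")

    nc = spatial.neighborhood_complexity(cells, tr["cluster"], radius=100.0)
    print(f"neighbourhood complexity: median {nc.median():.0f} distinct "
          f"clusters within 100 um (max {nc.max()})")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame({"depth": prof.depth, "cluster": tr["cluster"],
                  "complexity": nc}).to_csv(OUT / "depths.csv")
    pd.Series(lb.boundaries).to_csv(OUT / "layer_boundaries.csv",
                                    header=["normalized_depth"])

    # violin of IT cluster depth distributions, superficial to deep
    it = tr[tr["group"] == "IT"]
    order = (prof.depth.loc[it.index].groupby(it["cluster"]).median()
             .sort_values().index)
    fig, ax = plt.subplots(figsize=(10, 4))
    data = [prof.depth.loc[it.index[it["cluster"] == c]].dropna() for c in order]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(order) + 1))
    ax.set_xticklabels(order, rotation=90, fontsize=7)
    ax.set_ylabel("normalized cortical depth")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(OUT / "it_depth_violins.png", dpi=150)
    print(f"wrote {OUT/'depths.csv'}, {OUT/'layer_boundaries.csv'}, "
          f"{OUT/'it_depth_violins.png'}")


if __name__ == "__main__":
    main()
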