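# mopatlas

A tested, reusable implementation of the computational pipeline behind a
spatially resolved cell atlas of the mouse primary motor cortex (MOp) built
from multiplexed error-robust FISH (MERFISH)-style data — from barcode
design and image decoding through cell-level QC, two-round clustering,
laminar depth statistics, expression-gradient analyses, and
retrograde-projection mapping.

It is aimed at computational biologists who want to study, test, or adapt
the individual stages of such a pipeline. Because the raw imaging data of
an atlas experiment are terabyte-scale, the package ships a first-class
synthetic-data generator (`mopatlas.synth`) that emulates the statistical
structure every stage assumes — a 95-cluster taxonomy (39 excitatory,
42 inhibitory, 14 non-neuronal in 23 subclasses), laminar depth
distributions, a depth-graded IT (intratelencephalic) expression continuum,
negative-binomial counts with ~30% between-batch variation, 12% doublets,
segmentation artifacts, and per-cluster projection compositions — with full
ground truth, so every stage is validated by parameter recovery.

## The pipeline

1. **Codebook** (`mopatlas.codebook`). Each gene gets a binary barcode from
   a 22-bit, Hamming-weight-4, minimum-distance-4 code, read out over 22
   imaging rounds. The generator enumerates all weight-4 words whose on-bit
   positions satisfy Σᵢ i ≡ 0 (mod 22); any two such words share ≤ 2
   positions, forcing d(w, w′) ≥ 4, which corrects any single-bit error.
   The construction yields 335 codewords — enough for 242 genes plus 10
   unassigned "blank" barcodes whose call rate estimates the false-positive
   rate.
2. **Panel design** (`mopatlas.panel`). Marker genes are selected from
   clustered reference expression by mutual information I(X; cluster) on
   zero-binarized counts, plus pairwise differential expression
   (fold-change ≥ 2, p < 0.05, foreground expressing fraction ≥ 0.40,
   expressing-fraction ratio > 3) reduced by a greedy cover to ≥ 2 genes
   per direction for every cluster pair. Short or very highly expressed
   genes (≥ 200 mean counts in any cluster, or < 48 probe sites) are routed
   to sequential imaging rounds. Encoding probes tile transcripts with
   30-mers overlapping ≤ 20 nt.
3. **Spot decoding** (`mopatlas.decoding`). Image stacks are high-pass
   filtered, Lucy–Richardson deconvolved (20 iterations), and low-pass
   smoothed; each pixel's round-intensity vector is bit-called and decoded
   with single-error correction; 4-connected same-barcode pixels merge into
   molecules; a quality threshold is chosen adaptively so the blank-derived
   misidentification rate — (mean calls per blank barcode)/(mean calls per
   gene barcode) — is as close to 5% as possible without exceeding it.
   Cells are segmented by a seeded watershed (nuclei seed, total-mRNA
   landscape) and molecules aggregate into a cell-by-gene matrix.
4. **QC** (`mopatlas.qc`). Volume filter (< 100 µm³ or > 3× median),
   volume normalization, per-batch scaling of mean totals to 250,
   sequential-channel artifact filter (above the 90% quantile in ≥ 12 of 16
   channels), per-dye background subtraction, 2%/98% total-count quantile
   filter, and simulated-doublet removal (kNN score > 0.18, on a
   posterior-probability scale).
5. **Clustering** (`mopatlas.clustering`). Log-median-total z-scored
   expression, PCs kept while their eigenvalue beats the mean first
   eigenvalue of 20 column-shuffled matrices, Louvain communities on a
   Jaccard-weighted kNN graph. Round 1 (k = 10) routes clusters to five
   groups by markers (IT: *Slc17a7*+*Slc30a3*; non-IT excitatory; CGE:
   *Gad1/2*+*Lamp5/Sncg/Vip*; MGE: *Gad1/2*+*Sst/Pvalb*; non-neuronal);
   round 2 re-clusters each group (k = 40/r = 2 excitatory, k = 15/r = 2
   inhibitory, k = 20/r = 1 non-neuronal); doublet-like clusters
   co-expressing incompatible class markers are removed; a classifier
   (multinomial logistic regression or small MLP) transfers labels between
   datasets.
6. **Spatial statistics** (`mopatlas.spatial`). Soma depth = distance to a
   surface curve fitted through the VLMC layer, normalized per slice by the
   median L6b depth (surface = 0, L6b = 1); layer boundaries from the most
   superficial designated clusters; marker/density overlap statistics;
   neighbourhood complexity (distinct clusters within 100 µm).
7. **Gradient** (`mopatlas.gradient`). Depth-varying genes (range of the
   50-bin mean z-profile > 0.5, ordered by 10-bin rolling-mean peak),
   chance-normalized inter-cluster kNN connectivity (observed/expected
   inter-cluster edges, 19 PCs, k = 12), and diffusion pseudotime from a
   root cell in the most superficial IT cluster.
8. **Projection** (`mopatlas.projection`). Retrograde tracer channels are
   robust-normalized and thresholded into per-target on/off labels; depth
   enrichment = (fraction of a target's labelled cells per bin)/(fraction
   of all IT+L6b cells per bin); per-target compositions over clusters with
   bootstrap confidence intervals.

## Worked example

```python
from mopatlas import synth, workflows
from sklearn.metrics import adjusted_rand_score

atlas = synth.generate_atlas(n_cells=30000, seed=1)
mat, cells, report, assignment = workflows.cluster_atlas(atlas, seed=1)

tab = assignment.table.dropna(subset=["cluster"])
print(tab["cluster"].nunique())          # 94  (95 clusters in the truth)
truth = atlas.truth.loc[tab.index]
print(round(adjusted_rand_score(truth["cluster"], tab["cluster"]), 3))  # 0.905
exc = tab[tab["class"] == "glutamatergic"]
print(round(exc["subclass"].str.contains("IT").mean(), 3))              # 0.694
```

The 30,000-cell default atlas passes QC (doublet stage removes ≈ 11% of
cells, > 90% of them true doublets), the two-round procedure recovers 94 of
the 95 ground-truth clusters with an adjusted Rand index of 0.905 against
the generator's labels, and IT subclasses hold 69.4% of the excitatory
cells, matching the generated composition.

The numbered scripts under `analysis/` walk the full study in order —
codebook (`01`), panel and probes (`02`), decoding and segmentation (`03`),
QC (`04`), clustering (`05`), laminar statistics (`06`), the IT gradient
(`07`), and projection mapping (`08`) — each printing what it found and
writing tables under `results/`. For example, `analysis/06_spatial_stats.py`
reports recovered depths with a median error of 0.004 normalized units and
layer boundaries at 0.15 (L2/3), 0.38 (L4), 0.52–0.54 (L5 uncertainty
interval), 0.72 (L6) and 0.97–1.03 (L6b); `analysis/07_it_gradient.py`
reports a Spearman correlation of 0.94 between diffusion pseudotime and
cortical depth across ~11,000 IT cells.

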