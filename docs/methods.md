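# Methods

This note documents the models, parameter choices and numerical decisions
behind `mopatlas`, and what the synthetic-data generator does and does not
emulate.

## Barcode code and decoding

Barcodes are constant-weight binary words (weight 4) over `n_bits` imaging
rounds with minimum pairwise Hamming distance 4. The primary construction
enumerates, in lexicographic order, all weight-4 words whose on-bit
positions sum to 0 modulo `n_bits` ("sum-residue" construction). If two
such words shared 3 on-bit positions, the residue condition would force the
4th position to coincide modulo `n_bits`, making the words equal; hence any
two distinct words share at most 2 positions and their distance is ≥ 4. At
22 bits this yields 335 codewords; a greedy lexicographic scan (keep a word
iff it is ≥ d away from all kept words) is the fallback for parameter
combinations where the residue construction under-fills. Genes map onto
codewords in input order; blanks are sampled from the remaining pool with
the seed. Decoding returns the unique entry within Hamming distance
`max_errors` (0 or 1); ties or out-of-range words are no-calls — the
decoder never guesses, which keeps the blank-based false-positive
accounting conservative.

## Panel selection

Mutual information is computed on zero-binarized expression
(I(X;Y) = H(X) − H(X|Y), base-2), per neuronal group, ties broken by gene
name. The pairwise DE criteria are: mean fold-change ≥ 2, p < 0.05,
foreground expressing fraction ≥ 0.40, expressing-fraction ratio > 3
(background fraction 0 counts as +∞, i.e. passes). The p-value is a
two-group one-way analysis of log(x+1) values, evaluated as the equivalent
equal-variance two-sample t-test (for two groups the one-way ANOVA F equals
t²). Natural log with pseudocount 1; these were unspecified choices and are
conventional. The greedy cover adds, at each step, the candidate covering
the most ordered (foreground, background) pairs still short of
`min_per_direction`; pairs that cannot be covered are reported, never
dropped. Greedy set cover is not guaranteed minimal; on small instances it
is verified against brute force in the tests.

Probe placement prefers disjoint 30-mer slots (seeded sample of slots) and
falls back to an evenly spaced grid with overlap ≤ 20 nt only when the
requested probe count exceeds the disjoint capacity
(capacity = ⌊(L − 30)/10⌋ + 1 at 20 nt overlap). Combinatorial probes carry
2 of the 4 on-bit readouts, cycling a seeded permutation of all 6 pairs so
each on-bit appears on nearly equal numbers of probes (any ≥ 4 distinct
pairs cover all 4 bits). No melting-temperature or off-target screening is
performed; specificity screening belongs to oligo-design tooling outside
this package's scope.

## Decoding images

Preprocessing per round: background subtraction by Gaussian high-pass
(σ = 3 px default), Lucy–Richardson deconvolution (20 iterations, Gaussian
PSF σ = 1.3 px), Gaussian low-pass (σ = 1 px) to absorb sub-pixel centroid
wobble between rounds. Bit-calling thresholds each pixel's round vector at
the midpoint between the mean of its `weight` brightest rounds and the mean
of the rest; pixels below an intensity floor (10% of the stack maximum by
default) are not called. Candidate molecules are 4-connected components of
same-entry pixels; single-pixel candidates are dropped as noise. The
misidentification rate is (mean calls per blank entry)/(mean calls per
coding entry). The combined quality score is the rank product of mean
on-bit intensity and (1 − barcode distance) — monotone and unitless — and
the adaptive filter retains the longest quality-ranked prefix whose rate
does not exceed the 5% target; its resolution is therefore one blank call
(≈ 0.004 at ~600 retained molecules), and the retained rate sits at or just
under the target.

The pipeline is a 2-D single-plane reduction of a volumetric experiment:
cell "volume" is mask area × a nominal 10 µm slice thickness. All
downstream statistics consume volume as a scalar, so the reduction does not
change their semantics.

## QC cascade

Stage order is fixed: volume filter → volume normalization → batch
normalization → sequential artifact filter → per-dye background
subtraction → total-count quantile filter → doublet removal → dropped-gene
removal. The volume median is computed on all segmented cells before any
removal, and both cutoffs are strict. The 2%/98% totals are computed on the
batch-normalized matrix (the source protocol does not say whether before or
after normalization; after is recorded here as the package's choice, since
the quantiles are otherwise batch-confounded). Dropped sequential genes are
a config list, not hard-coded.

Doublet scores re-implement simulated-doublet kNN scoring: simulated
doublets are sums of random observed pairs (4× the observed count),
everything is total-normalized, log-transformed and embedded in 30 PCs, and
each observed cell's neighbour fraction q of simulated doublets is
converted to the posterior probability of being a doublet,
score = (qρ/r)/(qρ/r + (1−q)(1−ρ)), with prior ρ = expected rate (0.12) and
simulation ratio r. The 0.18 removal threshold therefore acts on a
probability scale. The neighbourhood is deliberately small (k = 5, i.e.
k(1+r) = 25 effective neighbours): with ~95 clusters each heterotypic
doublet species is rare, and a wide neighbourhood dilutes its simulated
counterparts with parent-cluster singlets, costing recall. On default
synthetic data the stage removes ≈ 11% of cells, > 90% of them true
doublets; the shortfall from the nominal 12% contamination is doublets
whose two parents contribute very unequal counts, which are geometrically
indistinguishable from the dominant parent — a recognized blind spot of
simulated-doublet detection. Because pair simulation is positional, doublet
scores are seed- but not cell-order-reproducible; all other stages commute
with cell reordering.

## Two-round clustering

Normalization scales each cell's total to the global median, applies
log(1+x), and z-scores each gene (zero-variance genes get z = 0). The PC
count keeps components whose eigenvalue exceeds the mean first eigenvalue
of 20 independently column-shuffled matrices. The kNN graph carries
shared-nearest-neighbour Jaccard weights — this down-weights stray edges
bridging distinct populations and markedly improves Louvain's behaviour on
expression continua (unweighted graphs let the IT continuum collapse into
a few communities). Louvain runs through a seeded RNG, so all clustering is
bit-reproducible given a seed. Round 1 uses k = 10, resolution 1; routing
assigns each round-1 cluster to one of five groups by cluster-mean marker
z-scores (threshold 0.5); round 2 uses k = 40/r = 2 (IT and non-IT
excitatory), k = 15/r = 2 (CGE, MGE), k = 20/r = 1 (non-neuronal), with PCs
re-selected per group by the shuffle criterion. Clusters whose mean
z-scores exceed the threshold for an incompatible marker pair
(*Slc17a7*+*Gad1*, *Slc17a7*+*Sox10*, *Gad1*+*Sox10*) are flagged as
doublet clusters and removed. Subclass names come from the arg-max
cluster-mean z over the group's subclass markers, and clusters are indexed
within subclass by decreasing size. Bootstrap stability (co-clustering
consistency over subsampled re-clusterings; merge threshold 0.6 by default)
is available but not part of the default pipeline. Label transfer z-scores
train and test independently on their shared genes and uses multinomial
logistic regression by default (a small MLP is config-selectable); on
held-out synthetic cells both reach ≥ 95% accuracy.

## Spatial statistics

The surface of each slice is a degree-2 polynomial fitted through the VLMC
centroids (the surface line is not parameterized at the source; a low-order
polynomial is this package's choice); depth is the shortest Euclidean
distance to the densely sampled curve, normalized by the slice's median L6b
depth. Slices without VLMC or L6b cells are excluded with a warning. Layer
boundaries are medians of designated most-superficial clusters; the L6b
band is the interquartile range of the L6b depths (the distribution "width"
is not quantified at the source; IQR is the recorded choice); the upper
boundary of L5 is reported as an uncertainty interval between the deepest
L4/5-IT-like and the most superficial L5-IT-like cluster medians. Binned
marker profiles use equal-count bins and the bin mean (switchable to
median). Density overlap integrates min(f̂ₐ, f̂ᵦ) of Gaussian KDEs (Scott's
rule; fixed bandwidth override available). Neighbourhood complexity counts
distinct cluster labels within 100 µm in the same slice, including the
index cell's own cluster (minimum 1) — "present within a neighbourhood
surrounding the cell" is ambiguous about the cell itself; inclusion is the
recorded choice.

## Gradient analyses

Depth-varying genes: cells split into 50 equal-count depth bins; a gene
qualifies when its per-bin mean z-score spans > 0.5; ordering is by the
peak of a 10-bin rolling mean. Connectivity: with E undirected kNN edges
and cluster fractions p, the expected inter-cluster edge count under random
endpoint placement is E·2·pₐ·p_b, and the weight is observed/expected —
an unstructured split of one population scores ≈ 1 (verified in tests) and
separated blobs ≈ 0. Weights below 0.1 are filtered for display only.
Pseudotime: diffusion map and diffusion pseudotime are computed with
scanpy on the kNN graph in PC space (19 PCs, k = 12, both re-derivable by
the shuffle criterion); the root cell is the root cluster's member closest
to its PC-space centroid (seeded tie-break). A disconnected graph raises
with component sizes. Exactly coincident expression profiles degenerate the
diffusion kernel (zero-distance neighbours); the duplication-invariance
test adds 1e-6 jitter for this reason.

## Projection statistics

Tracer intensities are robust-normalized per channel ((x − median)/MAD of
the full population, which is background-dominated) and thresholded
stringently (default 10 MADs) so weakly labelled cells stay off. The
tracer-imaged dataset passes the same doublet filter as any other dataset
before label transfer — doublets otherwise inherit arbitrary transferred
identities and dilute composition estimates. Depth enrichment uses 20
equal-count bins of the reference (IT + L6b) population (bin count
unstated at the source; 20 recorded here); empty reference bins are
reported missing, not zero. Compositions come with bootstrap-over-cells
percentile confidence intervals.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Taxonomy: 95 clusters (39 excitatory / 42 inhibitory / 14
non-neuronal) in 23 subclasses; class composition 60% excitatory (70% of
which IT), 15% inhibitory, 25% non-neuronal; within-subclass abundances
vary smoothly (±30% around equality, fixed by a structure seed). Counts are
gamma–Poisson (negative binomial, dispersion 8) with expected totals
proportional to cell volume (lognormal, median 300 µm³, σ = 0.30) and a
30% between-batch difference in mean totals. Doublets (12% of cells) are
sums of two independently sampled cell profiles; segmentation artifacts
(1%) have volumes of 20–90 µm³ with proportionally thinned counts;
fluorescence artifacts (0.5%) are bright in 14 of 16 sequential channels.
Depth geometry: 3 slices of 850–950 µm thickness with a mildly curved
surface; each cluster's depth is truncated-normal around its laminar
centre; VLMCs sit at the surface and L6b at normalized depth ~1.

The gene panel has 258 genes: real marker symbols for classes, subclasses
and IT layers; 20 gradient genes whose means follow Gaussian depth profiles
(amplitude 4, width 0.18) in IT cells; one cluster-defining marker per
cluster; 16 sequential-round genes (4 of which emulate poorly staining
genes dropped in QC); and low-level fillers. Non-IT clusters are discrete
(block markers, rate 8 vs baseline 0.1). IT clusters are a continuum with
partial discreteness: their layer markers and cluster markers follow depth
profiles evaluated at each *cell's* depth (widths 0.16 and 0.06), plus an
own-cluster additive component (rate 6) that keeps clusters molecularly
identifiable. This balance is the central modelling decision: it
simultaneously reproduces the two findings the pipeline must recover —
~95 separable clusters (two-round clustering recovers 94–95 with ARI ≈ 0.9
at 30,000 cells) and a spatial/molecular IT gradient (pseudotime–depth
Spearman ≥ 0.94; each cluster's strongest connectivity edge goes to a
depth-adjacent cluster). Tracer labelling probabilities are set per cluster
so that IT + L6b clusters carry 90% of labels (calibrated analytically from
the taxonomy weights), with one deep-IT cluster projecting only to MOs and
another only to TEa–ECT–PERI, emulating molecularly close clusters with
disjoint targets. Spot images render each on-bit as a Gaussian spot
(σ = 1.2 px) with optional amplitude jitter, bit dropout, background noise
and dim "ghost" artifacts of weight 3–5 round patterns — the error patterns
single-error correction is exposed to — which generate the false-positive
calls the blank barcodes monitor.

What the generator does **not** emulate: tissue morphology and vasculature,
3-D nuclear texture, optical crowding at realistic molecular density,
cluster-specific capture efficiency, spatial autocorrelation of batch
effects, or absolute per-gene expression levels of real cortex. Passing
the recovery tests therefore shows the pipeline's statistical machinery is
correct under its stated assumptions, not that it would meet the same
numbers on real images.

## Problem sizes and determinism

Default validation scales are chosen so the whole suite runs on a laptop:
30,000-cell atlas for clustering recovery, 10,000 cells for doublet and
tracer statistics, 300²-pixel fields with 600 molecules for decoding. All
stochastic steps (generator, PCA solver, Louvain, bootstraps, root-cell
tie-breaks) consume explicit seeds and reproduce bit-identically; the only
exception, noted above, is cell-order sensitivity of the doublet-pair
simulation.
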