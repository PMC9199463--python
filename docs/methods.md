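# Methods

This note documents the statistical procedures implemented in `perimark`,
the synthetic data they are validated on, and the numerical conventions
that make runs reproducible and diffable.

## Preprocessing

**Log-normalization.** Counts are depth-normalized per cell and
log-transformed: `x_gj = ln(1 + c_gj · S / L_j)` with `L_j` the cell's
library size and scale factor `S = 10,000`, the de facto droplet
convention. Zero counts map to zero, so sparsity is preserved; cells with
zero library size are an error (their barcodes are listed) rather than
silently dropped. The transform is monotone per gene and cell.

**Highly variable genes (VST).** For each gene we compute the mean and
variance of the *raw* counts, fit a local polynomial regression (degree 2,
tricube weights, span 0.3 — the published defaults of the
variance-stabilizing-transform method) of log10 variance on log10 mean over
genes with positive variance, and use the fitted trend as the expected
standard deviation. Counts are standardized by `(c − μ)/σ_expected`,
clipped at `√n_cells`, and the gene's variability score is the variance of
the clipped values. The top `n_hvg = 2,000` genes by score are kept (ties
broken by gene ID; if the universe is smaller, all genes are used with a
warning). The local regression is implemented in-package as a
tricube-weighted local quadratic fit; window size is
`min(max(⌈span·n⌉, 3), n)`.

**Scaling and PCA.** HVG expression is z-scored per gene over cells using
the population standard deviation (this makes the decomposition exactly
invariant to duplicating every cell), clipped at ±10, re-centered, and
decomposed by SVD. Per-component explained variance is `s²/(n−1)`. Sign
convention: each component is flipped so that its largest-magnitude gene
loading is positive, which pins the output across linear-algebra backends.
Default component counts are tissue-specific — 45 for kidney, 30 for
bladder, 35 otherwise — chosen from the explained-variance profiles
typical of these tissues' atlases; all are configurable.

## Clustering

**k-NN and SNN graph.** Exact Euclidean k-nearest neighbors in PC space
(`k = 20`); each cell's neighbor set contains the cell itself plus its
k−1 nearest others, with distance ties broken toward the lower cell index.
Edges are weighted by the Jaccard similarity of neighbor sets,
`|N_i ∩ N_j| / |N_i ∪ N_j|`, and edges below `prune = 1/15` are removed.
`k` and the prune threshold follow the community-standard defaults for
SNN clustering of droplet data.

**Louvain.** Communities maximize the resolution-scaled modularity
`Q(γ) = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/(2m)] δ(cᵢ,cⱼ)` over ordered node pairs
(aggregated-level self-loops count once), with `γ = 0.5`. The sweep order
is shuffled by the seed; a local move is accepted only when it improves Q
by more than 1e-10, with gain ties resolved toward the lower community id;
phases of local moves and graph aggregation repeat until no move improves
Q. Modularity is recorded after every pass and asserted non-decreasing.
Disconnected components and isolated nodes are handled naturally (an
edgeless graph yields singletons). Final cluster ids are contiguous from
0, ordered by decreasing size with ties broken by the smallest member
index. The implementation is validated against an exhaustive-partition
oracle on graphs of up to 8 nodes and cross-checked against igraph's
multilevel algorithm; note that the modularity optimum need not coincide
with planted structure on sparse graphs (at `k = 10` a two-cloud geometry
legitimately splits into five communities with higher Q — at the default
`k = 20` the clouds are recovered exactly).

## Gating stringent pericytes

"Expressing" always means raw count > 0; no magnitude threshold is applied
anywhere in the gate or the percent-expressed statistics, since detection
in droplet data is the robustly observable event.

A cluster is **pericyte-enriched** when its dual-positive fraction
(cells with both canonical markers, *Cspg4* and *Pdgfrb* by default,
at count > 0) satisfies two conditions: `f_c ≥ min_dual_fraction` (default
0.05, below the lowest stringent proportion a comparable cluster would
show) and `f_c ≥ fold_over_global × f_out` where `f_out` is the
dual-positive fraction among cells *outside* the candidate cluster
(default fold 5). The background excludes the candidate cluster itself:
with an inclusive background a single hot cluster in an otherwise cold
tissue could fail its own enrichment test purely because it dominates the
global fraction. Several clusters may qualify; they are pooled for gating.
If none qualifies the tissue is flagged and its marker/GSEA stages are
skipped while other tissues proceed.

**Stringent pericytes** are the cells inside enriched clusters with both
marker counts > 0. The per-tissue summary reports the stringent count, the
enriched-cluster cell count and their ratio, plus a cross-tissue total row
that conserves the per-tissue counts exactly.

## Marker discovery

**Wilcoxon rank-sum test.** Two modes share midrank handling:

* *exact* — the full permutation distribution of the rank sum over all
  C(n+m, n) group assignments, computed by a subset-sum polynomial over
  doubled midranks (midranks are half-integers, so doubling makes them
  integers and ties are handled exactly). Two-sided p is the probability
  of a deviation from the mean rank sum at least as large as observed.
* *normal* — mean `n(N+1)/2`, tie-corrected variance
  `nm/12 · [(N+1) − Σ(t³−t)/(N(N−1))]`, continuity correction 0.5. This
  reproduces the standard asymptotic two-sided p to machine precision.

The normal approximation's worst-case deviation from the exact p is below
0.02 once both groups have ≥ 5 observations, but grows to ~0.13 for a
group of 1 — an intrinsic property of the approximation, which is why the
DE stage requires at least 3 cells per group and realistic runs have far
more.

**DE table.** Genes detected in ≥ 3 cells are tested on normalized values
(stringent vs all other cells of the tissue, including non-stringent cells
inside enriched clusters). P-values are adjusted by Benjamini–Hochberg
step-up across tested genes (delegated to statsmodels). The fold change is
`log2((mean(eˣ−1 | stringent)+1) / (mean(eˣ−1 | other)+1))` — de-logged
normalized means with pseudocount 1 on both sides, symmetric and exactly
zero for identical groups. `pct1`/`pct2` are expressing fractions from raw
counts over stringent / all-other cells; `pct3` is the maximum expressing
fraction across clusters excluding the enriched one(s), computed for all
tested genes.

**Selection.** Strict inequalities throughout:
selected ⟺ `p_adj < 0.05 ∧ pct1 > 0.80 ∧ pct2 < 0.05`;
high-specificity additionally requires `pct3 < 0.10`. The
percent-expressed statistics are computed on raw counts: the count > 0
detection convention refers to the measured data, and depth normalization
cannot change which entries are zero.

**Cross-tissue comparison.** Every gene in the union of selected marker
sets is assigned to exactly one membership pattern (the set of tissues
selecting it); pattern sizes conserve the union size.

## Pre-ranked GSEA

Genes are ranked by average log2 fold change, descending, ties broken by
gene ID. For a set with `N_H` hits in a list of `N` genes, the running sum
gains `|r_i|^p / N_R` at hits (`N_R = Σ_hits |r|^p`, weight `p = 1`) and
loses `1/(N − N_H)` at misses; the enrichment score is the signed maximum
deviation from zero (ties between equal positive and negative extremes
resolve positive; if all hit weights are zero the weights fall back to
equal). With `p = 0` this reduces to the classic Kolmogorov–Smirnov
running statistic.

Significance uses **gene-set permutation**: null sets of identical size
drawn uniformly without replacement from the ranked genes
(`n_perm = 1,000` by default). The original method describes scrambling
phenotype labels, but a pre-ranked input has no per-sample labels to
scramble, so gene-set permutation is the only coherent scheme here; this
divergence is deliberate and documented rather than presented as the
original computation. The permutation p uses an add-one estimator
restricted to same-sign nulls (so p ≥ 1/(n_perm+1)); NES divides ES by the
mean |null ES| of the same sign; FDR q compares the pooled null NES
distribution to the observed NES distribution sign by sign, clipped to
[0, 1] and enforced monotone so a more extreme set never receives a larger
q. Sets sharing no genes with the ranking are dropped with a warning. A
12-set toy pathway collection ships with the package for exercising the
GMT path end to end.

## Spatial co-localization

Spots are transcript aggregates, not cells; no deconvolution is attempted.
Array coordinates are treated as a rectangular grid with 4-connectivity
(hex-lattice offsets are out of scope). Spots are clustered with exactly
the single-cell stack; pericyte spots are designated at **cluster level**
by the same dual-positive enrichment rule, so all spots of qualifying
clusters are included (and pooled when several qualify). Per-gene spot
sets use count > 0.

Co-localization of two marker spot sets A and B with the pericyte spots P
reports all 7 regions of the three-set partition plus overlap percentages.
Published percentages of this kind often leave their denominators
ambiguous, so ours are explicit: `pct_overlap(X) = 100·|X ∩ P|/|P|` and
`pct_both_in_P = 100·|A ∩ B ∩ P|/|P|`.

## Synthetic data

The generator produces the statistical structure the pipeline assumes,
with ground truth for every decision the pipeline makes.

* **Counts** are gamma-Poisson (negative binomial) with cell-type-specific
  means, a dispersion `θ = 2` shared across genes, and lognormal library
  factors (μ = 0, σ = 0.35). Each cell type carries a 40-gene signature
  program (NB mean 3 in-type, 0.02 elsewhere) so types separate in PC
  space the way real cell types do.
* **Cell types** default to pericyte 0.12, smooth muscle 0.15, fibroblast
  0.25, endothelial 0.20, other 0.28 — a mural-cell-rich mix in which the
  pericyte cluster is a minority population, as in tissue atlases.
* **Canonical pair.** A pericyte co-expresses both canonical genes with
  probability `dual_pos_rate = 0.85`; otherwise one or neither, uniformly.
  Smooth muscle expresses the second canonical gene alone at rate 0.7 —
  the confusable mural population — and background cells at 0.02.
* **Planted markers.** Ten tissue-specific markers per tissue, three
  shared markers with designated tissue subsets (the first spans the first
  two tissues, mirroring a lung∩heart marker), and five decoys per tissue.
  Marker expression is Bernoulli-gated: detected with probability
  `pi_in = 0.95` in target-tissue pericytes and `pi_out = 0.01` anywhere
  else; decoys use 0.5. A gated "on" draw is `1 + NB`, so the detection
  fraction equals the gate probability *exactly* — a multiplicative gate
  would shrink it by the NB zero mass (≈ 4 % at these means), breaking the
  calibration the pct filters are tested against. This exact control is
  the design point of the generator.
* **Spatial sections** place 1-wide self-avoiding artery paths (weighted
  to continue straight, so they look vessel-like) expressing a MYH11
  analogue, scattered capillary spots (10 %) expressing a PECAM1 analogue,
  pericyte spots 4-adjacent to capillaries expressing both canonical genes
  plus HIGD1B/NOTCH3 analogues, and low-noise background; each region also
  carries a program block so spot clustering can find it.
* **Determinism.** Per-tissue seeds derive from the master seed plus a
  CRC32 of the tissue label, modulo 2³¹ — reproducible, independent
  streams; identical config and seed give bit-identical matrices.

What the generator does **not** emulate: donor/batch structure (dataset
integration is out of scope), doublets, ambient RNA, and realistic
gene–gene correlation beyond the block programs. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to those artifacts in real atlases.

## Problem sizes and runtime

The validation suite runs the full four-tissue study at 300–800 cells and
1,200 genes per tissue, spatial sections up to 30×30 spots, 1,000–2,000
permutations/replicates for calibration experiments, and exhaustive
oracles (partition enumeration, rank-sum enumeration) at sizes where
enumeration is exact. These sizes give binomial standard errors of ~1 %
on the calibrated fractions while keeping the whole suite and the
acceptance script in the tens of seconds on one CPU; the pipeline itself
scales to desk-scale atlases (exact k-NN is quadratic in cells).

## Known limitations

* The enrichment gate's numeric rule is this package's operationalization
  of what is, in practice, a qualitative judgement (a cluster visibly
  dominated by dual-expressing cells); the self-excluded background and
  the 0.05/5× defaults are documented choices, not measured constants.
* No expression-magnitude threshold beyond count > 0 is applied when
  calling a cell dual-positive; highly expressing and barely detected
  cells are treated alike.
* No covariates are regressed out during scaling.
* The Wilcoxon normal mode should not be trusted for groups smaller than
  ~5; use exact mode there (the DE stage never does).
* FDR q from gene-set permutation is not comparable to phenotype-
  permutation q-values from the original GSEA software.
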