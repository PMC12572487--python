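# Methods

## Problem setting

The package classifies subjects (disorder vs. control) from resting-state
functional MRI summarized as region-wise BOLD signals. Two complementary
representations of each subject's functional connectivity are learned
jointly:

* a **non-Euclidean view** — a three-level hierarchy of brain graphs
  encoded with spectral graph convolutions, and
* a **Euclidean view** — the flattened Pearson FC matrix encoded with a
  1-D CNN,

each augmented with explicit second-order (high-order) feature statistics
before a fused softmax classifier.

## Hierarchical graph construction

A hierarchy table assigns every atlas region to a cluster (a lobe-like
subdivision) and a functional network (Yeo-7-style). Three graphs follow:

* **WAN** (whole-brain): nodes = networks; every network pair is an edge
  candidate (one block).
* **MAN** (meso): nodes = clusters; edges only between clusters of the
  same network (blocks = networks).
* **LAN** (local): nodes = regions; edges only between regions of the same
  cluster (blocks = clusters).

Node signals at a level are the column-wise concatenation of member
regions' voxel matrices, so inter-node similarity is measured by the same
statistic at every level: the RV coefficient

    RV(A, B) = Tr(AA'BB') / sqrt(Tr[(AA')²] · Tr[(BB')²])

computed on column-centered matrices. Centering is not shown in some
presentations of the formula but is part of the classical definition;
uncentered signals with a common nonzero mean saturate the statistic
toward 1. A `center=False` flag restores the raw cross-product form.

Within-block RV matrices are thresholded — an edge keeps its RV value when
it strictly exceeds a sparsity cutoff γ, the diagonal is 1 — and assembled
block-diagonally, so cross-block entries are *structural* zeros, not
thresholded ones. Node features are the node's full row of the
pre-threshold RV-profile matrix: the connectivity profile gives a fixed,
scan-length-independent feature dimension equal to the node count, and
retains information at high sparsity. A config alternative supplies
node-mean time series instead.

γ defaults to a single shared value per cohort, selected at the knee of
the retained-edge curve (fraction of off-diagonal entries surviving each
candidate γ on a 0.00–0.99 grid, step 0.01). The knee is the grid point of
maximum discrete curvature of the min-max-normalized curve (Kneedle-style;
central differences, interior points only, ties broken toward smaller γ).
Constant or linear curves raise an error and require an explicit γ.
Published per-dataset cutoffs for the real ABIDE-I / ABIDE-II / ADHD-200
cohorts (19.03%, 17.14%, 10.23%) are shipped as documentation only; they
cannot be re-derived without the original RV matrices.

## Graph branch (HGNN)

Per level, node features pass through `n_blocks` (default 3) ChebConv
blocks. A block applies a K-order Chebyshev spectral convolution
(K default 3)

    H' = Σ_{k<K} T_k(L̃) H θ_k,  T_0 = I, T_1 = L̃,
    T_k = 2 L̃ T_{k−1} − T_{k−2},

with L̃ = 2L/λ_max − I the rescaled symmetric normalized Laplacian
(λ_max computed per graph rather than bounded by 2 — exact rescaling keeps
the polynomial basis well conditioned on small graphs), followed by batch
normalization (statistics over batch and node axes, per feature), ReLU,
dropout, and a residual connection (identity when dimensions match, a
learned linear projection otherwise). Residuals are the over-smoothing
guard: a residual-free stack of row-stochastic propagations collapses
node-feature variance, which the test suite checks comparatively.

Block outputs are combined by adaptive feature maps (AFM): a learned
logit vector passed through softmax weights the three block outputs, so
the effective receptive scale is data-driven. AFM logits are initialized
from N(0, 0.01²).

Graph high-order pooling (GHOP) forms the Gram matrix ZᵀZ of the
aggregated node embeddings. Its upper triangle (with diagonal,
d_h(d_h+1)/2 values — the lower triangle is redundant) is passed through
signed-square-root + L2 normalization and a one-hidden-layer MLP (width
d_h). The level embedding concatenates a mean-over-nodes readout with this
high-order term (2·d_h values); the three level embeddings concatenate to
the branch output (6·d_h). The signed-sqrt/L2 step is the standard
conditioning for flattened bilinear features: raw Gram entries grow with
node count and push initial logits into softmax saturation, which a
fraction of random initializations never escapes.

## CNN branch (ESFE)

The strict upper triangle of the N×N Pearson FC matrix (row-major;
N(N−1)/2 values — the unit diagonal is uninformative) feeds two valid
(no-padding) 1-D convolution layers implemented as cross-correlation
exactly as indexed (no kernel flip): defaults 8 channels/kernel 7/stride 2
then 16 channels/kernel 5/stride 2, ReLU between, then an MLP to the
first-order feature Z_fc ∈ R^d (d default 64). High-order pooling (HOP)
takes the outer product Z_fc Z_fcᵀ — pairwise multiplicative interactions
between feature dimensions — whose normalized upper triangle feeds a
second MLP; the branch output is concat(Z_fc, MLP(·)) of length 2d. A
`hop_mode="channel_gram"` switch instead forms the Gram matrix over
conv-channel feature maps, for the reading of second-order pooling that
operates on feature maps rather than the final vector.

## Fusion, training, evaluation

The two branch outputs concatenate (6·d_h + 2d) into an MLP head (hidden
128, 32; ReLU; dropout) with softmax over two classes. Training minimizes
binary cross-entropy (computed from logits via log-softmax for numerical
stability; identical in value to the probability form) with Adam. Defaults
follow the reference setting — dropout 0.3, learning rate 1e-4 — while
the synthetic-cohort experiments use 1e-3 and ≤100 epochs, appropriate for
120-subject cohorts.

Evaluation uses repeated stratified random 70/10/20
train/validation/test splits (10 repeats by default); the validation split
selects the checkpoint with lowest validation loss. Metrics: accuracy,
sensitivity, specificity (0.5 threshold, patient = positive class),
rank-based AUC, and their arithmetic mean. Internal comparisons between
ablation variants use a one-sided paired sign-flip permutation test (exact
enumeration up to 20 pairs).

The ablation lattice is expressed purely as config switches: graph branch
with all three levels or LAN only, with/without GHOP; CNN branch
with/without HOP; and their combinations — no separate code paths.

## Node saliency

Region importance combines both branches: the graph side scores each LAN
node by gradient × input magnitude of the patient-class logit with respect
to that node's connectivity-profile features (mean over subjects and
feature dimensions); the CNN side attributes first-conv activation
magnitudes back through each output position's receptive field to FC
vector positions, and each FC entry (i, j) credits both regions. The two
scores are min-max normalized and averaged; the default report is the
top-10 regions.

## Population graph

A second, transductive stage treats subjects as nodes. Embedding
similarity M1 = exp(−ρ²/2σ²) uses the correlation distance ρ between
subject embeddings with σ the mean squared distance over pairs. Phenotype
agreement M2 averages indicator channels (sex match, site match,
|Δage| ≤ 2 years; window configurable) — a Parisot-style kernel, since the
construction is otherwise unspecified. The support is C = 1{M1∘M2 ≥ mean
off-diagonal}, configurable to top-k per node; edge weights W are cosine
similarities (mapped to [0, 1]) of a shared-weight MLP encoding of the
phenotype vectors (one-hot sex/site, z-scored age; zero-norm outputs fall
back to 0.5, the orthogonality convention). A' = C ∘ W with unit
self-loops. Classification is one symmetric-normalized first-order graph
convolution (depth configurable) over A' followed by an MLP, trained on
the labeled subset only. Setting M2 ≡ W ≡ 1 degrades the graph to
embedding similarity alone, reproducing the with/without-phenotypes
contrast as a config switch.

## Synthetic cohort generator

The generator emulates hierarchically correlated voxel signals with
planted group differences in inter-network coupling — the working model of
neurodevelopmental disorders as altered between-network resting-state
coupling. A Gaussian latent cascade, i.i.d. over time points:

* network factors jointly normal with baseline correlation ρ_x; planted
  network pairs get ρ_x + δ in the patient class;
* cluster factor = √ρ_n · f_net + √(1−ρ_n) ξ;
* region factor = √ρ_c · f_cluster + √(1−ρ_c) ξ;
* voxel = √ρ_r · f_region + √(1−ρ_r) · noise.

Implied correlations have closed forms (same region ρ_r; same cluster
ρ_r·ρ_c; same network ρ_r·ρ_c·ρ_n; across networks ρ_r·ρ_c·ρ_n·ρ_x), which
the tests verify empirically at n_time = 2000 within ±0.05. A self-pair
effect ("netX", "netX") raises the within-cluster coupling ρ_c of that
network's clusters only, producing a group difference *confined to one
network* that remains visible at the region level (where graph blocks are
clusters — a cross-cluster effect would fall on structural zeros there).

Defaults are the reference study conditions: 60 subjects per class,
4 networks × 2 clusters × 3 regions × 20 voxels, 150 time points,
ρ_r = 0.8 > ρ_c = 0.6 > ρ_n = 0.4 > ρ_x = 0.1, δ = +0.4 between net1 and
net2. The correlation ladder was chosen once as a realistic ordering
(voxels within an ROI strongly coupled; coupling decaying up the
hierarchy); the strict ordering is validated at construction, as is
positive semi-definiteness of the implied network correlation matrix for
both classes. Phenotypes: sex ~ Bernoulli(0.5), age ~ Uniform(8, 20)
years, three sites. An AR(1) temporal option (stationary unit variance)
adds autocorrelation for realism and defaults off — i.i.d. time points
exercise every operator.

The saliency experiment uses 3 networks × 2 clusters × 4 regions
(8 regions per network out of 24) with a +0.35 within-network effect, so
that a top-10 ranking can meaningfully concentrate in the affected
network; under the 4-network default each network holds only 6 regions
and a 7-of-10 concentration criterion would be unsatisfiable.

What passing these tests does **not** show about real data: the generator
has no temporal autocorrelation by default, no site/batch effects, no
motion artifacts, no hemodynamic convolution, and its group difference is
a single clean coupling shift. Recovery here demonstrates that the
pipeline is implemented correctly and can detect the class of effect it
targets, not that it attains any particular accuracy on clinical cohorts.

## Numerical choices and limitations

* Everything trainable runs on an in-repo reverse-mode autodiff core
  (float64), gradient-checked against central finite differences; Adam
  with standard bias correction.
* Strict inequality at the threshold (edges with RV exactly γ drop);
  probability clamping at 1e-7 in the probability-form cross-entropy.
* λ_max falls back to the spectral bound 2 for edgeless graphs or
  eigensolver failure.
* Determinism: every stochastic step draws from a generator seeded by the
  run config; identical seed + config reproduces losses, parameters and
  serialized outputs bit-for-bit on one platform.
* The experiment protocols train 60 epochs on the 120-subject cohort;
  the reported problem sizes are stated alongside every result.
* Multi-class labels, NIfTI ingestion, atlas registration, dynamic
  connectivity and learned hierarchies are out of scope.

Because each held-out test set holds only 24 subjects, single-split
accuracies fluctuate by roughly ±0.1 between seeds even when training has
converged; reported recovery numbers are means over seeds and should be
read with that granularity (1 subject = 0.042 accuracy).
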