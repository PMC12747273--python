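# Methods

This note documents the models implemented in patchseek, the synthetic
data conditions under which they are validated, and the numerical and
design choices made where the design was genuinely open. Every number
mentioned here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Tissue segmentation and patching

Segmentation follows the standard coarse colour pipeline for H&E
slides: RGB→HSV, median blur of the saturation channel (default kernel
7 px), thresholding, then binary closing (default 5 px) to fill small
gaps. The threshold defaults to Otsu's method on the blurred saturation
channel — a parameter-free choice consistent with saturation-threshold
segmentation — and can be overridden with a fixed value. A blank
(saturation-constant) image has no Otsu split and yields an empty mask
by definition rather than an arbitrary threshold.

Patches are non-overlapping `size_px` squares (default 256) on a grid
anchored at the image origin; partial edge tiles are discarded, and a
tile is kept iff its tissue-mask coverage is ≥ `min_tissue_frac`
(default 0.5 — the tile-keeping rule is not standardised anywhere, and
0.5 is the symmetric choice that avoids background-dominated patches).
Coordinates are 0-based, boxes half-open, y downward, one convention
across all modules. Magnification normalisation only downsamples
(area averaging, integer factors among 80X/40X/20X/10X); upsampling is
an error because resolution cannot be invented.

ST spot patches use edge 2^⌈log₂(64/mpp)⌉ pixels — the power of two
that covers at least 64 µm of tissue at the scan's microns-per-pixel —
centred on each spot and clamped (not dropped) at image borders so the
spot↔patch bijection needed by the association statistics survives.

## Encoding and the unit-norm contract

The engine is backbone-agnostic: any callable mapping a patch stack to
an N×d matrix works. The in-repo `ToyHistogramEncoder` (8-bin RGB
histograms + 4 gradient summaries, seeded random projection) exists so
every downstream stage runs and is testable without pretrained weights;
it is a deterministic stand-in for a learned encoder, not an attempt at
one. A single linear layer projects backbone features to the shared
256-d space (identity-padded weights are available for encoder-only
use).

All vectors are unit-normalised in exactly one place
(`unit_normalize`), after projection and before indexing, attention
scoring, or clustering. On unit vectors ‖u−v‖² = 2 − 2·u·v, so
Euclidean and cosine rankings coincide for every K — the property the
index backends, the spot clustering, and the significance scores all
rely on. Zero rows are an error naming the row rather than silently
dropped.

## Gated-attention MIL

Forward model per slide bag H ∈ ℝ^{N×d} (d = 256 by default):

- attention logit per patch: e_n = W·(tanh(V h_n + b_v) ⊙ σ(U h_n + b_u)) + b_w
- weights s = softmax(e) with max-subtraction stabilisation
- bag vector h_bag = Σ s_n h_n (a convex combination of rows)
- heads: per 3-class mutation task, logits = C_tᵀ h_bag + c_t; per
  expression task a scalar linear head.

Bias terms are included in all layers (zero biases reproduce the plain
weight-matrix algebra). Head counts are constructor parameters rather
than constants — the canonical configuration is 11 mutation tasks and
55 expression tasks, but nothing in the architecture depends on it.

Training is plain-numpy analytic backpropagation with Adam
(lr 1e-4, β₁ 0.9, β₂ 0.999, L2 weight decay 1e-5, default 100 epochs).
One optimizer step consumes `batch_slides × grad_accum_subbatches`
slides (defaults 2 × 8), with gradients averaged across the accumulated
sub-batches before each update. Classification uses weighted
cross-entropy with w_c = 1/p_c computed on the training labels (an
absent class is an error directing the caller to re-split); regression
uses MSE; missing labels (−1 for classes, NaN for targets) mask that
slide out of that task. The best epoch maximises Σ AUC + Σ ρ on the
validation split, ties to the earliest epoch. Heads are initialised at
zero so predictions start neutral and move in the gradient's direction
from the first step; projection and attention layers use Xavier
initialisation. Splits are patient-level with re-draw until every
partition holds a positive (class-1) slide for every task, bounded at
1000 attempts.

AUC for the 3-class heads is computed one-vs-rest on the probability of
class 1 (the functional-mutation class). This is a documented default
for mapping 3-class heads onto binary reporting, not the only possible
construction.

## Vector indexing

All k-means in the package (PQ codebooks, IVF coarse quantiser, mosaic,
spot clustering) share one implementation: seeded k-means++
initialisation, at most 25 Lloyd iterations, assignment ties to the
lowest centroid id, optional restarts keeping the lowest-inertia
solution.

**IVF-PQ.** Coarse k-means partitions items into `nlist` cells;
residuals to the cell centroid are product-quantised (`m` subspaces,
`ksub` centroids each; `ksub` ≤ 256 keeps one byte per subcode, so an
item costs m bytes). Residual encoding is the default (direct encoding
is behind a flag) because it is the standard accuracy-improving
convention where the choice is otherwise open. Queries scan the coarse
centroids exactly — at desk scale (nlist ≤ 256) an HNSW shortcut for
centroid location saves nothing, and graph construction is out of
scope — then rank candidates in the `nprobe` nearest cells by
asymmetric distance (per-subspace lookup tables against the query
residual). `nprobe` > `nlist` clamps with a warning; empty probed lists
can return fewer than K hits, flagged on the result.

**ITQ-LSH.** PCA to `n_bits` dimensions (features zero-padded when the
input dimension is below the code length), then 50 iterations (default;
the count is otherwise unstated in the literature contract we follow)
alternating sign assignment B = sign(VR) with the orthogonal Procrustes
update of R. The quantization error ‖B − VR‖² is non-increasing by
construction and is exposed for inspection. Codes are compared by
Hamming distance.

**Mosaic.** K-means over the concatenation of z-scored features and
z-scored patch-centre coordinates (standardised separately, since the
published mosaic variants differ on scaling); within each cluster the
items nearest the centroid are kept, ⌈fraction·size⌉ and at least one
per non-empty cluster. The fraction is a parameter covering both the
5% and 20% regimes in use.

**Persistence.** One binary file: 8-byte magic, little-endian header
length, JSON header (backend, params, format version, array manifest),
then raw arrays. Truncation and version mismatch raise errors;
round-trips reproduce search results bit-identically.

## Retrieval significance

The background is drawn once per cohort (default 10,000 patches,
without replacement, or all items when fewer) with a stored seed, so
z/p are reproducible across queries. z = (d_hit − mean d_bg)/sd d_bg;
p = #{d_bg ≤ d_hit}/|bg| — the plain empirical fraction, deliberately
without the common (r+1)/(n+1) smoothing, so p = 0 is attainable for a
hit closer than every background patch. Slide ranking sums rank scores
K+1−rank per slide (monotone in both hit count and hit quality,
integer-valued); ties break toward the smaller best-hit distance.
Multi-patch queries without trained attention fall back to uniform
weights, keeping the engine usable encoder-only.

The null calibration of p is checked on exchangeable pairs: the
distance from a background member to a random other member, scored
against the background distribution, is uniform on (0,1) up to 1/|bg|
granularity (KS < 0.1 at n = 500). Top-1 hit distances are *not* null
quantities — they concentrate near zero by construction — which is why
the calibration uses random pairs.

## Evaluation protocols

AP@5 = Σᵢ Precisionᵢ·Relᵢ / 5 over a length-5 list; mAP@5 averages per
class; summaries use the median across classes and datasets. Relevance
is exact label equality (no ontology partial credit). In leave-one-out
patch retrieval the self-match is removed *before* the top-5 cut —
otherwise every AP inflates by a guaranteed rank-1 hit. In
leave-one-slide-out matching, each slide's query patch is its most
representative one (global minimum distance to its mosaic-cluster
centroid), the database is every other slide (optionally
mosaic-subsampled), and slides are ranked by their closest patch.

One chance-level fact worth recording: the expected AP@5 under label
permutation is far below the class prior, because the precision terms
compound. At prior 0.25 the Monte-Carlo expectation is ≈ 0.145, and
the pipeline reproduces it (0.143 over 40 permutations); tests assert
against that oracle, not against the prior.

## ST association

Spot clustering is k-means with k = 8 on unit-norm spot-patch
embeddings, strictly per profile — clustering across profiles would mix
slide-level batch effects into morphology clusters. Five restarts guard
against local minima. For each gene × cluster: two-sided Wilcoxon
rank-sum (scipy `mannwhitneyu`: exact for tie-free groups under 20,
tie-corrected normal approximation otherwise) and Cohen's d in the
classical pooled-SD form — the d variant is not standardised for this
use, and pooled SD is the symmetric default. Statistics run on log1p
counts (no depth normalisation; variance-stabilising transforms are a
visualisation concern, not part of the statistics path). BH-FDR is
applied per profile across all of its gene × cluster tests, matching
the query logic that compares clusters within a parent slide;
zero-variance records carry d = NaN and are excluded. Gene queries
return clusters with d > d_min (default 1) and q < q_max (default
0.05), sorted by d.

Matched-spot expression keeps genes detected (count > 0) in ≥ 75% of
matched spots, ranked by mean log1p expression. GSEA is the classic
unweighted running sum (gain 1/|set∩ranked| at members, loss
1/(N−|set|) elsewhere; ES = running-max), with a one-sided permutation
p over random same-size gene sets (default 1000 permutations).

## Synthetic data: what it emulates and what it does not

The generators define the validation conditions:

- **Slides** (`gen_slide`): saturated uniform-colour regions on
  near-white glass with Gaussian pixel noise (sd 3 by default). This
  exercises the full segmentation→patching→encoding path with an exact
  pixel-level ground truth; it does not emulate H&E texture, stain
  variation, or scanner artifacts, so passing tests certify the
  pipeline mechanics, not robustness to staining.
- **MIL cohorts** (`gen_mil_cohort`): patches are isotropic standard
  Gaussians; each 3-class task owns two orthonormal directions, and a
  class-c slide shifts `signal_fraction` of its patches by
  `effect_size` (in noise SDs) along the class direction; regression
  targets are the slides' planted coefficients plus 10% observation
  noise. Defaults (effect 5, fraction 0.5) are the strong-signal regime
  in which recovery must be near-perfect; the ablation condition
  concentrates the signal in a single patch of 32, where mean pooling
  dilutes it 32-fold and attention's advantage is structural rather
  than statistical luck.
- **ST profiles** (`gen_st_profile`): spots on a grid; cluster centres
  are orthonormal directions scaled by `cluster_separation` (default 6
  vs unit noise — separable after normalisation), so "well-separated"
  is literal; expression is log-scale Gaussian
  (mean 2, sd 0.5) with DE genes shifted by d·sd in their cluster, and
  counts are rounded log-normal intensities so the planted d survives
  the engine's log1p to within rounding. Library-size variation,
  zero-inflation, and spatial autocorrelation of expression are not
  modelled.
- **Embedding databases** (`gen_embedding_clusters`): many small groups
  of near-identical unit vectors (default ~10 members, noise sd 0.05) —
  the near-duplicate structure real patch databases have, and the
  regime in which 8-byte PQ codes can preserve top-10 neighbourhoods
  (recall@10 ≈ 0.99 at nlist 32, m 8, ksub 16, nprobe 8 on 10,000
  vectors). With few large clusters the same settings cannot exceed
  recall ≈ 0.3 for any encoder, because within-cluster orderings sit
  below quantization resolution; the group structure is therefore part
  of the stated conditions, not a tuning knob.

One global seed expands into named counter-based substreams
(`SeedSequence` spawn keys from hashed component names), so adding a
generator or calling one more often never perturbs another's draws.

## Problem sizes used in validation

Tests and the acceptance script scale the study down to sizes the
methods' asymptotics already hold at, chosen as the package's own
validation conditions: 10,000-vector databases for recall, 200-slide
cohorts (32 patches, d_raw 32, d_proj 32) for MIL recovery, 400-spot
profiles for ST recovery with 100 seeds, 500 replicates for the null
calibrations, and 30–40 training epochs (the planted signal is strong
enough that the 100-epoch default adds nothing). The projection width
follows the raw feature width in tests; nothing in the mathematics
depends on d = 256.

## Known limitations

- No WSI pyramid reader: inputs are in-memory rasters or PNG/TIFF.
  `seg_downsample` exists for large images, but gigapixel streaming is
  out of scope.
- The toy encoder separates colour/texture classes, not histologic
  entities; any scientific use requires injecting a real backbone
  through the encoder contract.
- IVF-PQ centroid location is an exact scan; at millions of items a
  graph-based coarse search would be needed.
- The empirical p-value is granular at 1/|background| and exactly 0 is
  possible; consumers needing strictly positive p should smooth.
- GSEA permutes gene sets, not phenotypes; it tests set concentration
  in a fixed ranking only.
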