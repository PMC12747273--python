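# patchseek

Desk-scale content-based image retrieval for H&E histology, with the
molecular-prediction encoder and spatial-transcriptomics association
statistics that make the retrieved patches interpretable.

Pathologists and computational biologists often want to ask, of a tissue
region: *where else does this morphology occur, and what does it mean
molecularly?* Answering that at scale requires (1) cutting whole-slide
images into fixed-size patches over tissue only, (2) encoding each patch
as a vector whose geometry reflects morphology, (3) indexing millions of
vectors compactly enough to search on a desk, (4) attaching a
significance estimate to each hit, and (5) linking image-feature
clusters to gene expression where spatial transcriptomics is available.
patchseek implements that whole pipeline as a Python library plus a thin
`patchseek` CLI, with a synthetic-data module that generates every input
class with planted ground truth so the engine is testable end to end
without any downloads.

## The models at the core

**Gated-attention multiple-instance learning.** A slide is a bag
H ∈ ℝ^{N×256} of patch vectors (a projection layer maps any backbone's
features to 256-d). Each patch gets an attention weight

    s_n = softmax_n( W·( tanh(V h_nᵀ) ⊙ sigmoid(U h_nᵀ) ) ),
    W ∈ ℝ^{1×256},  V, U ∈ ℝ^{256×256}

and the slide representation is h_bag = Σ_n s_n h_n. Task heads predict
per-patient molecular labels: 3-class mutation-effect heads (weighted
cross-entropy, class weights w_c = 1/p_c) and scalar gene-set expression
heads (MSE); the training loss is the plain sum over all tasks,
optimised with Adam (lr 1e-4, β₁ 0.9, β₂ 0.999, weight decay 1e-5) and
gradient accumulation over sub-batches of whole slides. Splits are
patient-level 80/10/10, re-drawn until every partition has positive
labels for every classification task; the kept epoch maximises the
overall score Σ AUC + Σ Spearman ρ on the evaluation split.

**Unit-norm retrieval geometry.** All embeddings are scaled to unit
length, so ‖u−v‖² = 2 − 2·u·v and Euclidean top-K equals cosine top-K.
Three index backends share one search contract: exact brute force (the
oracle), IVF-PQ (coarse k-means Voronoi cells, product-quantised
residuals, asymmetric-distance search over the `nprobe` nearest cells),
and ITQ-LSH (PCA + learned orthogonal rotation to 32/64-bit codes,
Hamming search). A "mosaic" subsampler keeps the top fraction of
cluster-representative patches per slide to shrink the search space.

**Hit significance.** Per cohort, a fixed random sample of 10,000
patches estimates the background distance distribution; a hit at
distance d scores z = (d − mean d_bg)/sd d_bg and empirical
p = #{d_bg ≤ d}/|bg|. Whole slides are ranked by the sum of rank scores
K+1−rank over their hits.

**Transcriptomics ↔ morphology.** Patches centred on ST spots (edge
2^⌈log₂(64/mpp)⌉ px) are encoded and k-means-clustered into 8 clusters
per profile; each gene × cluster pair gets a two-sided Wilcoxon rank-sum
p and a pooled-SD Cohen's d (in-cluster vs out-of-cluster spots), with
BH-FDR across the profile's tests. A gene query returns clusters with
d > 1 and q < 0.05. In the reverse direction, spots matched by an image
query yield genes detected in ≥75% of matched spots ranked by mean
expression, scored by classic running-sum GSEA with a one-sided
permutation p-value.

## Worked example

Generate a synthetic slide with two tissue disks, segment, patch,
encode, index, and query one of the indexed patches:

```python
from patchseek.synthetic import SyntheticSlideSpec, gen_slide
from patchseek.patching import segment_tissue, extract_patches
from patchseek.encoding import ToyHistogramEncoder, unit_normalize
from patchseek.index import build_exact
from patchseek.retrieval import BackgroundSample, query

spec = SyntheticSlideSpec(
    width_px=512, height_px=512,
    tissue_regions=(("disk", (160, 160), 120, 0), ("disk", (380, 380), 90, 1)),
    noise_sd=2.0, seed=1,
)
image, tissue, labels = gen_slide(spec)
mask = segment_tissue(image)
refs, patches = extract_patches(image, mask, size_px=64, min_tissue_frac=0.5)
print(f"kept {len(refs)} of {(512 // 64) ** 2} grid tiles")

emb = unit_normalize(ToyHistogramEncoder(d_raw=16, seed=0)(patches), refs)
index = build_exact(emb)
background = BackgroundSample.draw(emb.n, size=emb.n, seed=0)
hits, ranking = query(emb.values[3], index, k=5, background=background, embeddings=emb)
for h in hits:
    print(f"rank {h.rank}: ({h.patch.x},{h.patch.y}) "
          f"d={h.distance:.4f} z={h.z_score:+.2f} p={h.p_value:.3f}")
```

prints

```
kept 13 of 64 grid tiles
rank 1: (64,128) d=0.0000 z=-0.72 p=0.077
rank 2: (192,128) d=0.0001 z=-0.72 p=0.154
rank 3: (128,64) d=0.0011 z=-0.72 p=0.231
rank 4: (128,128) d=0.0017 z=-0.72 p=0.308
rank 5: (128,192) d=0.0035 z=-0.72 p=0.385
```

Only the 13 tiles with ≥50% tissue coverage survive patching. The query
is itself an indexed patch, so rank 1 returns it at distance 0; the
other hits are patches from the same disk, morphologically
near-identical under the toy encoder. All five z-scores round to −0.72
because the background here is the 13-patch cohort itself, split between
within-disk distances (≈0) and cross-disk distances (≈√2): every hit
sits the same ~0.7 SD below the background mean. The empirical p is
granular at 1/13 for the same reason — on a realistic cohort the
background has 10,000 members and p resolves to 1e-4.

The same flow is available from the shell:

```bash
patchseek synth slide --seed 1 --out slide/
patchseek patch --image slide/slide.png --out patches/ --size 64
patchseek encode --patches patches/ --out emb.h5
patchseek index build --emb emb.h5 --backend ivfpq --out idx.bin
patchseek query --index idx.bin --image slide/slide.png --emb emb.h5 --k 5 --patch-size 64
```

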