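"""End-to-end query pipeline with empirical hit significance.

A query region is tiled into patches, encoded, aggregated into one unit
vector, and searched against an index.  Each hit's distance is scored
against a background distribution — the distances from the query to a
fixed random sample of database patches (10,000 by default, drawn once
per cohort) — giving a z-score (more negative = stronger match) and an
empirical p-value, the fraction of background distances at or below the
hit distance.  Whole slides are ranked by summing the rank scores
``K + 1 − rank`` of their hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import block_reduce

from ._rng import substream
from .encoding import EmbeddingMatrix, unit_normalize
from .mil import GatedAttentionParams, aggregate, attention_scores
from .patching import PatchRef

__all__ = [
    "RetrievalHit",
    "BackgroundSample",
    "SlideRanking",
    "encode_query",
    "significance",
    "rank_slides",
    "query",
    "halve_resolution",
]

DEFAULT_BACKGROUND_SIZE = 10_000


@dataclass
class RetrievalHit:
    patch: PatchRef | int
    distance: float
    rank: int
    z_score: float = np.nan
    p_value: float = np.nan


@dataclass
class BackgroundSample:
    """Fixed random patch sample estimating the null distance distribution."""

    cohort_id: str
    item_ids: np.ndarray
    seed: int

    @classmethod
    def draw(
        cls,
        n_items: int,
        cohort_id: str = "cohort",
        size: int = DEFAULT_BACKGROUND_SIZE,
        seed: int = 0,
    ) -> "BackgroundSample":
        """Sample ``size`` item ids without replacement (all if fewer)."""
        rng = substream(seed, f"background_{cohort_id}")
        size = min(size, n_items)
        ids = np.sort(rng.choice(n_items, size=size, replace=False))
        return cls(cohort_id, ids, seed)


@dataclass
class SlideRanking:
    slide_ids: list[str]
    scores: np.ndarray
    hits_per_slide: dict[str, list[RetrievalHit]] = field(default_factory=dict)


def encode_query(
    region: np.ndarray,
    encoder,
    patch_size: int = 256,
    attention: GatedAttentionParams | None = None,
    projection=None,
) -> np.ndarray:
    """Encode an image region into a single unit-norm query vector.

    The region is tiled into ``patch_size`` squares (a region smaller
    than one patch is center-padded with white to patch size); patch
    vectors come from ``encoder`` (+ optional ``projection`` callable)
    and are aggregated by gated attention when trained parameters are
    supplied, otherwise by a uniform-weight mean.
    """
    region = np.asarray(region)
    h, w = region.shape[:2]
    if h < patch_size or w < patch_size:
        pad_h, pad_w = max(patch_size - h, 0), max(patch_size - w, 0)
        widths = [
            (pad_h // 2, pad_h - pad_h // 2),
            (pad_w // 2, pad_w - pad_w // 2),
        ] + [(0, 0)] * (region.ndim - 2)
        region = np.pad(region, widths, constant_values=255)
        h, w = region.shape[:2]
    patches = [
        region[y : y + patch_size, x : x + patch_size]
        for y in range(0, h - patch_size + 1, patch_size)
        for x in range(0, w - patch_size + 1, patch_size)
    ]
    if not patches:
        raise ValueError("region yielded no patches")
    raw = encoder(np.stack(patches))
    if projection is not None:
        raw = projection(raw)
    H = unit_normalize(raw).values
    if H.shape[0] == 1:
        vec = H[0]
    else:
        s = (
            attention_scores(H, attention)
            if attention is not None
            else np.full(H.shape[0], 1.0 / H.shape[0])
        )
        vec = aggregate(H, s)
    return unit_normalize(vec[None, :]).values[0]


def significance(
    hit_distance: float,
    background: BackgroundSample,
    query_vec: np.ndarray,
    embeddings: EmbeddingMatrix | np.ndarray,
) -> tuple[float, float]:
    """Empirical (z, p) of a hit distance against the background sample.

    z = (d_hit − mean(d_bg)) / sd(d_bg); p = #{d_bg ≤ d_hit} / |bg|.
    The p-value is the plain empirical fraction (no +1 smoothing), so an
    exact p of 0 is attainable.
    """
    values = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
    if background.item_ids.size == 0:
        raise ValueError("empty background sample")
    d_bg = np.linalg.norm(values[background.item_ids] - np.asarray(query_vec), axis=1)
    sd = d_bg.std()
    if sd == 0:
        raise ValueError("background distances have zero variance")
    z = (hit_distance - d_bg.mean()) / sd
    p = float(np.count_nonzero(d_bg <= hit_distance)) / d_bg.size
    return float(z), p


def rank_slides(hits: list[RetrievalHit], k: int | None = None) -> SlideRanking:
    """Order slides by the sum of their hits' rank scores (K+1−rank).

    Ties between slides break toward the smaller best-hit distance.
    """
    if not hits:
        return SlideRanking([], np.empty(0))
    k = k if k is not None else max(h.rank for h in hits)
    per_slide: dict[str, list[RetrievalHit]] = {}
    for h in hits:
        slide = h.patch.slide_id if isinstance(h.patch, PatchRef) else str(h.patch)
        per_slide.setdefault(slide, []).append(h)
    rows = [
        (slide, sum(k + 1 - h.rank for h in hs), min(h.distance for h in hs))
        for slide, hs in per_slide.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[2], r[0]))
    return SlideRanking(
        [r[0] for r in rows],
        np.array([r[1] for r in rows], dtype=np.float64),
        per_slide,
    )


def query(
    query_vec: np.ndarray,
    index,
    k: int = 50,
    background: BackgroundSample | None = None,
    embeddings: EmbeddingMatrix | np.ndarray | None = None,
    unified_per_slide: bool = False,
) -> tuple[list[RetrievalHit], SlideRanking]:
    """Search → significance per hit → slide ranking.

    ``unified_per_slide`` keeps only the best (smallest-distance) patch
    per slide in the returned hit list, mirroring how multi-hit output is
    unified for side-by-side comparison of retrieval engines.
    """
    result = index.search(query_vec, k=k)
    meta = getattr(index, "item_meta_", [])
    hits = []
    for rank, (item, dist) in enumerate(zip(result.item_ids, result.distances), start=1):
        patch = meta[item] if meta else int(item)
        z, p = (np.nan, np.nan)
        if background is not None and embeddings is not None:
            z, p = significance(float(dist), background, query_vec, embeddings)
        hits.append(RetrievalHit(patch, float(dist), rank, z, p))
    ranking = rank_slides(hits, k=k)
    if unified_per_slide:
        hits = [min(hs, key=lambda h: h.distance) for hs in ranking.hits_per_slide.values()]
        hits.sort(key=lambda h: h.rank)
    return hits, ranking


def halve_resolution(image: np.ndarray) -> np.ndarray:
    """Area-average 2× downsample — the fallback for over-zoomed queries."""
    image = np.asarray(image)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2×2")
    block = (2, 2) + (1,) * (image.ndim - 2)
    out = block_reduce(image.astype(np.float64), block, np.mean)
    if np.issubdtype(image.dtype, np.integer):
        out = np.round(out).astype(image.dtype)
    return out
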