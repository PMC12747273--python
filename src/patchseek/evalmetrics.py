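"""Retrieval-quality metrics and evaluation protocols.

Two protocols are provided: leave-one-out patch retrieval scored by
mAP@5 (each patch queries an index of all patches, the self-match is
removed before the top-5 cut), and leave-one-slide-out label matching
(each slide's most representative patch queries the remaining cohort;
the top-5 slides are scored against the query slide's label).  Class
and dataset summaries use the median, and relevance is exact label
equality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._kmeans import kmeans
from ._rng import substream
from .encoding import EmbeddingMatrix
from .index import build_exact, build_itq_lsh, build_ivfpq, mosaic_select

__all__ = [
    "ap_at_5",
    "map_at_5",
    "leave_one_out_patch_eval",
    "leave_one_slide_out_eval",
]

_BUILDERS = {"exact": build_exact, "ivfpq": build_ivfpq, "itq_lsh": build_itq_lsh}


def ap_at_5(query_label, retrieved_labels) -> float:
    """Average precision over a length-5 retrieval list.

    AP@5 = Σ_i Precision_i · Rel_i / 5 with Rel_i the correctness flag of
    the i-th hit and Precision_i the fraction of correct hits in the top i.
    """
    retrieved = list(retrieved_labels)
    if len(retrieved) != 5:
        raise ValueError(f"AP@5 needs exactly 5 retrieved labels, got {len(retrieved)}")
    rel = np.array([r == query_label for r in retrieved], dtype=np.float64)
    precision = np.cumsum(rel) / np.arange(1, 6)
    return float(np.sum(precision * rel) / 5.0)


def map_at_5(
    query_labels,
    retrieved_labels,
    datasets=None,
) -> dict:
    """Per-class mean AP@5 and the median summary across classes/datasets.

    Returns ``{"table": DataFrame(class, dataset, map5), "median": float}``.
    Classes with no queries are simply absent; an empty input errors.
    """
    query_labels = list(query_labels)
    if not query_labels:
        raise ValueError("no queries")
    datasets = list(datasets) if datasets is not None else ["default"] * len(query_labels)
    aps = [ap_at_5(q, r) for q, r in zip(query_labels, retrieved_labels)]
    df = pd.DataFrame({"class": query_labels, "dataset": datasets, "ap5": aps})
    table = (
        df.groupby(["class", "dataset"], sort=True)["ap5"]
        .mean()
        .reset_index()
        .rename(columns={"ap5": "map5"})
    )
    return {"table": table, "median": float(table["map5"].median())}


def leave_one_out_patch_eval(
    embeddings,
    labels,
    index_backend: str = "exact",
    datasets=None,
    **index_kwargs,
) -> dict:
    """mAP@5 of every patch querying an index over all patches.

    The self-match is removed from the retrieved list *before* the top-5
    truncation (otherwise AP inflates), so the index must hold at least
    six items.
    """
    values = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
    labels = list(labels)
    n = values.shape[0]
    if n < 6:
        raise ValueError("need at least 6 items for leave-one-out AP@5")
    index = _BUILDERS[index_backend](values, **index_kwargs)
    retrieved = []
    for i in range(n):
        k = 7
        ids = index.search(values[i], k=k).item_ids
        ids = [j for j in ids if j != i]
        while len(ids) < 5 and k < n:
            k = min(2 * k, n)
            ids = [j for j in index.search(values[i], k=k).item_ids if j != i]
        retrieved.append([labels[j] for j in ids[:5]])
    return map_at_5(labels, retrieved, datasets)


def _representative_patch(values: np.ndarray, coords: np.ndarray, n_clusters: int, seed: int) -> int:
    """Most representative patch: globally closest to its mosaic centroid."""
    k = min(n_clusters, values.shape[0])
    X = np.concatenate(
        [
            (values - values.mean(0)) / np.where(values.std(0) == 0, 1, values.std(0)),
            (coords - coords.mean(0)) / np.where(coords.std(0) == 0, 1, coords.std(0)),
        ],
        axis=1,
    )
    centroids, labels = kmeans(X, k, substream(seed, "representative_patch"))
    d = np.sum((X - centroids[labels]) ** 2, axis=1)
    return int(np.argmin(d))


def leave_one_slide_out_eval(
    slide_embeddings: list[np.ndarray],
    slide_labels,
    coords: list[np.ndarray] | None = None,
    mosaic_fraction: float = 1.0,
    n_clusters: int = 9,
    seed: int = 0,
) -> dict:
    """Leave-one-slide-out label matching over a slide cohort.

    For each query slide, its most representative patch (mosaic-centroid
    ranking, top 1) queries the patches of all remaining slides —
    subsampled to ``mosaic_fraction`` per slide via :func:`mosaic_select`
    — and the five slides holding the closest patches are scored by
    AP@5 against the query slide's label.  Labels with a single slide
    are excluded with a warning.  Returns per-label mAP and the median.
    """
    slide_labels = list(slide_labels)
    n_slides = len(slide_embeddings)
    if coords is None:
        coords = [
            np.arange(len(e), dtype=np.float64)[:, None] for e in slide_embeddings
        ]
    counts = pd.Series(slide_labels).value_counts()
    singletons = set(counts[counts < 2].index)
    if singletons:
        warnings.warn(f"label(s) {sorted(map(str, singletons))} have one slide; excluded")

    kept: list[np.ndarray] = []
    for s in range(n_slides):
        values = np.asarray(slide_embeddings[s], dtype=np.float64)
        if mosaic_fraction < 1.0 and values.shape[0] > 1:
            ids = mosaic_select(
                values, coords[s], fraction=mosaic_fraction,
                n_clusters=min(n_clusters, values.shape[0]), seed=seed,
            )
            kept.append(ids)
        else:
            kept.append(np.arange(values.shape[0]))

    query_labels, retrieved = [], []
    for s in range(n_slides):
        if slide_labels[s] in singletons:
            continue
        values = np.asarray(slide_embeddings[s], dtype=np.float64)
        q = values[_representative_patch(values, np.atleast_2d(coords[s]), n_clusters, seed)]
        best: list[tuple[float, int]] = []
        for t in range(n_slides):
            if t == s:
                continue
            other = np.asarray(slide_embeddings[t], dtype=np.float64)[kept[t]]
            d = np.min(np.sum((other - q) ** 2, axis=1))
            best.append((float(d), t))
        best.sort()
        query_labels.append(slide_labels[s])
        retrieved.append([slide_labels[t] for _, t in best[:5]])
    return map_at_5(query_labels, retrieved)
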