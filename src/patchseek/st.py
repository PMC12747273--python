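"""Spatial-transcriptomics ↔ image-feature association statistics.

Patches centred on ST detection spots are encoded and k-means-clustered
(k = 8 by default, per profile — never pooled across profiles, to avoid
cross-slide batch effects).  For every gene × cluster pair the in-cluster
spots are compared with the out-of-cluster spots of the same profile by
a two-sided Wilcoxon rank-sum test and Cohen's d (pooled-SD form), with
Benjamini–Hochberg correction across all gene×cluster tests of the
profile.  A gene query returns the (profile, cluster) pairs where the
gene is high — d > 1 and FDR q < 0.05 by default.  Expression statistics
run on log1p counts.

The module also covers the image→expression direction: given retrieval
hits over ST-paired patches, genes detected in at least 75% of the
matched spots are returned ranked by mean expression, and a classic
(unweighted) running-sum GSEA with a one-sided permutation p-value
scores gene sets against any per-gene ranking profile (mean expression
or Cohen's d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from ._kmeans import kmeans
from ._rng import substream
from .st_profile import STProfile, load_st_profile, save_st_profile  # noqa: F401

__all__ = [
    "STProfile",
    "cluster_spots",
    "gene_cluster_stats",
    "bh_fdr",
    "query_gene",
    "matched_spot_expression",
    "gsea",
]


def cluster_spots(spot_embeddings, k: int = 8, seed: int = 0, n_init: int = 5) -> np.ndarray:
    """K-means labels over unit-norm spot-patch embeddings.

    On unit vectors Euclidean k-means is cosine k-means (the 2−2cos
    identity), so clusters group spots by morphological similarity.
    ``n_init`` restarts guard against local minima; the lowest-inertia
    solution wins.  Empty clusters are permitted on degenerate input,
    with a warning.
    """
    values = getattr(spot_embeddings, "values", spot_embeddings)
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] < k:
        raise ValueError(f"need at least k={k} spots, got {values.shape[0]}")
    _, labels = kmeans(values, k, substream(seed, "cluster_spots"), n_init=n_init)
    occupied = np.unique(labels)
    if occupied.size < k:
        warnings.warn(f"{k - occupied.size} of {k} clusters are empty")
    return labels


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free groups,
    tie-corrected normal approximation otherwise."""
    if min(len(x), len(y)) < 20 and np.unique(np.concatenate([x, y])).size == len(x) + len(y):
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Classical two-sample Cohen's d with pooled standard deviation."""
    nx, ny = len(x), len(y)
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled == 0:
        return np.nan
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1).

    NaN inputs propagate as NaN and do not count toward the number of
    tests.
    """
    p = np.asarray(p_values, dtype=np.float64)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def gene_cluster_stats(
    counts,
    cluster_labels,
    gene_names: list[str] | None = None,
    profile_id: str = "profile",
    min_group: int = 2,
) -> pd.DataFrame:
    """Per (gene, cluster) in-vs-out rank-sum p and Cohen's d, BH-corrected.

    ``counts`` is genes×spots (sparse or dense, raw counts; log1p is
    applied internally).  BH runs across all gene×cluster tests of the
    profile.  Clusters with fewer than ``min_group`` spots on either side
    are skipped; zero-pooled-SD records carry d = NaN and are excluded
    from gene queries by their q = NaN.
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=np.float64)
    expr = np.log1p(X)
    labels = np.asarray(cluster_labels)
    if expr.shape[1] != labels.size:
        raise ValueError("counts columns must align with cluster labels")
    genes = gene_names or [f"gene{g}" for g in range(expr.shape[0])]
    rows = []
    for c in np.unique(labels):
        inside = labels == c
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in < min_group or n_out < min_group:
            continue
        for g in range(expr.shape[0]):
            x, y = expr[g, inside], expr[g, ~inside]
            d = _cohens_d(x, y)
            p = np.nan if np.isnan(d) else _rank_sum_p(x, y)
            rows.append((profile_id, int(c), genes[g], d, p))
    table = pd.DataFrame(
        rows, columns=["profile_id", "cluster_id", "gene", "cohens_d", "p_value"]
    )
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    return table


def query_gene(
    gene: str,
    association_tables: pd.DataFrame | list[pd.DataFrame],
    d_min: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """All (profile, cluster) pairs where ``gene`` is high.

    Scans the association tables for records with Cohen's d > ``d_min``
    and q < ``q_max``, sorted by d descending.  An unknown gene returns
    an empty result with a warning rather than an error.
    """
    if isinstance(association_tables, list):
        association_tables = pd.concat(association_tables, ignore_index=True)
    records = association_tables[association_tables["gene"] == gene]
    if records.empty:
        warnings.warn(f"gene {gene!r} absent from all association tables")
        return records
    hits = records[(records["cohens_d"] > d_min) & (records["q_value"] < q_max)]
    return hits.sort_values("cohens_d", ascending=False).reset_index(drop=True)


def matched_spot_expression(
    hit_spot_indices,
    profile: STProfile,
    detect_frac: float = 0.75,
) -> pd.DataFrame:
    """Expression over the spots matched by an image query.

    Keeps genes detected (count > 0) in at least ``detect_frac`` of the
    matched spots and ranks them by mean log1p expression descending.
    """
    spots = np.asarray(list(hit_spot_indices), dtype=np.int64)
    if spots.size == 0:
        raise ValueError("no ST-paired hits")
    X = profile.counts[:, spots]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    detected = (X > 0).mean(axis=1)
    keep = detected >= detect_frac
    table = pd.DataFrame(
        {
            "gene": np.asarray(profile.gene_names)[keep],
            "detect_frac": detected[keep],
            "mean_expression": np.log1p(X[keep]).mean(axis=1),
        }
    )
    return table.sort_values(
        "mean_expression", ascending=False, kind="stable"
    ).reset_index(drop=True)


def gsea(
    scores: pd.Series | dict,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Classic running-sum enrichment of ``gene_set`` in a score ranking.

    Genes are ranked by score descending; the running sum gains
    1/|set∩ranked| at members and loses 1/(N−|set|) elsewhere; ES is the
    maximum of the running sum.  The p-value is one-sided: the fraction
    of ``n_perm`` random same-size gene sets whose ES is at least the
    observed one.
    """
    scores = pd.Series(scores, dtype=np.float64)
    ranked = scores.sort_values(ascending=False, kind="stable").index.to_numpy()
    n = ranked.size
    members = np.isin(ranked, list(gene_set))
    k = int(members.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked genes")
    if k == n:
        raise ValueError("gene set covers all ranked genes; enrichment degenerate")
    es = _running_max(members, k, n)
    rng = substream(seed, "gsea_permutations")
    null = np.empty(n_perm)
    hit, miss = 1.0 / k, -1.0 / (n - k)
    for b in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        null[b] = np.maximum.accumulate(np.cumsum(np.where(perm, hit, miss))).max()
    p = float(np.count_nonzero(null >= es)) / n_perm
    return float(es), p


def _running_max(members: np.ndarray, k: int, n: int) -> float:
    steps = np.where(members, 1.0 / k, -1.0 / (n - k))
    return float(np.cumsum(steps).max())
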