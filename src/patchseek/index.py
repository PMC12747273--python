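"""Searchable vector indexes over unit-norm embeddings.

Three backends share one search contract (ascending Euclidean distance,
ties to the lower item id):

* ``ExactIndex`` — brute force over raw vectors; the oracle every
  approximate backend is measured against.
* ``IVFPQIndex`` — inverted-file coarse k-means partition with product
  quantization of the residuals and asymmetric (ADC) distances, probing
  the ``nprobe`` nearest Voronoi cells per query.
* ``ITQLSHIndex`` — PCA + iterative-quantization rotation to compact
  binary codes (32 or 64 bits) compared by Hamming distance.

``mosaic_select`` subsamples an indexed set down to its most
representative patches (k-means over standardized features and spatial
coordinates, keeping the items nearest each cluster centroid), the
mechanism that shrinks a slide's search space to a 5–20% mosaic.
"""

from __future__ import annotations

import json
import math
import struct
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from ._kmeans import assign, kmeans
from ._rng import substream
from .encoding import EmbeddingMatrix
from .patching import PatchRef

__all__ = [
    "SearchResult",
    "ExactIndex",
    "ProductQuantizer",
    "IVFPQIndex",
    "ITQHasher",
    "ITQLSHIndex",
    "build_exact",
    "build_ivfpq",
    "build_itq_lsh",
    "mosaic_select",
    "save_index",
    "load_index",
]


@dataclass
class SearchResult:
    """Top-K hits: item ids with ascending non-negative distances."""

    item_ids: np.ndarray
    distances: np.ndarray
    complete: bool = True  # False when probed lists held fewer than K items

    def __post_init__(self) -> None:
        self.item_ids = np.asarray(self.item_ids, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.item_ids) != len(self.distances):
            raise ValueError("ids and distances must align")
        if np.any(self.distances < -1e-9):
            raise ValueError("distances must be non-negative")
        if np.any(np.diff(self.distances) < -1e-9):
            raise ValueError("distances must be ascending")

    def __len__(self) -> int:
        return len(self.item_ids)


def _check_unit(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    norms = np.linalg.norm(values, axis=1)
    if values.shape[0] and not np.allclose(norms, 1.0, atol=1e-5):
        raise ValueError("index requires unit-norm rows; call unit_normalize first")
    return values


def _as_values(embeddings) -> tuple[np.ndarray, list[PatchRef]]:
    if isinstance(embeddings, EmbeddingMatrix):
        return embeddings.values, list(embeddings.meta)
    return _check_unit(embeddings), []


def _top_k(distances: np.ndarray, ids: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Smallest-k by (distance, id) — deterministic under ties."""
    order = np.lexsort((ids, distances))[:k]
    return ids[order], distances[order]


class ExactIndex(BaseEstimator):
    """Brute-force Euclidean search over the raw unit vectors."""

    backend = "exact"

    def fit(self, embeddings):
        values, meta = _as_values(embeddings)
        self.values_ = values
        self.item_meta_ = meta
        return self

    @property
    def n_items(self) -> int:
        return self.values_.shape[0]

    @property
    def dim(self) -> int:
        return self.values_.shape[1]

    def search(self, query: np.ndarray, k: int = 5) -> SearchResult:
        query = np.asarray(query, dtype=np.float64).reshape(-1)
        if query.shape[0] != self.dim:
            raise ValueError(
                f"query dimension {query.shape[0]} != index dimension {self.dim}"
            )
        d2 = np.maximum(np.sum((self.values_ - query) ** 2, axis=1), 0.0)
        ids, dist2 = _top_k(d2, np.arange(self.n_items), k)
        return SearchResult(ids, np.sqrt(dist2))


class ProductQuantizer(BaseEstimator):
    """Per-subspace k-means codebooks; m sub-vector codes per item.

    With ``ksub <= 256`` each subcode fits one byte, so an item costs m
    bytes of code memory (the compact-code regime of the IVF-PQ index).
    """

    def __init__(self, m: int = 8, ksub: int = 256, seed: int = 0):
        self.m = m
        self.ksub = ksub
        self.seed = seed

    def fit(self, X: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        if d % self.m:
            raise ValueError(f"dimension {d} not divisible by m={self.m}")
        if self.ksub > n:
            raise ValueError(f"ksub={self.ksub} exceeds n_items={n}")
        dsub = d // self.m
        rng = substream(self.seed, "pq_train")
        self.codebooks_ = np.empty((self.m, self.ksub, dsub))
        for i in range(self.m):
            sub = X[:, i * dsub : (i + 1) * dsub]
            self.codebooks_[i], _ = kmeans(sub, self.ksub, rng)
        self.dsub_ = dsub
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Encode rows to (n, m) centroid-id codes."""
        X = np.asarray(X, dtype=np.float64)
        codes = np.empty((X.shape[0], self.m), dtype=np.uint16)
        for i in range(self.m):
            sub = X[:, i * self.dsub_ : (i + 1) * self.dsub_]
            codes[:, i] = assign(sub, self.codebooks_[i])
        return codes

    def inverse_transform(self, codes: np.ndarray) -> np.ndarray:
        parts = [self.codebooks_[i][codes[:, i]] for i in range(self.m)]
        return np.concatenate(parts, axis=1)

    def adc_lut(self, query: np.ndarray) -> np.ndarray:
        """Squared distance from each query sub-vector to every centroid."""
        query = np.asarray(query, dtype=np.float64).reshape(self.m, self.dsub_)
        return np.stack(
            [
                np.sum((self.codebooks_[i] - query[i]) ** 2, axis=1)
                for i in range(self.m)
            ]
        )

    def adc_distance(self, query: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """Asymmetric distances: sqrt of summed per-subspace squared terms."""
        codes = np.atleast_2d(codes)
        lut = self.adc_lut(query)
        d2 = lut[np.arange(self.m)[None, :], codes].sum(axis=1)
        return np.sqrt(np.maximum(d2, 0.0))


class IVFPQIndex(BaseEstimator):
    """Inverted-file + product-quantization approximate index.

    Items are partitioned into ``nlist`` Voronoi cells by coarse k-means;
    residuals to the cell centroid are PQ-encoded (``encode_residuals``
    False switches to direct encoding).  A query scans the coarse
    centroids exactly (at desk scale an HNSW shortcut is unnecessary),
    probes the ``nprobe`` nearest cells, and ranks candidates by ADC
    distance.
    """

    backend = "ivfpq"

    def __init__(
        self,
        nlist: int = 32,
        m: int = 8,
        ksub: int = 256,
        nprobe: int = 8,
        encode_residuals: bool = True,
        seed: int = 0,
    ):
        self.nlist = nlist
        self.m = m
        self.ksub = ksub
        self.nprobe = nprobe
        self.encode_residuals = encode_residuals
        self.seed = seed

    def fit(self, embeddings):
        values, meta = _as_values(embeddings)
        n = values.shape[0]
        if self.nlist > n:
            raise ValueError(f"nlist={self.nlist} exceeds n_items={n}")
        rng = substream(self.seed, "ivf_coarse")
        self.centroids_, labels = kmeans(values, self.nlist, rng)
        train = values - self.centroids_[labels] if self.encode_residuals else values
        self.pq_ = ProductQuantizer(self.m, self.ksub, self.seed).fit(train)
        self.codes_ = self.pq_.transform(train)
        self.list_ids_ = [np.flatnonzero(labels == j) for j in range(self.nlist)]
        self.labels_ = labels
        self.values_dim_ = values.shape[1]
        self.n_items_ = n
        self.item_meta_ = meta
        return self

    @property
    def n_items(self) -> int:
        return self.n_items_

    @property
    def dim(self) -> int:
        return self.values_dim_

    def search(self, query: np.ndarray, k: int = 5, nprobe: int | None = None) -> SearchResult:
        query = np.asarray(query, dtype=np.float64).reshape(-1)
        if query.shape[0] != self.dim:
            raise ValueError(
                f"query dimension {query.shape[0]} != index dimension {self.dim}"
            )
        nprobe = self.nprobe if nprobe is None else nprobe
        if nprobe > self.nlist:
            warnings.warn(f"nprobe={nprobe} clamped to nlist={self.nlist}")
            nprobe = self.nlist
        cd = np.sum((self.centroids_ - query) ** 2, axis=1)
        probe = np.argsort(cd, kind="stable")[:nprobe]
        all_ids, all_d = [], []
        for j in probe:
            ids = self.list_ids_[j]
            if ids.size == 0:
                continue
            q = query - self.centroids_[j] if self.encode_residuals else query
            all_ids.append(ids)
            all_d.append(self.pq_.adc_distance(q, self.codes_[ids]))
        if not all_ids:
            return SearchResult(np.empty(0, np.int64), np.empty(0), complete=False)
        ids = np.concatenate(all_ids)
        dist = np.concatenate(all_d)
        top_ids, top_d = _top_k(dist, ids, k)
        if len(top_ids) < k:
            warnings.warn(f"probed lists held only {len(top_ids)} < k={k} items")
        return SearchResult(top_ids, top_d, complete=len(top_ids) >= k)


class ITQHasher(BaseEstimator):
    """PCA + iterative-quantization rotation to ``n_bits`` binary codes.

    Alternates sign assignment ``B = sign(VR)`` with the orthogonal
    Procrustes update of R, which never increases the quantization error
    ``‖B − VR‖²`` (tracked in ``quantization_errors_``).
    """

    def __init__(self, n_bits: int = 64, n_iter: int = 50, seed: int = 0):
        self.n_bits = n_bits
        self.n_iter = n_iter
        self.seed = seed

    def fit(self, X: np.ndarray):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] < self.n_bits:  # zero-pad features up to the code length
            X = np.pad(X, ((0, 0), (0, self.n_bits - X.shape[1])))
        self.pad_dim_ = X.shape[1]
        pca = PCA(n_components=self.n_bits, random_state=abs(self.seed) % (2**31)).fit(X)
        self.mean_ = pca.mean_
        self.components_ = pca.components_
        V = (X - self.mean_) @ self.components_.T
        rng = substream(self.seed, "itq_rotation")
        R, _ = np.linalg.qr(rng.standard_normal((self.n_bits, self.n_bits)))
        errors = []
        for _ in range(self.n_iter):
            Z = V @ R
            B = np.where(Z >= 0, 1.0, -1.0)
            errors.append(float(np.sum((B - Z) ** 2)))
            U, _, Vt = np.linalg.svd(V.T @ B)
            R = U @ Vt
        self.rotation_ = R
        self.quantization_errors_ = errors
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Binary codes as a boolean (n, n_bits) array."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] < self.pad_dim_:
            X = np.pad(X, ((0, 0), (0, self.pad_dim_ - X.shape[1])))
        return ((X - self.mean_) @ self.components_.T @ self.rotation_) >= 0


class ITQLSHIndex(BaseEstimator):
    """Binary-code index searched by Hamming distance."""

    backend = "itq_lsh"

    def __init__(self, n_bits: int = 64, n_iter: int = 50, seed: int = 0):
        self.n_bits = n_bits
        self.n_iter = n_iter
        self.seed = seed

    def fit(self, embeddings):
        values, meta = _as_values(embeddings)
        self.hasher_ = ITQHasher(self.n_bits, self.n_iter, self.seed).fit(values)
        self.codes_ = self.hasher_.transform(values)
        self.values_dim_ = values.shape[1]
        self.item_meta_ = meta
        return self

    @property
    def n_items(self) -> int:
        return self.codes_.shape[0]

    @property
    def dim(self) -> int:
        return self.values_dim_

    def search(self, query: np.ndarray, k: int = 5) -> SearchResult:
        query = np.asarray(query, dtype=np.float64).reshape(-1)
        if query.shape[0] != self.dim:
            raise ValueError(
                f"query dimension {query.shape[0]} != index dimension {self.dim}"
            )
        qcode = self.hasher_.transform(query[None, :])[0]
        ham = np.count_nonzero(self.codes_ != qcode, axis=1).astype(np.float64)
        ids, dist = _top_k(ham, np.arange(self.n_items), k)
        return SearchResult(ids, dist)


def build_exact(embeddings) -> ExactIndex:
    return ExactIndex().fit(embeddings)


def build_ivfpq(embeddings, nlist=32, m=8, ksub=256, nprobe=8, seed=0, **kw) -> IVFPQIndex:
    return IVFPQIndex(nlist=nlist, m=m, ksub=ksub, nprobe=nprobe, seed=seed, **kw).fit(
        embeddings
    )


def build_itq_lsh(embeddings, n_bits=64, n_iter=50, seed=0) -> ITQLSHIndex:
    return ITQLSHIndex(n_bits=n_bits, n_iter=n_iter, seed=seed).fit(embeddings)


def mosaic_select(
    embeddings,
    coords: np.ndarray,
    fraction: float = 0.2,
    n_clusters: int = 9,
    seed: int = 0,
) -> np.ndarray:
    """Representative-patch subsample (the "mosaic") of an item set.

    K-means runs on the concatenation of z-scored features and z-scored
    patch-center coordinates; within each cluster, items are ranked by
    distance to their centroid and the closest ``ceil(fraction·size)``
    (at least one) are kept.  Returned ids are sorted ascending.
    """
    values, _ = _as_values(embeddings)
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coords must align with embeddings")
    if n_clusters > values.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_items={values.shape[0]}")

    def zscore(a):
        sd = a.std(axis=0)
        sd[sd == 0] = 1.0
        return (a - a.mean(axis=0)) / sd

    X = np.concatenate([zscore(values), zscore(coords)], axis=1)
    rng = substream(seed, "mosaic_kmeans")
    centroids, labels = kmeans(X, n_clusters, rng)
    keep: list[np.ndarray] = []
    for j in range(n_clusters):
        members = np.flatnonzero(labels == j)
        if members.size == 0:
            continue
        d = np.sum((X[members] - centroids[j]) ** 2, axis=1)
        n_keep = max(math.ceil(fraction * members.size), 1)
        order = np.lexsort((members, d))[:n_keep]
        keep.append(members[order])
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# persistence: one binary file = magic, JSON header, raw little-endian arrays

_MAGIC = b"PSIDX001"
_FORMAT_VERSION = 1


def _meta_to_arrays(meta: list[PatchRef]) -> dict[str, np.ndarray]:
    return {
        "meta_slide": np.array([r.slide_id for r in meta], dtype="S64"),
        "meta_x": np.array([r.x for r in meta], dtype=np.int64),
        "meta_y": np.array([r.y for r in meta], dtype=np.int64),
        "meta_size": np.array([r.size_px for r in meta], dtype=np.int64),
        "meta_mag": np.array([r.magnification_tag for r in meta], dtype="S8"),
    }


def _arrays_to_meta(arrays: dict[str, np.ndarray]) -> list[PatchRef]:
    if "meta_slide" not in arrays or arrays["meta_slide"].size == 0:
        return []
    return [
        PatchRef(s.decode(), int(x), int(y), int(sz), mag.decode())
        for s, x, y, sz, mag in zip(
            arrays["meta_slide"], arrays["meta_x"], arrays["meta_y"],
            arrays["meta_size"], arrays["meta_mag"],
        )
    ]


def _collect_arrays(index) -> tuple[dict, dict[str, np.ndarray]]:
    arrays: dict[str, np.ndarray] = {}
    if isinstance(index, ExactIndex):
        params: dict = {}
        arrays["values"] = index.values_
    elif isinstance(index, IVFPQIndex):
        params = {
            "nlist": index.nlist, "m": index.m, "ksub": index.ksub,
            "nprobe": index.nprobe, "encode_residuals": index.encode_residuals,
            "seed": index.seed, "dim": index.values_dim_,
        }
        arrays["centroids"] = index.centroids_
        arrays["codes"] = index.codes_
        arrays["labels"] = index.labels_
        arrays["codebooks"] = index.pq_.codebooks_
    elif isinstance(index, ITQLSHIndex):
        params = {
            "n_bits": index.n_bits, "n_iter": index.n_iter, "seed": index.seed,
            "dim": index.values_dim_, "pad_dim": index.hasher_.pad_dim_,
        }
        arrays["pca_mean"] = index.hasher_.mean_
        arrays["pca_components"] = index.hasher_.components_
        arrays["rotation"] = index.hasher_.rotation_
        arrays["codes"] = index.codes_.astype(np.uint8)
    else:
        raise TypeError(f"cannot save index of type {type(index).__name__}")
    arrays.update(_meta_to_arrays(index.item_meta_))
    return params, arrays


def save_index(index, path) -> None:
    """Write any backend to the single-file binary container."""
    params, arrays = _collect_arrays(index)
    header = {
        "format_version": _FORMAT_VERSION,
        "backend": index.backend,
        "n_items": index.n_items,
        "params": params,
        "arrays": [
            {"name": k, "dtype": str(v.dtype), "shape": list(v.shape)}
            for k, v in arrays.items()
        ],
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<Q", len(blob)))
        f.write(blob)
        for v in arrays.values():
            f.write(np.ascontiguousarray(v).tobytes())


def load_index(path):
    """Restore an index saved by :func:`save_index`; search is bit-identical."""
    with open(path, "rb") as f:
        magic = f.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError("not a patchseek index file")
        raw_len = f.read(8)
        if len(raw_len) < 8:
            raise ValueError("truncated index file")
        (hlen,) = struct.unpack("<Q", raw_len)
        blob = f.read(hlen)
        if len(blob) < hlen:
            raise ValueError("truncated index file")
        header = json.loads(blob)
        if header["format_version"] != _FORMAT_VERSION:
            raise ValueError(
                f"index format version {header['format_version']} unsupported"
            )
        arrays = {}
        for spec in header["arrays"]:
            dtype = np.dtype(spec["dtype"])
            count = int(np.prod(spec["shape"])) if spec["shape"] else 1
            buf = f.read(count * dtype.itemsize)
            if len(buf) < count * dtype.itemsize:
                raise ValueError("truncated index file")
            arrays[spec["name"]] = np.frombuffer(buf, dtype=dtype).reshape(spec["shape"])

    backend, params = header["backend"], header["params"]
    meta = _arrays_to_meta(arrays)
    if backend == "exact":
        idx = ExactIndex()
        idx.values_ = arrays["values"].astype(np.float64)
        idx.item_meta_ = meta
    elif backend == "ivfpq":
        idx = IVFPQIndex(
            nlist=params["nlist"], m=params["m"], ksub=params["ksub"],
            nprobe=params["nprobe"], encode_residuals=params["encode_residuals"],
            seed=params["seed"],
        )
        idx.centroids_ = arrays["centroids"].astype(np.float64)
        idx.codes_ = arrays["codes"].astype(np.uint16)
        idx.labels_ = arrays["labels"].astype(np.int64)
        idx.list_ids_ = [np.flatnonzero(idx.labels_ == j) for j in range(idx.nlist)]
        idx.pq_ = ProductQuantizer(params["m"], params["ksub"], params["seed"])
        idx.pq_.codebooks_ = arrays["codebooks"].astype(np.float64)
        idx.pq_.dsub_ = idx.pq_.codebooks_.shape[2]
        idx.values_dim_ = params["dim"]
        idx.n_items_ = len(idx.labels_)
        idx.item_meta_ = meta
    elif backend == "itq_lsh":
        idx = ITQLSHIndex(n_bits=params["n_bits"], n_iter=params["n_iter"], seed=params["seed"])
        hasher = ITQHasher(params["n_bits"], params["n_iter"], params["seed"])
        hasher.pad_dim_ = params["pad_dim"]
        hasher.mean_ = arrays["pca_mean"].astype(np.float64)
        hasher.components_ = arrays["pca_components"].astype(np.float64)
        hasher.rotation_ = arrays["rotation"].astype(np.float64)
        idx.hasher_ = hasher
        idx.codes_ = arrays["codes"].astype(bool)
        idx.values_dim_ = params["dim"]
        idx.item_meta_ = meta
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return idx
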