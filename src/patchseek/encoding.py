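"""Patch encoding: pluggable backbones, 256-d projection, unit normalisation.

The engine is encoder-agnostic: any callable mapping a stack of equal-size
pixel patches to an N×d_raw matrix can serve as the backbone.  A small
deterministic colour/texture encoder ships in-repo so the whole pipeline
runs without pretrained weights.  Downstream modules consume
:class:`EmbeddingMatrix` rows of exact unit Euclidean norm, which makes
cosine similarity and Euclidean distance produce identical rankings
(``‖u−v‖² = 2 − 2·u·v`` for unit vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from ._rng import substream
from .patching import PatchRef

__all__ = [
    "EmbeddingMatrix",
    "ToyHistogramEncoder",
    "encode_patches",
    "project",
    "unit_normalize",
    "save_embeddings",
    "load_embeddings",
]


@dataclass
class EmbeddingMatrix:
    """N×D feature matrix with one :class:`PatchRef` per row.

    Rows are unit-norm (within 1e-6) and finite; both are checked at
    construction because every index backend relies on them.
    """

    values: np.ndarray
    meta: list[PatchRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embedding entries")
        if self.meta and len(self.meta) != self.values.shape[0]:
            raise ValueError("meta length must equal number of rows")
        norms = np.linalg.norm(self.values, axis=1)
        if self.values.shape[0] and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("rows must be unit-norm; call unit_normalize first")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


class ToyHistogramEncoder:
    """Deterministic colour-histogram + gradient-texture patch encoder.

    Features per patch: an 8-bin histogram for each RGB channel (24
    values, normalised to frequencies) plus mean and standard deviation
    of the absolute intensity gradient along each image axis (4 values).
    A fixed seeded random projection maps the 28 features to ``d_raw``.
    """

    N_FEATURES = 28

    def __init__(self, d_raw: int = 32, seed: int = 0):
        if d_raw < 1:
            raise ValueError("d_raw must be >= 1")
        self.d_raw = d_raw
        self.seed = seed
        rng = substream(seed, "toy_histogram_projection")
        self._proj = rng.standard_normal((self.N_FEATURES, d_raw)) / np.sqrt(
            self.N_FEATURES
        )

    def _features(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=np.float64)
        if patch.ndim == 2:
            patch = patch[..., None].repeat(3, axis=2)
        feats = []
        for c in range(3):
            hist, _ = np.histogram(patch[..., c], bins=8, range=(0, 256))
            feats.append(hist / patch[..., c].size)
        gray = patch.mean(axis=2)
        gy, gx = np.gradient(gray)
        feats.append(
            np.array([np.abs(gx).mean(), np.abs(gx).std(), np.abs(gy).mean(), np.abs(gy).std()])
            / 255.0
        )
        return np.concatenate(feats)

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim < 3:
            raise ValueError("expected a stack of patches")
        feats = np.stack([self._features(p) for p in patches])
        return feats @ self._proj


def encode_patches(patches, encoder) -> np.ndarray:
    """Apply ``encoder`` (any callable stack→matrix) to equal-size patches."""
    shapes = {np.asarray(p).shape for p in patches}
    if len(shapes) > 1:
        raise ValueError(f"mixed patch sizes: {sorted(shapes)}")
    return np.asarray(encoder(np.asarray(patches)), dtype=np.float64)


def project(raw: np.ndarray, weights: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Affine row-wise map ``raw @ weights + bias`` (d_raw → d_proj)."""
    raw = np.asarray(raw, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if raw.ndim != 2 or weights.ndim != 2 or raw.shape[1] != weights.shape[0]:
        raise ValueError(
            f"shape mismatch: raw {raw.shape} vs weights {weights.shape}"
        )
    out = raw @ weights
    if bias is not None:
        bias = np.asarray(bias, dtype=np.float64)
        if bias.shape != (weights.shape[1],):
            raise ValueError("bias shape must be (d_proj,)")
        out = out + bias
    return out


def identity_pad_weights(d_raw: int, d_proj: int) -> np.ndarray:
    """Identity projection padded (or truncated) to ``d_proj`` columns.

    Lets the index run on raw backbone features when no trained
    projection is supplied.
    """
    w = np.zeros((d_raw, d_proj))
    k = min(d_raw, d_proj)
    w[:k, :k] = np.eye(k)
    return w


def unit_normalize(matrix: np.ndarray, meta: list[PatchRef] | None = None) -> EmbeddingMatrix:
    """Scale every row to unit Euclidean length, preserving direction."""
    matrix = np.asarray(matrix, dtype=np.float64)
    norms = np.linalg.norm(matrix, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"cannot normalize all-zero row(s) {zero.tolist()}")
    return EmbeddingMatrix(matrix / norms[:, None], meta or [])


_REF_DTYPE = np.dtype(
    [("slide_id", "S64"), ("x", "i8"), ("y", "i8"), ("size_px", "i8"), ("mag", "S8")]
)


def save_embeddings(path, emb: EmbeddingMatrix, encoder_kind: str = "", seed: int = 0) -> None:
    """Persist an embedding matrix + patch refs to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("embeddings", data=emb.values.astype(np.float32))
        refs = np.array(
            [
                (r.slide_id.encode(), r.x, r.y, r.size_px, r.magnification_tag.encode())
                for r in emb.meta
            ],
            dtype=_REF_DTYPE,
        )
        f.create_dataset("patch_refs", data=refs)
        f.attrs["d_proj"] = emb.dim
        f.attrs["encoder_kind"] = encoder_kind
        f.attrs["seed"] = seed


def load_embeddings(path) -> EmbeddingMatrix:
    with h5py.File(path, "r") as f:
        values = f["embeddings"][...].astype(np.float64)
        meta = [
            PatchRef(
                r["slide_id"].decode(), int(r["x"]), int(r["y"]),
                int(r["size_px"]), r["mag"].decode(),
            )
            for r in f["patch_refs"][...]
        ]
    # float32 storage loses a little norm precision; restore the invariant
    return unit_normalize(values, meta)
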