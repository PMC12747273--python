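"""Synthetic inputs with planted ground truth.

Everything the engine consumes can be generated here: textured
tissue-vs-background slide images, multiple-instance cohorts of patch
embeddings with planted class signal, and spatial-transcriptomics
profiles with planted cluster-specific differential expression at stated
effect sizes.  All generators are bit-reproducible given their spec; one
global seed expands into named substreams so adding a generator never
perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .encoding import unit_normalize
from .st_profile import STProfile

__all__ = [
    "SyntheticSlideSpec",
    "MILCohortSpec",
    "STProfileSpec",
    "MILCohort",
    "gen_slide",
    "gen_mil_cohort",
    "gen_st_profile",
    "gen_embedding_clusters",
    "build_expression_labels",
    "label_patch_by_majority_area",
    "UNLABELED",
]

#: sentinel returned when a patch box contains no annotated pixel
UNLABELED = -1

# saturated region colors, cycled by class label, on a near-white background
_REGION_COLORS = [
    (200, 40, 60),
    (40, 160, 60),
    (60, 60, 200),
    (200, 140, 30),
    (150, 40, 170),
    (30, 170, 170),
]


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Geometry of a fake slide: saturated tissue regions on near-white glass."""

    width_px: int = 512
    height_px: int = 512
    tissue_regions: tuple = ()  # (shape, (cx, cy), radius_px, class_label)
    background_color: tuple = (245, 245, 245)
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for shape, (cx, cy), r, _label in self.tissue_regions:
            if shape not in ("disk", "square"):
                raise ValueError(f"unknown region shape {shape!r}")
            if not (0 <= cx < self.width_px and 0 <= cy < self.height_px):
                raise ValueError("region center outside image bounds")
            if r <= 0:
                raise ValueError("region radius must be positive")


def _region_mask(shape: str, cx: float, cy: float, r: float, w: int, h: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    if shape == "disk":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return (np.abs(xx - cx) <= r) & (np.abs(yy - cy) <= r)


def gen_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a slide; returns ``(image, tissue_mask, label_map)``.

    Regions are drawn in saturated colours so the HSV saturation
    segmenter can recover them; the label map holds each region's class
    per pixel and :data:`UNLABELED` elsewhere.  Overlapping regions with
    conflicting class labels are an error.
    """
    w, h = spec.width_px, spec.height_px
    rng = substream(spec.seed, "gen_slide")
    image = np.tile(np.asarray(spec.background_color, float), (h, w, 1))
    tissue = np.zeros((h, w), dtype=bool)
    labels = np.full((h, w), UNLABELED, dtype=np.int64)
    for shape, (cx, cy), r, label in spec.tissue_regions:
        m = _region_mask(shape, cx, cy, r, w, h)
        conflict = m & tissue & (labels != label)
        if conflict.any():
            raise ValueError("overlapping regions with conflicting labels")
        color = _REGION_COLORS[label % len(_REGION_COLORS)]
        image[m] = color
        tissue |= m
        labels[m] = label
    if spec.noise_sd > 0:
        image = image + rng.normal(0, spec.noise_sd, image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8), tissue, labels


@dataclass(frozen=True)
class MILCohortSpec:
    """Cohort of per-slide embedding bags with planted molecular signal.

    ``effect_size`` is the mean shift of signal patches in units of the
    isotropic unit-variance embedding noise; ``signal_fraction`` is the
    fraction of patches in a non-baseline slide that carry the shift.
    """

    n_patients: int = 100
    patches_per_slide: int = 32
    d_raw: int = 32
    signal_fraction: float = 0.5
    effect_size: float = 5.0
    n_mutation_tasks: int = 1
    n_regression_tasks: int = 1
    slides_per_patient: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.signal_fraction <= 1:
            raise ValueError("signal_fraction must be in (0, 1]")
        if int(self.signal_fraction * self.patches_per_slide) < 1:
            raise ValueError(
                "signal_fraction * patches_per_slide must be >= 1 patch"
            )


@dataclass
class MILCohort:
    bags: list[np.ndarray]  # per slide: n_patches × d_raw
    slide_ids: list[str]
    patient_ids: list[str]
    class_labels: np.ndarray  # n_slides × n_mutation_tasks, values in {0,1,2}
    reg_targets: np.ndarray  # n_slides × n_regression_tasks
    spec: MILCohortSpec | None = None


def gen_mil_cohort(spec: MILCohortSpec) -> MILCohort:
    """Draw a cohort of embedding bags with planted class/regression signal.

    Baseline patches are isotropic standard Gaussians.  For each
    3-class mutation task, classes 1 and 2 each own an orthonormal
    direction; a slide of class c>0 has ``signal_fraction`` of its
    patches shifted by ``effect_size`` along that task's class
    direction.  Each regression task owns a further direction; the
    slide's planted coefficient scales the shift of its signal patches
    and the target equals that coefficient plus observation noise.
    """
    rng = substream(spec.seed, "gen_mil_cohort")
    n_dirs = 2 * spec.n_mutation_tasks + spec.n_regression_tasks
    if n_dirs > spec.d_raw:
        raise ValueError("d_raw too small for the requested task directions")
    # orthonormal planted directions via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.standard_normal((spec.d_raw, n_dirs)))
    cls_dirs = q[:, : 2 * spec.n_mutation_tasks].T.reshape(
        spec.n_mutation_tasks, 2, spec.d_raw
    )
    reg_dirs = q[:, 2 * spec.n_mutation_tasks :].T

    n_signal = int(spec.signal_fraction * spec.patches_per_slide)
    bags, slide_ids, patient_ids = [], [], []
    n_slides = spec.n_patients * spec.slides_per_patient
    class_labels = np.zeros((n_slides, spec.n_mutation_tasks), dtype=np.int64)
    reg_targets = np.zeros((n_slides, spec.n_regression_tasks))

    s = 0
    for p in range(spec.n_patients):
        cls = rng.integers(0, 3, size=spec.n_mutation_tasks)
        coef = rng.standard_normal(spec.n_regression_tasks)
        for k in range(spec.slides_per_patient):
            bag = rng.standard_normal((spec.patches_per_slide, spec.d_raw))
            sig = rng.choice(spec.patches_per_slide, size=n_signal, replace=False)
            for t in range(spec.n_mutation_tasks):
                if cls[t] > 0:
                    bag[sig] += spec.effect_size * cls_dirs[t, cls[t] - 1]
            for j in range(spec.n_regression_tasks):
                bag[sig] += coef[j] * spec.effect_size * reg_dirs[j]
            bags.append(bag)
            slide_ids.append(f"P{p:04d}_S{k}")
            patient_ids.append(f"P{p:04d}")
            class_labels[s] = cls
            reg_targets[s] = coef + 0.1 * rng.standard_normal(spec.n_regression_tasks)
            s += 1
    return MILCohort(bags, slide_ids, patient_ids, class_labels, reg_targets, spec)


@dataclass(frozen=True)
class STProfileSpec:
    """Spatial profile with planted morphology clusters and DE genes.

    ``de_genes`` plants (gene, cluster, Cohen's d) triples: the gene's
    continuous log-scale expression in that cluster is shifted by
    ``d · baseline_sd`` so the population standardized mean difference
    equals the target.  Counts are rounded log-normal intensities, so
    the planted d survives the engine's log1p transform up to rounding.
    """

    n_spots: int = 400
    n_genes: int = 50
    n_clusters: int = 8
    spot_spacing_px: float = 100.0
    mpp: float = 0.5
    de_genes: tuple = ()  # (gene_idx, cluster_idx, cohens_d_target)
    baseline_mean: float = 2.0
    baseline_sd: float = 0.5
    cluster_separation: float = 6.0
    embed_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        for g, c, d in self.de_genes:
            if not (0 <= g < self.n_genes and 0 <= c < self.n_clusters):
                raise ValueError("de_genes references invalid gene/cluster index")
            if d != 0 and self.baseline_sd == 0:
                raise ValueError("Cohen's d target undefined with baseline_sd=0")


def gen_st_profile(spec: STProfileSpec, profile_id: str = "synthetic_st") -> STProfile:
    """Generate an :class:`STProfile` with planted clusters and DE genes."""
    rng = substream(spec.seed, "gen_st_profile")
    side = math.ceil(math.sqrt(spec.n_spots))
    grid = np.array(
        [(i % side, i // side) for i in range(spec.n_spots)], dtype=np.float64
    )
    spot_xy = (grid + 1) * spec.spot_spacing_px

    labels = rng.integers(0, spec.n_clusters, size=spec.n_spots)
    if spec.n_clusters <= spec.embed_dim:
        # orthonormal center directions: maximal, uniform angular separation
        q, _ = np.linalg.qr(rng.standard_normal((spec.embed_dim, spec.n_clusters)))
        centers = spec.cluster_separation * q.T
    else:
        centers = rng.standard_normal((spec.n_clusters, spec.embed_dim))
        centers *= spec.cluster_separation / np.linalg.norm(centers, axis=1, keepdims=True)
    emb = centers[labels] + rng.standard_normal((spec.n_spots, spec.embed_dim))
    embeddings = unit_normalize(emb)

    intensity = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(
        (spec.n_genes, spec.n_spots)
    )
    for g, c, d in spec.de_genes:
        intensity[g, labels == c] += d * spec.baseline_sd
    counts = np.maximum(np.round(np.expm1(np.maximum(intensity, 0))), 0)

    return STProfile(
        profile_id=profile_id,
        spot_ids=[f"spot{i:04d}" for i in range(spec.n_spots)],
        spot_xy=spot_xy,
        mpp=spec.mpp,
        counts=sp.csr_matrix(counts),
        gene_names=[f"GENE{g:04d}" for g in range(spec.n_genes)],
        spot_embeddings=embeddings,
        cluster_labels=labels,
    )


def gen_embedding_clusters(
    n_items: int,
    dim: int = 64,
    n_clusters: int = 1000,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors in small near-duplicate groups; returns (values, labels).

    Emulates a precomputed patch-embedding database: each cluster is a
    group of morphologically near-identical patches (one random unit
    center direction plus isotropic noise of ``noise_sd`` per
    coordinate, re-normalised).  Items are distributed round-robin so
    cluster sizes differ by at most one.
    """
    rng = substream(seed, "gen_embedding_clusters")
    if n_clusters > n_items:
        raise ValueError("n_clusters exceeds n_items")
    centers = rng.standard_normal((n_clusters, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    labels = np.arange(n_items) % n_clusters
    values = centers[labels] + noise_sd * rng.standard_normal((n_items, dim))
    return unit_normalize(values).values, labels


def build_expression_labels(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    ctl_genes: list[str],
    normal_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Turn a genes×samples FPKM matrix into per-sample regression labels.

    Values are transformed to log2(FPKM+1) and centred gene-wise by the
    mean over the designated normal samples (or over all samples when no
    normals exist).  The output has one column per gene set (mean of its
    centred member genes) plus a ``CTL`` column, the per-sample median of
    the five cytotoxic-T-lymphocyte genes.
    """
    missing = [g for g in ctl_genes if g not in expression.index]
    if missing:
        raise ValueError(f"ctl_genes absent from matrix: {missing}")
    logged = np.log2(expression.astype(np.float64) + 1.0)
    ref_cols = normal_samples if normal_samples else list(logged.columns)
    centered = logged.sub(logged[ref_cols].mean(axis=1), axis=0)
    out = {}
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        absent = [g for g in genes if g not in centered.index]
        if absent:
            raise ValueError(f"gene set {name!r} members absent: {absent}")
        out[name] = centered.loc[genes].mean(axis=0)
    out["CTL"] = centered.loc[ctl_genes].median(axis=0)
    return pd.DataFrame(out)


def label_patch_by_majority_area(
    annotation_mask: np.ndarray, patch_box: tuple[int, int, int, int]
) -> int:
    """Label of the largest annotated area in ``patch_box`` (x, y, w, h).

    Pixels equal to :data:`UNLABELED` are ignored; a fully unlabeled box
    returns :data:`UNLABELED`.  Exact area ties resolve to the smallest
    label id, which is deterministic and independent of pixel order.
    """
    x, y, w, h = patch_box
    mask = np.asarray(annotation_mask)
    if x < 0 or y < 0 or x + w > mask.shape[1] or y + h > mask.shape[0]:
        raise ValueError("patch box outside mask bounds")
    window = mask[y : y + h, x : x + w]
    values, counts = np.unique(window[window != UNLABELED], return_counts=True)
    if values.size == 0:
        return UNLABELED
    # np.unique returns sorted labels, argmax takes the first maximum:
    # the tie rule (smallest label id) falls out of the ordering
    return int(values[np.argmax(counts)])
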