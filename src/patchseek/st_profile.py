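"""Container and text I/O for a spatial-transcriptomics profile.

A profile couples spot pixel coordinates on an H&E slide (with the scan's
microns-per-pixel), a sparse gene×spot count matrix, per-spot image-patch
embeddings, and a per-spot cluster label.  On disk a profile is a plain
directory: Matrix Market counts plus TSV gene and spot tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .encoding import EmbeddingMatrix, unit_normalize

__all__ = ["STProfile", "save_st_profile", "load_st_profile"]


@dataclass
class STProfile:
    profile_id: str
    spot_ids: list[str]
    spot_xy: np.ndarray  # n_spots×2 pixel coordinates
    mpp: float
    counts: sp.csr_matrix  # genes×spots
    gene_names: list[str]
    spot_embeddings: EmbeddingMatrix | None = None
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_xy = np.asarray(self.spot_xy, dtype=np.float64)
        if self.counts.shape[1] != len(self.spot_ids):
            raise ValueError("counts columns must align with spots")
        if self.counts.shape[0] != len(self.gene_names):
            raise ValueError("counts rows must align with gene names")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


def save_st_profile(profile: STProfile, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "counts.mtx", sp.coo_matrix(profile.counts))
    pd.DataFrame({"gene": profile.gene_names}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    spots = pd.DataFrame(
        {
            "spot_id": profile.spot_ids,
            "x_px": profile.spot_xy[:, 0],
            "y_px": profile.spot_xy[:, 1],
            "mpp": profile.mpp,
        }
    )
    if profile.cluster_labels is not None:
        spots["cluster"] = profile.cluster_labels
    spots.to_csv(out / "spots.tsv", sep="\t", index=False)
    if profile.spot_embeddings is not None:
        np.savetxt(out / "spot_embeddings.tsv", profile.spot_embeddings.values, delimiter="\t")


def load_st_profile(in_dir, profile_id: str | None = None) -> STProfile:
    src = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(src / "counts.mtx"))
    genes = pd.read_csv(src / "genes.tsv", sep="\t")["gene"].astype(str).tolist()
    spots = pd.read_csv(src / "spots.tsv", sep="\t")
    emb = None
    emb_path = src / "spot_embeddings.tsv"
    if emb_path.exists():
        emb = unit_normalize(np.loadtxt(emb_path, delimiter="\t", ndmin=2))
    labels = spots["cluster"].to_numpy() if "cluster" in spots else None
    return STProfile(
        profile_id=profile_id or src.name,
        spot_ids=spots["spot_id"].astype(str).tolist(),
        spot_xy=spots[["x_px", "y_px"]].to_numpy(),
        mpp=float(spots["mpp"].iloc[0]),
        counts=counts,
        gene_names=genes,
        spot_embeddings=emb,
        cluster_labels=labels,
    )
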