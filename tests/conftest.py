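import numpy as np
import pytest

from patchseek.synthetic import (
    MILCohortSpec,
    STProfileSpec,
    SyntheticSlideSpec,
    gen_embedding_clusters,
    gen_mil_cohort,
    gen_slide,
    gen_st_profile,
)


@pytest.fixture(scope="session")
def disk_slide():
    """One saturated disk on near-white glass, plus its ground truth."""
    spec = SyntheticSlideSpec(
        width_px=512,
        height_px=512,
        tissue_regions=(("disk", (256, 256), 150, 0),),
        noise_sd=2.0,
        seed=7,
    )
    return gen_slide(spec) + (spec,)


@pytest.fixture(scope="session")
def clustered_embeddings():
    """2000 unit vectors in 200 near-duplicate groups (D=64)."""
    return gen_embedding_clusters(2000, dim=64, n_clusters=200, noise_sd=0.05, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    spec = MILCohortSpec(
        n_patients=60, patches_per_slide=16, d_raw=16,
        signal_fraction=0.5, effect_size=5.0, seed=5,
    )
    return gen_mil_cohort(spec)


@pytest.fixture(scope="session")
def planted_st_profile():
    spec = STProfileSpec(
        n_spots=400, n_genes=50, n_clusters=8,
        de_genes=((7, 3, 2.0),), seed=11,
    )
    return gen_st_profile(spec)
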