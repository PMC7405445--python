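import numpy as np
import pytest

from robustrad.core import LABEL_CODES, LabelMap, MRIStudy, SEQUENCES, VolumeGrid
from robustrad.phantom import (
    CenterProfile,
    PhantomParams,
    SurvivalModel,
    generate_case,
    generate_cohort,
    single_center_profile,
    single_center_survival,
)


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Compact phantom (36^3 grid, small tumour) for fast tests."""
    return PhantomParams(
        grid_shape=(36, 36, 36),
        tumor_axes={
            "nec": (3.0, 2.5, 2.5),
            "cet": (5.5, 5.0, 4.5),
            "core": (7.5, 7.0, 6.0),
            "ed": (10.0, 9.0, 8.0),
        },
        center_jitter_mm=2.0,
    )


@pytest.fixture(scope="session")
def study(small_params) -> MRIStudy:
    st = generate_case(small_params, single_center_profile(), seed=11)
    st.os_days = 500.0
    return st


@pytest.fixture(scope="session")
def small_cohort(small_params):
    studies, clinical = generate_cohort(
        6, small_params, single_center_profile(), single_center_survival(), seed=7
    )
    return studies, clinical


def make_ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    )
    return ((coords - np.asarray(center)) ** 2).sum(-1) <= radius**2


def random_label_map(rng, shape=(14, 14, 14)) -> LabelMap:
    data = rng.integers(0, 5, size=shape).astype(np.int16)
    return LabelMap(data, (1.0, 1.0, 1.0))
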