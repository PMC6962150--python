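import numpy as np
import pytest

from radstab.core import BinaryMask, ImageVolume
from radstab.features import DiscretizedVOI
from radstab.synthetic import (
    CohortConfig,
    LesionParams,
    RaterProfile,
    simulate_cohort,
)

SMALL_PARAMS = LesionParams(
    shape=(64, 64, 48),
    spacing=(3.0, 3.0, 3.0),
    volume_range_cm3=(30.0, 70.0),
    n_foci=2,
)


def make_voi(levels: np.ndarray, G: int) -> DiscretizedVOI:
    """Wrap a raw level array (−1 = outside) as a DiscretizedVOI."""
    levels = np.asarray(levels, dtype=np.int32)
    mask = levels >= 0
    return DiscretizedVOI(levels=levels, mask=mask, G=G, n_voxels=int(mask.sum()))


def volume_and_mask(values: np.ndarray, mask: np.ndarray | None = None,
                    spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return (
        ImageVolume(values, spacing=spacing),
        BinaryMask(mask, spacing=spacing),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """3 lesions × 3 raters on a reduced grid; shared across tests."""
    cfg = CohortConfig(
        n_lesions=3,
        rater_profiles=[
            RaterProfile("r1", 0.4, -1.0, 12.0),
            RaterProfile("r2", 0.6, 1.0, 15.0),
            RaterProfile("r3", 0.8, 3.0, 10.0),
        ],
        master_seed=11,
        lesion_params=SMALL_PARAMS,
    )
    return cfg, simulate_cohort(cfg)
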