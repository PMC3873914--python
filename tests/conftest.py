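import numpy as np
import pytest

from dscnorm.phantom import (
    DEFAULT_AIF,
    AcquisitionParams,
    CohortSpec,
    TissueSpec,
    default_cohort_spec,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def time_grid(acq) -> np.ndarray:
    return acq.time


def two_roi_spec(noise: float = 0.0, seed: int = 0, ratio_cbf=(0.20, 0.10)) -> CohortSpec:
    """Minimal phantom with two tissue regions of known CBF ratio plus an
    arterial region, shared kinetics otherwise."""
    specs = [
        TissueSpec(1, "roi_a", "frontal", "lh", "cortical_gm", ratio_cbf[0], 4.0),
        TissueSpec(2, "roi_b", "frontal", "rh", "cortical_gm", ratio_cbf[1], 4.0),
        TissueSpec(3, "artery", "artery", "both", "artery", 1.0, 1.0),
    ]
    return CohortSpec(
        group_sizes={"control": 1},
        tissue_specs=specs,
        aif_params=DEFAULT_AIF,
        global_cv=0.0,
        regional_cv=0.0,
        signal_noise_sd=noise,
        shape=(12, 12, 4),
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_spec() -> CohortSpec:
    """Study-sized cohort spec with the default group effects."""
    return default_cohort_spec(seed=0)
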