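import warnings

import numpy as np
import pytest

from fiberscore import CohortSimParams, ImageSimParams, simulate_cohort, simulate_image

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def ten_fiber_image():
    """Noiseless simulator image with 10 fibers and its ground truth."""
    params = ImageSimParams(n_fibers=10, image_size_px=256, noise_sd=0.0, seed=3)
    return simulate_image(params)


@pytest.fixture(scope="session")
def null_cohort_2000():
    """n=2000 cohort with no covariate effect, ~30% censoring."""
    return simulate_cohort(
        CohortSimParams(
            n_patients=2000,
            beta={"latent": 0.0},
            censoring_target=0.3,
            admin_horizon_months=240.0,
            include_clinical=False,
            include_tacs=False,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def km_hand_fixture():
    """Six-patient two-group fixture with hand-verified KM and log-rank.

    Times 1..6 months, events 1,1,0,1,0,1, groups A,A,A,B,B,B. Worked by
    hand: O_A = 2, E_A = 0.5 + 0.4 = 0.9, V = 0.25 + 0.24 = 0.49, so the
    log-rank statistic is (2 - 0.9)^2 / 0.49 = 2.4694. KM(A) steps to 2/3
    at t=1 and 1/3 at t=2; KM(B) steps to 2/3 at t=4 and 0 at t=6.
    """
    return {
        "time": np.array([1.0, 2, 3, 4, 5, 6]),
        "event": np.array([1, 1, 0, 1, 0, 1]),
        "group_high": np.array([0.0, 0, 0, 1, 1, 1]),
        "expected_chi2": (2 - 0.9) ** 2 / 0.49,
        "expected_km_low": [1.0, 2 / 3, 1 / 3, 1 / 3],
        "expected_km_high": [1.0, 2 / 3, 2 / 3, 0.0],
    }
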