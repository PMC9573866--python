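import datetime

import numpy as np
import pytest

from otolife import CohortParams, MilledInterval, OtolithProfile, gen_fish_cohort


@pytest.fixture
def simple_profile() -> OtolithProfile:
    """A small hand-constructed JP profile with round numbers."""
    widths = np.full(117, 2.0)  # ages 4..120 dph
    return OtolithProfile(
        fish_id="F1",
        region="JP",
        increment_widths=widths,
        sl_catch_mm=120.0,
        or_first_um=10.0,
        hatch_date=datetime.date(2008, 3, 1),
        milled_intervals=[
            MilledInterval(0, 30, -5.0, 0.5),
            MilledInterval(31, 45, -5.2, 0.4),
        ],
        first_increment_dph=3,
        or_catch_um=1000.0,
    )


@pytest.fixture(scope="session")
def noisefree_jp_cohort():
    """Noise-free JP cohort: every downstream estimator should be exact."""
    params = CohortParams.for_region(
        "JP", n_fish=4, seed=11, ar1_sigma=0.0, fish_temp_halfwidth=0.0,
        iso_noise_d18o=0.0, iso_noise_d13c=0.0,
    )
    profiles, truth = gen_fish_cohort(params)
    return params, profiles, truth


@pytest.fixture(scope="session")
def default_ca_cohort():
    """CA cohort under the default study conditions."""
    params = CohortParams.for_region("CA", n_fish=100, seed=3)
    profiles, truth = gen_fish_cohort(params)
    return params, profiles, truth
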