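import numpy as np
import pytest

from centipet import synthetic as syn
from centipet import thresholds as thr


@pytest.fixture
def dip_rate():
    """Rate function with a negative floor and an upward zero crossing at 10 CL."""
    return syn.RateFunction(
        "piecewise_linear", {"slope": 0.25, "zero_crossing": 10.0, "floor": -1.0}
    )


def make_longitudinal_pairs(rate_function, n=243, noise=2.5, seed=0):
    """Shared helper: simulate a cohort and return LongitudinalPair objects."""
    df = syn.gen_longitudinal_cohort(
        syn.LongitudinalSimParams(
            n_subjects=n,
            rate_function=rate_function,
            measurement_noise_sd=noise,
            seed=seed,
            baseline_means=(0.0, 60.0),
            baseline_sds=(8.0, 30.0),
        )
    )
    return thr.pairs_from_frame(df)


@pytest.fixture
def constant_tac_pair():
    """Constant target (2.0) and reference (1.0) TACs on a 10..90 min grid."""
    from centipet.quantify import TimeActivityCurve

    mid = np.arange(10.0, 95.0, 5.0)
    dur = np.full(mid.size, 5.0)
    return (
        TimeActivityCurve(mid, dur, np.full(mid.size, 2.0)),
        TimeActivityCurve(mid, dur, np.full(mid.size, 1.0)),
    )
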