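import numpy as np
import pytest

from uhrv import (
    CohortConfig,
    cohort_features,
    generate_cohort,
)
from uhrv.rr_io import Condition, NNExcerpt, RRSeries


def make_excerpt(intervals, nominal_scale=300, **kw) -> NNExcerpt:
    """NNExcerpt from a bare interval list, onsets cumulative."""
    iv = np.asarray(intervals, dtype=float)
    return NNExcerpt(iv, np.cumsum(iv), nominal_scale, **kw)


def make_series(intervals, labels=None, subject_id="S000", condition="rest"):
    iv = np.asarray(intervals, dtype=float)
    if labels is None:
        labels = ["N"] * len(iv)
    return RRSeries(
        subject_id=subject_id,
        condition=Condition(condition),
        beat_times=np.cumsum(iv),
        rr_intervals=iv,
        labels=np.asarray(labels, dtype=object),
    )


def tone_excerpt(amp_ms, freq_hz=0.25, mean_ms=1000.0, duration_s=300.0,
                 nominal_scale=300) -> NNExcerpt:
    """Noise-free sinusoidal tachogram evaluated at cumulative beat times."""
    t, ts, rr = 0.0, [], []
    while t < duration_s:
        v = mean_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
        t += v / 1000.0
        ts.append(t * 1000.0)
        rr.append(v)
    return NNExcerpt(np.array(rr), np.array(ts), nominal_scale)


@pytest.fixture(scope="session")
def small_cohort():
    """14-subject paired cohort with the default stress contrast."""
    return generate_cohort(CohortConfig(n_subjects=14, seed=5))


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    """Long feature table of the small cohort (central + consecutive 60 s)."""
    return cohort_features(
        small_cohort, scales=(300, 180, 120, 60), consecutive_scale=60
    )
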