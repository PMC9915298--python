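import numpy as np
import pandas as pd
import pytest

import sedcut as sc
from sedcut.metrics import EpochSeries, WORN


@pytest.fixture(scope="session")
def lab_cohort():
    """35-participant simulated laboratory cohort, reduced to activity means."""
    from sedcut.pipeline import run_lab_study
    return run_lab_study(n_participants=35, seed=11).summaries


@pytest.fixture(scope="session")
def small_freeliving():
    """One 2-day free-living recording with a miscalibrated sensor."""
    sensor = sc.SensorSpec(noise_sd_mg=4.0, offset_g=(0.03, -0.02, 0.01),
                           gain=(1.02, 0.99, 1.00))
    rec, events = sc.generate_freeliving_recording(2, sensor, seed=42)
    return rec, events, sensor


def make_recording(magnitudes, axis=2, rate=20.0,
                   start="2023-03-06 00:00:00"):
    """Recording whose samples point along one axis with given magnitudes."""
    mags = np.asarray(magnitudes, dtype=float)
    samples = np.zeros((mags.size, 3))
    samples[:, axis] = mags
    return sc.RawRecording(start_time=start, sample_rate_hz=rate,
                           samples=samples)


def make_epoch_series(enmo, mad=None, start="2023-03-06 00:00:00",
                      epoch_s=5.0, wear=None):
    enmo = np.asarray(enmo, dtype=float)
    mad = enmo.copy() if mad is None else np.asarray(mad, dtype=float)
    wear = np.full(enmo.size, WORN) if wear is None else np.asarray(wear)
    return EpochSeries(pd.Timestamp(start), epoch_s, enmo, mad, wear)
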