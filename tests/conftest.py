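import numpy as np
import pytest

from shadowfeat.characterize import CalibrationResult, FeatureCalibration
from shadowfeat.synthetic import default_accelerometer_spec, simulate_activity_stream
from shadowfeat.timeseries_io import SensorSeries


@pytest.fixture(scope="session")
def small_stream():
    """Short 7-activity tri-axial stream (300 samples per bout)."""
    return simulate_activity_stream(
        default_accelerometer_spec(segment_length=300), seed=0
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """Benchmark spec small enough for learner round-trips in tests."""
    return default_accelerometer_spec(segment_length=150)


def manual_calibration(feature_names, base_window, smoother="moving_average",
                       H_start=0.5, log_intercept=0.0):
    """Hand-built calibration for fixed-window shadow tests."""
    feats = {
        name: FeatureCalibration(
            feature=name, H_start=H_start, log_intercept=log_intercept,
            smoother=smoother, base_window=base_window,
            stationary=True, trend=False, random_walk=False,
            grade=1, intensity="Very weak",
        )
        for name in feature_names
    }
    return CalibrationResult(features=feats, calibration_span=0)


@pytest.fixture
def series_1to10():
    return SensorSeries(values=np.arange(1.0, 11.0)[:, None],
                        feature_names=["x"])
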