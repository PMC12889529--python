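import numpy as np
import pytest

from gridsep.binning import BinningSpec, Occupancy4D, TuningCurve4D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tuning_curve(rate4d, visits=None, spec=None, dt=0.01):
    """Wrap a 4D rate array into a TuningCurve4D for model tests.

    ``visits`` defaults to 100 everywhere (all bins high-occupancy).
    NaN rates get zero visits.
    """
    if spec is None:
        spec = BinningSpec()
    rate4d = np.asarray(rate4d, dtype=float)
    assert rate4d.shape == spec.shape
    if visits is None:
        visits = np.full(spec.shape, 100)
    visits = np.where(np.isfinite(rate4d), visits, 0)
    seconds = visits * dt
    spikes = np.where(np.isfinite(rate4d), np.nan_to_num(rate4d) * seconds, 0.0)
    return TuningCurve4D(
        rate=rate4d,
        occupancy=Occupancy4D(seconds=seconds, visits=visits),
        mask_high=visits >= spec.occupancy_threshold,
        spec=spec,
        spike_counts=spikes,
    )


@pytest.fixture
def small_spec():
    """Reduced 6x6x3x3 binning geometry for cheap model tests."""
    return BinningSpec(pos_bin=25.0, pos_range=75.0, vel_bin=50.0 / 3, vel_range=25.0)
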