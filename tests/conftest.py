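import numpy as np
import pytest

from dcehist import DynamicSeries, PhantomConfig, generate_cohort
from dcehist.pipeline import cohort_records


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort (16 TZ + 14 PZ patients) at default noise."""
    return generate_cohort(PhantomConfig(seed=2024))


@pytest.fixture(scope="session")
def default_records(default_cohort):
    """Feature records of the default cohort (2 ROIs x 2 diameters x 2 maps each)."""
    return cohort_records(default_cohort)


@pytest.fixture()
def uniform_series():
    """Tiny series where every voxel follows the same known raw trace."""

    def make(trace, spacing=(3.2, 1.0, 1.0), n_baseline=3, dt=10.0, shape=(2, 4, 4)):
        trace = np.asarray(trace, dtype=float)
        signal = np.broadcast_to(trace, shape + (trace.size,)).copy()
        times = np.arange(trace.size) * dt
        return DynamicSeries(
            signal=signal,
            frame_times_s=times,
            voxel_spacing_mm=spacing,
            n_baseline_frames=n_baseline,
        )

    return make
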