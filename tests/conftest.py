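import numpy as np
import pytest

from diffcs import AxisMeta, Peak, generate_fid


@pytest.fixture
def axes_small():
    """A small 2D grid: 64-point indirect (2.7 kHz), 64-point direct (1.5 kHz)."""
    return AxisMeta(64, 2700.0, 118.0, 70.94), AxisMeta(64, 1500.0, 8.2, 700.0)


@pytest.fixture
def axes_column():
    """Indirect axis at the full study size (256 points, 2.7 kHz)."""
    return AxisMeta(256, 2700.0)


@pytest.fixture
def three_peak_column(axes_column):
    """Noiseless 3-peak t1 column (heights 1.0 / 0.6 / 0.3)."""
    t = axes_column.times
    return sum(
        a * np.exp((2j * np.pi * f - 12.0) * t)
        for a, f in [(1.0, 300.0), (0.6, -500.0), (0.3, 900.0)]
    )


@pytest.fixture
def two_peak_fid(axes_small):
    ax1, ax2 = axes_small
    peaks = [Peak(300.0, 200.0, 12.0, 20.0, 1.0), Peak(-500.0, -300.0, 15.0, 25.0, 0.7)]
    return generate_fid(peaks, ax1, ax2)
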