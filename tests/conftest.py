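import numpy as np
import pandas as pd
import pytest

from chondrocolumn import (FrameSpec, PivotScenario, TissueParams,
                           generate_tissue, simulate_pivot_track)


def make_cells(points, clone_id="c1", axes=None, zone="proliferative"):
    """Build a minimal cell table from centroid (x, y) pairs."""
    points = np.asarray(points, dtype=float)
    if axes is None:
        axes = np.tile([0.0, 1.0], (len(points), 1))
    axes = np.asarray(axes, dtype=float)
    return pd.DataFrame({
        "cell_id": [f"{clone_id}_c{i}" for i in range(len(points))],
        "clone_id": clone_id,
        "zone": zone,
        "t_h": 0.0,
        "x_um": points[:, 0],
        "y_um": points[:, 1],
        "minor_axis_dx": axes[:, 0],
        "minor_axis_dy": axes[:, 1],
    })


def axes_from_phi(phi_deg):
    """Minor-axis vectors at given angles (degrees) from the +y PD axis."""
    a = np.radians(np.asarray(phi_deg, dtype=float))
    return np.column_stack([np.sin(a), np.cos(a)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wild_type_track():
    return simulate_pivot_track(
        PivotScenario(final_pivot_deg=85.0, noise_sd_deg=0.0, seed=0))


@pytest.fixture
def small_tissue():
    return generate_tissue(TissueParams(n_clones=10, seed=7))


@pytest.fixture
def quiet_frame_spec():
    return FrameSpec(noise_sd=0.0, seed=0)
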