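import numpy as np
import pandas as pd
import pytest

from hemoflow.geometry import ChannelGeometry, FlowConfig
from hemoflow.flow import solve_rectangular_flow
from hemoflow.optics import OpticalConstants
from hemoflow.simulate import NoiseSpec, render_phase, render_transmission


@pytest.fixture(scope="session")
def geom():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def optics():
    return OpticalConstants()


@pytest.fixture(scope="session")
def default_field(geom):
    """Series flow solution for the single-inlet rate (0.06 mL/min)."""
    return solve_rectangular_flow(geom, 0.06, n_terms=101)


def make_placements(cells):
    """Placement table from (x, y, z_off, radius, chb) tuples."""
    optics = OpticalConstants()
    rows = []
    for i, (x, y, z, r, chb) in enumerate(cells):
        rows.append(
            {
                "frame": 0,
                "cell_id": i,
                "x_fov_um": x,
                "y_fov_um": y,
                "z_off_um": z,
                "radius_um": r,
                "chb_g_ml": chb,
                "kind": "rbc",
                "abs_per_um": optics.absorbance_per_um(chb),
                "delta_n": optics.delta_n(chb),
                "u_mm_s": 5.0,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def singlet_placement():
    """One in-focus RBC (r = 2.78 μm, cHB = 0.33 g/mL) mid-FOV."""
    return make_placements([(88.0, 66.0, 0.0, 2.78, 0.33)])


@pytest.fixture(scope="session")
def singlet_transmission(singlet_placement, geom, optics):
    return render_transmission(
        singlet_placement, optics, geom, n_frames=1, noise=NoiseSpec.none(), seed=0
    )


@pytest.fixture(scope="session")
def singlet_phase(singlet_placement, geom, optics):
    # 11 leading cell-free frames feed the median background downstream
    placed = singlet_placement.assign(frame=11)
    return render_phase(
        placed, optics, geom, n_frames=12, noise=NoiseSpec.none(), seed=0
    )
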