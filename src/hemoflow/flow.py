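"""Pressure-driven laminar flow in a rectangular microchannel.

The axial velocity of steady pressure-driven (Poiseuille) flow in a
rectangular duct of width w (x in [0, w]) and height h (z in [0, h]),
with no-slip walls, is the classical Fourier series

    u(x, z) = S * sum_{n odd} (1/n^3)
              * [1 - cosh(n pi (x - w/2) / h) / cosh(n pi w / (2 h))]
              * sin(n pi z / h),

where the sine expansion runs along the short dimension h and the
hyperbolic saturation along the long dimension w.  This orientation
converges rapidly for shallow channels (here h/w ~ 0.07).  The prefactor
S absorbs the pressure gradient and viscosity; the solver fixes it by
requiring the analytic cross-sectional flux of the series to equal the
imposed volumetric rate Q, so neither the pressure drop nor the viscosity
ever needs to be known.

Derived quantities used by the cell-counting estimators:

* ``section_boundary`` — the distance r_s from each side wall at which the
  mid-height velocity first reaches (1 - rel_deviation) of the maximum;
  the channel is split into two slow "side" regions of width r_s and one
  flat "center" region in between.
* ``section_mean_velocities`` — mean mid-height velocities of the center
  and side regions.
* ``capture_multiplicity`` — the expected number of consecutive frames,
  tau = l_FOV / (u * dt), in which one cell is imaged.
* ``focused_stream_width`` — width of a hydrodynamically focused sample
  stream, w_f = Q_i / (v_f * h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .geometry import ChannelGeometry, ML_PER_MIN_TO_UM3_PER_S

__all__ = [
    "VelocityField",
    "solve_rectangular_flow",
    "section_boundary",
    "section_mean_velocities",
    "capture_multiplicity",
    "focused_stream_width",
]


def _cosh_ratio(a: np.ndarray, b: float) -> np.ndarray:
    """cosh(a)/cosh(b) evaluated without overflow for 0 <= |a| <= b."""
    a = np.abs(a)
    return (np.exp(a - b) + np.exp(-a - b)) / (1.0 + np.exp(-2.0 * b))


@dataclass(frozen=True)
class VelocityField:
    """Series solution of duct flow, scaled to a volumetric rate.

    Velocities are in mm/s, coordinates in μm with x = 0 at the left wall
    and z = 0 at the channel floor.  ``scale`` is the series prefactor in
    mm/s; evaluation at arbitrary points goes through :meth:`velocity`.
    """

    geometry: ChannelGeometry
    q_ml_min: float
    n_terms: int
    scale: float  # series prefactor, mm/s
    u_max: float = field(init=False)

    def __post_init__(self) -> None:
        g = self.geometry
        object.__setattr__(
            self, "u_max", float(self.velocity(g.width / 2.0, g.height / 2.0))
        )

    @property
    def u_mean(self) -> float:
        """Cross-section mean velocity Q / (w h), mm/s."""
        g = self.geometry
        q_um3_s = self.q_ml_min * ML_PER_MIN_TO_UM3_PER_S
        return q_um3_s / (g.width * g.height) / 1000.0

    def velocity(self, x, z):
        """Axial velocity u(x, z) in mm/s; x, z in μm (broadcastable)."""
        g = self.geometry
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        w, h = g.width, g.height
        total = np.zeros(np.broadcast_shapes(x.shape, z.shape))
        for n in range(1, 2 * self.n_terms, 2):
            b = n * np.pi * w / (2.0 * h)
            term = (1.0 - _cosh_ratio(n * np.pi * (x - w / 2.0) / h, b)) * np.sin(
                n * np.pi * z / h
            )
            total += term / n**3
        # outside the duct (including on the walls) the velocity is zero
        inside = (x >= 0) & (x <= w) & (z >= 0) & (z <= h)
        return np.where(inside, self.scale * total, 0.0)

    def midheight_profile(self, x):
        """u(x, h/2) in mm/s for x in μm."""
        return self.velocity(x, self.geometry.height / 2.0)

    def grid(self, nx: int = 201, nz: int = 51):
        """Velocity sampled on a regular grid; returns (x, z, u[z, x])."""
        g = self.geometry
        x = np.linspace(0.0, g.width, nx)
        z = np.linspace(0.0, g.height, nz)
        return x, z, self.velocity(x[None, :], z[:, None])

    def flux_um3_s(self) -> float:
        """Analytic cross-sectional flux of the series, μm³/s."""
        return _series_flux(self.geometry, self.n_terms) * self.scale * 1000.0


def _series_flux(geom: ChannelGeometry, n_terms: int) -> float:
    """Flux of the unscaled series (prefactor 1 μm/s), μm³/s per unit scale.

    Uses the exact integrals  ∫ sin(nπz/h) dz = 2h/(nπ)  (odd n) and
    ∫ [1 - cosh/cosh] dx = w - (2h/(nπ)) tanh(nπw/(2h)).
    """
    w, h = geom.width, geom.height
    total = 0.0
    for n in range(1, 2 * n_terms, 2):
        k = n * np.pi / h
        total += (2.0 / (n * np.pi * n**3)) * h * (w - (2.0 / k) * np.tanh(k * w / 2.0))
    return total


def solve_rectangular_flow(
    geom: ChannelGeometry, q_ml_min: float, n_terms: int = 101
) -> VelocityField:
    """Solve duct flow for a volumetric rate ``q_ml_min`` (mL/min).

    ``n_terms`` counts the odd harmonics retained (n = 1, 3, ..., 2*n_terms-1).
    The returned field satisfies no-slip on all four walls and carries
    exactly the imposed flux (the scaling is analytic, not fitted).
    """
    if q_ml_min <= 0:
        raise ValueError("volumetric rate must be positive")
    if n_terms < 26:
        raise ValueError("need at least 26 odd harmonics (n up to 51)")
    q_um3_s = q_ml_min * ML_PER_MIN_TO_UM3_PER_S
    scale_um_s = q_um3_s / _series_flux(geom, n_terms)
    return VelocityField(
        geometry=geom, q_ml_min=q_ml_min, n_terms=n_terms, scale=scale_um_s / 1000.0
    )


def section_boundary(fld: VelocityField, rel_deviation: float = 0.025) -> float:
    """Side-region width r_s (μm) from the mid-height velocity profile.

    Returns the distance from each side wall at which u(x, h/2) first
    reaches (1 - rel_deviation) * u_max.  The mid-height profile rises
    monotonically from the wall, so the crossing exists and is unique.
    """
    if not (0.0 < rel_deviation < 1.0):
        raise ValueError("rel_deviation must lie strictly between 0 and 1")
    target = (1.0 - rel_deviation) * fld.u_max
    w = fld.geometry.width

    def g(x: float) -> float:
        return float(fld.midheight_profile(x)) - target

    # bracket: g(0) = -target < 0, g(w/2) = u_max - target > 0
    return float(brentq(g, 0.0, w / 2.0, xtol=1e-6))


def section_mean_velocities(fld: VelocityField, rs: float) -> tuple[float, float]:
    """Mean mid-height velocities (u_c, u_s) of center and side regions, mm/s.

    The center region spans x in [rs, w - rs]; the two side regions span
    [0, rs] and [w - rs, w].  Integration uses adaptive quadrature on the
    series profile.
    """
    w = fld.geometry.width
    if not (0.0 < rs < w / 2.0):
        raise ValueError("rs must lie strictly between 0 and w/2")

    def prof(x: float) -> float:
        return float(fld.midheight_profile(x))

    center, _ = quad(prof, rs, w - rs, limit=200)
    side, _ = quad(prof, 0.0, rs, limit=200)
    u_c = center / (w - 2.0 * rs)
    u_s = side / rs  # both sides are mirror images
    return u_c, u_s


def capture_multiplicity(l_fov_um: float, u_mm_s: float, dt_s: float) -> float:
    """Expected frame appearances tau = l_FOV / (u * dt) of one cell.

    Values above 1 mean a cell is imaged in several consecutive frames;
    values below 1 mean only that fraction of passing cells is imaged.
    """
    if l_fov_um <= 0 or u_mm_s <= 0 or dt_s <= 0:
        raise ValueError("FOV length, velocity and frame interval must be positive")
    return l_fov_um / (u_mm_s * 1000.0 * dt_s)


def focused_stream_width(qi_ml_min: float, v_f_mm_s: float, h_um: float) -> float:
    """Hydrodynamically focused stream width w_f = Q_i / (v_f * h), μm.

    ``qi_ml_min`` is the sample-inlet rate (mL/min), ``v_f_mm_s`` the mean
    velocity of the focused stream and ``h_um`` the channel height.
    """
    if qi_ml_min < 0:
        raise ValueError("sample rate must be non-negative")
    if v_f_mm_s <= 0 or h_um <= 0:
        raise ValueError("velocity and height must be positive")
    qi_um3_s = qi_ml_min * ML_PER_MIN_TO_UM3_PER_S
    return qi_um3_s / (v_f_mm_s * 1000.0 * h_um)
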