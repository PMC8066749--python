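"""Synthetic imaging of sphered RBC suspensions in the microchannel.

The generator produces ground-truthed transmission and phase frame stacks
so every downstream stage (background correction, segmentation, feature
extraction, filtering, photometry, counting) can be exercised without an
instrument.  It emulates:

* a population of isovolumetrically sphered RBCs (volume ~ N(90 fl, 13 fl),
  cHB ~ N(33 g/dL, 2.2 g/dL)) plus optional platelet / leukocyte / debris
  contaminants,
* advection through the channel by the laminar velocity field, either
  spread across the cell sheath (single-inlet mode, with a center-weighted
  lateral count profile whose mean/max ratio equals the distribution
  factor delta) or confined to a hydrodynamically focused stream,
* per-pixel transmission attenuation I = I0 * 10^(-eps c/M * chord) and
  phase retardation dPhi = (2 pi / lambda) dn * chord through the sphere
  chord at each pixel,
* defocus-dependent Gaussian blur (plus an optional diffraction ring) and
  additive read / shot sensor noise.

Cells are rendered only while their center lies inside the camera FOV;
the ground-truth table records every cell and every per-frame placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .flow import VelocityField
from .geometry import ChannelGeometry, FlowConfig
from .optics import OpticalConstants

__all__ = [
    "PopulationParams",
    "DefocusSpec",
    "NoiseSpec",
    "FrameStack",
    "sample_population",
    "simulate_passage",
    "render_transmission",
    "render_phase",
    "write_stack",
    "read_stack",
]

#: area filter used for counting is 9.5 μm²; its equivalent radius
_PLATELET_RADIUS_CAP = float(np.sqrt(9.5 / np.pi))  # ~1.74 μm


@dataclass(frozen=True)
class PopulationParams:
    """Distribution spec for :func:`sample_population`.

    RBC volumes and hemoglobin concentrations are normal with the stated
    mean/SD (clipped to physical ranges); radii follow by sphere
    inversion r = (3V / 4 pi)^(1/3).  ``z_sd_um`` is the SD of the
    vertical offset from mid-height, emulating imperfect vertical
    focusing; it is the main knob stressing the focus-sensitive quality
    filters.
    """

    mcv_fl: float = 90.0
    volume_sd_fl: float = 13.0
    chcm_g_dl: float = 33.0
    chb_sd_g_dl: float = 2.2
    z_sd_um: float = 1.2
    platelet_fraction: float = 0.0
    leukocyte_fraction: float = 0.0
    debris_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_sd_fl < 0 or self.chb_sd_g_dl < 0 or self.z_sd_um < 0:
            raise ValueError("standard deviations must be non-negative")
        fracs = (self.platelet_fraction, self.leukocyte_fraction, self.debris_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("contaminant fractions must be >= 0 and sum to <= 1")


@dataclass(frozen=True)
class DefocusSpec:
    """Defocus blur model.

    A cell at vertical offset |z| beyond the depth of focus is blurred
    with a Gaussian of width sigma = sigma_um_per_dof * (|z|/DOF - 1)
    (in μm, converted to pixels at render time), optionally ringed with a
    single bright diffraction ring of the given amplitude at radius
    r + ring_k * |z|.
    """

    sigma_um_per_dof: float = 0.8
    ring_amplitude: float = 0.0
    ring_k: float = 0.3
    ring_width_um: float = 0.5

    def sigma_um(self, z_off_um: float, dof_um: float) -> float:
        return self.sigma_um_per_dof * max(0.0, abs(z_off_um) / dof_um - 1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise: additive read noise plus signal-dependent shot term.

    Transmission: std = sqrt(read_sigma^2 + shot_gain * I) counts.
    Phase: additive Gaussian of ``phase_sigma_rad`` radians.
    """

    read_sigma: float = 60.0
    shot_gain: float = 1.0
    phase_sigma_rad: float = 0.02

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(read_sigma=0.0, shot_gain=0.0, phase_sigma_rad=0.0)


@dataclass
class FrameStack:
    """An ordered stack of 2D frames plus acquisition metadata.

    ``frames`` has shape (n_frames, ny, nx); rows run along the flow
    direction, columns across it.  ``background`` is a cell-free
    reference frame of the same shape (transmission) or None (phase,
    where the leading frames of the stack serve as reference).
    """

    frames: np.ndarray
    modality: str  # "transmission" | "phase"
    pixel_size_um: float
    timestamps_s: np.ndarray
    background: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) array")
        if self.background is not None and self.background.shape != self.frames.shape[1:]:
            raise ValueError("background shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _radius_from_volume_fl(volume_fl: np.ndarray) -> np.ndarray:
    # 1 fl = 1 μm³
    return (3.0 * volume_fl / (4.0 * np.pi)) ** (1.0 / 3.0)


def sample_population(
    n: int,
    params: PopulationParams | None = None,
    seed: int | np.random.Generator | None = None,
    duration_s: float = 10.0,
    lead_s: float = 0.0,
) -> pd.DataFrame:
    """Draw a ground-truth cell population.

    Returns a DataFrame with one row per cell: ``cell_id``, ``kind``
    (rbc/platelet/leukocyte/debris), ``radius_um``, ``volume_fl``,
    ``chb_g_ml``, ``z_off_um`` (vertical offset from mid-height),
    ``entry_s`` (time the cell center crosses the upstream FOV edge,
    uniform on [lead_s, duration_s]), plus the rendering contrasts
    ``abs_per_um`` (decadic absorbance per μm of path at 425 nm) and
    ``delta_n`` (refractive contrast at 530 nm).  Lateral positions are
    assigned later by :func:`simulate_passage` according to the fluidic
    mode.  Reproducible for a fixed seed.
    """
    params = params or PopulationParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n < 0:
        raise ValueError("n must be non-negative")
    optics = OpticalConstants()

    kinds = rng.choice(
        ["platelet", "leukocyte", "debris", "rbc"],
        size=n,
        p=[
            params.platelet_fraction,
            params.leukocyte_fraction,
            params.debris_fraction,
            1.0 - params.platelet_fraction - params.leukocyte_fraction - params.debris_fraction,
        ],
    )
    volume = np.clip(rng.normal(params.mcv_fl, params.volume_sd_fl, n), 20.0, 250.0)
    chb = np.clip(rng.normal(params.chcm_g_dl / 100.0, params.chb_sd_g_dl / 100.0, n), 0.05, 0.60)
    radius = _radius_from_volume_fl(volume)

    is_plt = kinds == "platelet"
    is_wbc = kinds == "leukocyte"
    is_deb = kinds == "debris"
    # platelets strictly below the counting filter's equivalent radius
    radius[is_plt] = np.clip(
        rng.normal(1.2, 0.25, is_plt.sum()), 0.5, 0.95 * _PLATELET_RADIUS_CAP
    )
    radius[is_wbc] = np.clip(rng.normal(4.5, 0.5, is_wbc.sum()), 3.6, 6.5)
    radius[is_deb] = np.clip(rng.normal(1.0, 0.5, is_deb.sum()), 0.3, 2.5)
    non_rbc = is_plt | is_wbc | is_deb
    chb[non_rbc] = 0.0
    volume = 4.0 / 3.0 * np.pi * radius**3

    abs_per_um = optics.absorbance_per_um(chb)
    delta_n = optics.delta_n(chb)
    # contaminants carry no hemoglobin but still scatter/retard weakly
    abs_per_um[is_plt] = 0.10
    abs_per_um[is_wbc] = 0.06
    abs_per_um[is_deb] = 0.15
    delta_n[is_plt] = 0.030
    delta_n[is_wbc] = 0.022
    delta_n[is_deb] = 0.015

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "kind": kinds,
            "radius_um": radius,
            "volume_fl": volume,
            "chb_g_ml": chb,
            "z_off_um": rng.normal(0.0, params.z_sd_um, n),
            "entry_s": rng.uniform(lead_s, duration_s, n),
            "abs_per_um": abs_per_um,
            "delta_n": delta_n,
        }
    )


def _laminar_lateral_sampler(
    field_: VelocityField,
    sheath_width_um: float,
    delta: float,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Sample lateral positions for single-inlet flow.

    The per-frame *count* profile across the sheath is the parabola-capped
    g(xi) = 1 - a xi^2 with a = 3 (1 - delta), whose mean/max ratio equals
    the distribution factor delta.  Since a snapshot count at x is
    proportional to arrival flux / velocity, arrivals are drawn from a
    density proportional to g(x) * u(x, h/2), by rejection sampling.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError("delta must lie in (0, 1]")
    a = 3.0 * (1.0 - delta)
    w = field_.geometry.width
    lo = (w - sheath_width_um) / 2.0
    hi = (w + sheath_width_um) / 2.0
    grid = np.linspace(lo, hi, 4001)
    u_grid = np.asarray(field_.midheight_profile(grid)) / field_.u_max
    out = np.empty(n)
    got = 0
    while got < n:
        m = max(2 * (n - got), 256)
        x = rng.uniform(lo, hi, m)
        xi = 2.0 * (x - w / 2.0) / sheath_width_um
        g = 1.0 - a * xi**2
        dens = g * np.interp(x, grid, u_grid)
        keep = x[rng.uniform(0.0, 1.0, m) < np.clip(dens, 0.0, 1.0)]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def simulate_passage(
    pop: pd.DataFrame,
    field_: VelocityField,
    geom: ChannelGeometry,
    flow_cfg: FlowConfig,
    mode: str = "laminar",
    wf_um: float | None = None,
    sheath_width_um: float = 1801.0,
    delta: float = 0.79,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Advect a population through the channel and place it into frames.

    ``mode="laminar"`` spreads cells over ``sheath_width_um`` (centered)
    with the delta-weighted lateral profile; ``mode="focused"`` confines
    them to within ``wf_um`` of the centerline (required in that mode).
    Each cell advances by u(x, z) * dt per frame and is emitted into a
    frame whenever its center lies inside the FOV.

    Returns the placement table with one row per (frame, cell) pair:
    ``frame``, ``cell_id``, ``x_fov_um`` (across flow), ``y_fov_um``
    (along flow), ``z_off_um``, ``radius_um``, ``chb_g_ml``, ``kind``,
    ``abs_per_um``, ``delta_n``, ``u_mm_s``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(pop)
    if mode == "laminar":
        x = _laminar_lateral_sampler(field_, sheath_width_um, delta, rng, n)
    elif mode == "focused":
        if wf_um is None:
            raise ValueError("focused mode requires the stream width wf_um")
        x = rng.uniform(
            (geom.width - wf_um) / 2.0, (geom.width + wf_um) / 2.0, n
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    z_abs = geom.height / 2.0 + pop["z_off_um"].to_numpy()
    u_mm_s = np.asarray(field_.velocity(x, np.clip(z_abs, 0.0, geom.height)))
    u_um_s = u_mm_s * 1000.0
    dt = flow_cfg.dt
    fov_lo = (geom.width - geom.fov_width) / 2.0
    in_fov_x = (x >= fov_lo) & (x <= fov_lo + geom.fov_width)

    entry = pop["entry_s"].to_numpy()
    sel = np.nonzero(in_fov_x & (u_um_s > 0))[0]
    # frames with 0 <= y(t_k) < l_FOV, y(t) = (t - entry) * u
    k0 = np.maximum(np.ceil(entry[sel] / dt).astype(np.int64), 0)
    k1 = np.minimum(
        np.floor((entry[sel] + geom.fov_length / u_um_s[sel]) / dt).astype(np.int64),
        flow_cfg.n_frames - 1,
    )
    counts = np.maximum(k1 - k0 + 1, 0)
    have = counts > 0
    sel, k0, counts = sel[have], k0[have], counts[have]
    if counts.sum() > 0:
        idx = np.repeat(sel, counts)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        within = np.arange(counts.sum()) - np.repeat(starts, counts)
        frames = np.repeat(k0, counts) + within
        y = (frames * dt - entry[idx]) * u_um_s[idx]
        ok = (y >= 0.0) & (y < geom.fov_length)
        idx, frames, y = idx[ok], frames[ok], y[ok]
        placed = pd.DataFrame(
            {
                "frame": frames.astype(int),
                "cell_id": pop["cell_id"].to_numpy()[idx],
                "x_fov_um": x[idx] - fov_lo,
                "y_fov_um": y,
            }
        )
        for col in ("z_off_um", "radius_um", "chb_g_ml", "kind", "abs_per_um", "delta_n"):
            placed[col] = pop[col].to_numpy()[idx]
        placed["u_mm_s"] = u_mm_s[idx]
    else:
        placed = pd.DataFrame(
            columns=[
                "frame", "cell_id", "x_fov_um", "y_fov_um", "z_off_um",
                "radius_um", "chb_g_ml", "kind", "abs_per_um", "delta_n", "u_mm_s",
            ]
        )
    return placed.sort_values(["frame", "cell_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# rendering


def _frame_shape(geom: ChannelGeometry, pixel_size_um: float) -> tuple[int, int]:
    ny = int(round(geom.fov_length / pixel_size_um))
    nx = int(round(geom.fov_width / pixel_size_um))
    return ny, nx


def _chord_patch(
    radius_um: float,
    x_um: float,
    y_um: float,
    pixel_size_um: float,
    shape: tuple[int, int],
    pad_px: int = 0,
    oversample: int = 1,
):
    """Sphere chord length (μm) sampled around a cell.

    With ``oversample`` > 1 the chord is sampled at oversample² points
    per pixel (so nonlinear per-point transforms can be averaged over
    the pixel area, the way a physical sensor integrates intensity).
    Returns (patch, (row_slice, col_slice)) restricted to the frame, or
    None if the cell does not intersect it; the patch has shape
    (rows * oversample, cols * oversample).
    """
    ny, nx = shape
    r_px = radius_um / pixel_size_um
    cy = y_um / pixel_size_um - 0.5
    cx = x_um / pixel_size_um - 0.5
    ext = int(np.ceil(r_px)) + 1 + pad_px
    r0, r1 = int(np.floor(cy)) - ext, int(np.ceil(cy)) + ext + 1
    c0, c1 = int(np.floor(cx)) - ext, int(np.ceil(cx)) + ext + 1
    r0, r1 = max(r0, 0), min(r1, ny)
    c0, c1 = max(c0, 0), min(c1, nx)
    if r0 >= r1 or c0 >= c1:
        return None
    os_ = max(int(oversample), 1)
    sub = (np.arange(os_) + 0.5) / os_ - 0.5
    rr = ((np.arange(r0, r1)[:, None] + sub[None, :]).ravel() - cy) * pixel_size_um
    cc = ((np.arange(c0, c1)[:, None] + sub[None, :]).ravel() - cx) * pixel_size_um
    rho2 = rr[:, None] ** 2 + cc[None, :] ** 2
    chord = 2.0 * np.sqrt(np.maximum(radius_um**2 - rho2, 0.0))
    return chord, (slice(r0, r1), slice(c0, c1))


def _pixel_average(fine: np.ndarray, oversample: int) -> np.ndarray:
    """Average an oversampled patch down to pixel resolution."""
    if oversample <= 1:
        return fine
    h, w = fine.shape[0] // oversample, fine.shape[1] // oversample
    return fine.reshape(h, oversample, w, oversample).mean(axis=(1, 3))


def _gaussian_blur(patch: np.ndarray, sigma_px: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    if sigma_px <= 0:
        return patch
    return gaussian_filter(patch, sigma_px, mode="constant", cval=0.0)


def _ring_profile(
    radius_um, z_off_um, spec: DefocusSpec, x_um, y_um, pixel_size_um, shape
):
    """Optional single bright diffraction ring around a defocused cell."""
    if spec.ring_amplitude <= 0 or z_off_um == 0:
        return None
    r_ring = radius_um + spec.ring_k * abs(z_off_um)
    ext_um = r_ring + 3 * spec.ring_width_um
    got = _chord_patch(ext_um, x_um, y_um, pixel_size_um, shape)
    if got is None:
        return None
    chord, sl = got
    rho = np.sqrt(np.maximum(ext_um**2 - (chord / 2.0) ** 2, 0.0))
    ring = spec.ring_amplitude * np.exp(
        -0.5 * ((rho - r_ring) / spec.ring_width_um) ** 2
    )
    return ring, sl


def render_transmission(
    placements: pd.DataFrame,
    optics: OpticalConstants | None = None,
    geom: ChannelGeometry | None = None,
    flow_cfg: FlowConfig | None = None,
    n_frames: int | None = None,
    pixel_size_um: float = 0.344,
    i0: float = 30000.0,
    noise: NoiseSpec | None = None,
    defocus: DefocusSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> FrameStack:
    """Render the bright-field transmission stack (16-bit counts).

    Each cell multiplies the local transmittance by
    10^(-abs_per_um * chord); overlapping cells therefore compose
    multiplicatively.  Cells beyond the transmission depth of focus are
    blurred (and optionally ringed) per ``defocus``.  A cell-free
    background frame at level ``i0`` is attached for background
    correction and I0 estimation downstream.
    """
    optics = optics or OpticalConstants()
    geom = geom or ChannelGeometry()
    noise = noise if noise is not None else NoiseSpec()
    defocus = defocus or DefocusSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_frames is None:
        if flow_cfg is not None:
            n_frames = flow_cfg.n_frames
        else:
            n_frames = int(placements["frame"].max()) + 1 if len(placements) else 0
    shape = _frame_shape(geom, pixel_size_um)
    dt = flow_cfg.dt if flow_cfg is not None else 0.01

    frames = np.empty((n_frames,) + shape, dtype=np.uint16)
    trans = np.ones(shape)
    by_frame = placements.groupby("frame") if len(placements) else {}
    groups = dict(list(by_frame)) if len(placements) else {}
    for k in range(n_frames):
        trans[:] = 1.0
        if k in groups:
            for row in groups[k].itertuples():
                got = _chord_patch(
                    row.radius_um, row.x_fov_um, row.y_fov_um, pixel_size_um, shape,
                    pad_px=6,
                )
                if got is None:
                    continue
                chord, sl = got
                t_patch = 10.0 ** (-row.abs_per_um * chord)
                sigma_um = defocus.sigma_um(row.z_off_um, optics.dof_trans_um)
                if sigma_um > 0:
                    t_patch = 1.0 + _gaussian_blur(t_patch - 1.0, sigma_um / pixel_size_um)
                ring = _ring_profile(
                    row.radius_um, row.z_off_um, defocus,
                    row.x_fov_um, row.y_fov_um, pixel_size_um, shape,
                )
                trans[sl] *= t_patch
                if ring is not None:
                    rpatch, rsl = ring
                    trans[rsl] = trans[rsl] * (1.0 + rpatch)
        img = i0 * trans
        if noise.read_sigma > 0 or noise.shot_gain > 0:
            std = np.sqrt(noise.read_sigma**2 + noise.shot_gain * img)
            img = img + rng.normal(0.0, 1.0, shape) * std
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    bg = i0 * np.ones(shape)
    if noise.read_sigma > 0 or noise.shot_gain > 0:
        bg = bg + rng.normal(0.0, 1.0, shape) * np.sqrt(
            noise.read_sigma**2 + noise.shot_gain * bg
        )
    background = np.clip(np.round(bg), 0, 65535).astype(np.uint16)
    return FrameStack(
        frames=frames,
        modality="transmission",
        pixel_size_um=pixel_size_um,
        timestamps_s=np.arange(n_frames) * dt,
        background=background,
        meta={"i0": i0},
    )


def render_phase(
    placements: pd.DataFrame,
    optics: OpticalConstants | None = None,
    geom: ChannelGeometry | None = None,
    flow_cfg: FlowConfig | None = None,
    n_frames: int | None = None,
    pixel_size_um: float = 0.344,
    noise: NoiseSpec | None = None,
    defocus: DefocusSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> FrameStack:
    """Render the quantitative-phase stack (float32 radians).

    Phase shifts of overlapping cells add.  When the placement table was
    generated with a lead-in (no entries in the first frames), those
    frames are cell-free and serve as the median background reference
    downstream.
    """
    optics = optics or OpticalConstants()
    geom = geom or ChannelGeometry()
    noise = noise if noise is not None else NoiseSpec()
    defocus = defocus or DefocusSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_frames is None:
        if flow_cfg is not None:
            n_frames = flow_cfg.n_frames
        else:
            n_frames = int(placements["frame"].max()) + 1 if len(placements) else 0
    shape = _frame_shape(geom, pixel_size_um)
    dt = flow_cfg.dt if flow_cfg is not None else 0.01
    k_phase = 2.0 * np.pi / optics.lambda_phase_um

    frames = np.zeros((n_frames,) + shape, dtype=np.float32)
    groups = dict(list(placements.groupby("frame"))) if len(placements) else {}
    for k in range(n_frames):
        acc = np.zeros(shape)
        if k in groups:
            for row in groups[k].itertuples():
                got = _chord_patch(
                    row.radius_um, row.x_fov_um, row.y_fov_um, pixel_size_um, shape,
                    pad_px=6,
                )
                if got is None:
                    continue
                chord, sl = got
                phi = k_phase * row.delta_n * chord
                sigma_um = defocus.sigma_um(row.z_off_um, optics.dof_phase_um)
                if sigma_um > 0:
                    phi = _gaussian_blur(phi, sigma_um / pixel_size_um)
                acc[sl] += phi
        if noise.phase_sigma_rad > 0:
            acc = acc + rng.normal(0.0, noise.phase_sigma_rad, shape)
        frames[k] = acc.astype(np.float32)
    return FrameStack(
        frames=frames,
        modality="phase",
        pixel_size_um=pixel_size_um,
        timestamps_s=np.arange(n_frames) * dt,
        background=None,
    )


def write_stack(
    stack: FrameStack,
    tiff_path,
    ground_truth: pd.DataFrame | None = None,
    ground_truth_path=None,
) -> None:
    """Write a multi-page TIFF (plus optional ground-truth CSV).

    Integer (transmission) stacks round-trip bit-exactly; phase stacks
    are stored as 32-bit float pages.
    """
    try:
        tifffile.imwrite(str(tiff_path), stack.frames, photometric="minisblack",
                         metadata={
                             "modality": stack.modality,
                             "pixel_size_um": stack.pixel_size_um,
                         })
        if stack.background is not None:
            bgp = str(tiff_path).replace(".tif", "_background.tif")
            tifffile.imwrite(bgp, stack.background, photometric="minisblack")
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing stack to {tiff_path}: {exc}") from exc
    if ground_truth is not None:
        if ground_truth_path is None:
            ground_truth_path = str(tiff_path).replace(".tif", "_truth.csv")
        ground_truth.to_csv(ground_truth_path, index=False)


def read_stack(tiff_path, modality: str, pixel_size_um: float, dt_s: float = 0.01) -> FrameStack:
    """Read a stack previously written by :func:`write_stack`."""
    frames = tifffile.imread(str(tiff_path))
    if frames.ndim == 2:
        frames = frames[None]
    import os

    bgp = str(tiff_path).replace(".tif", "_background.tif")
    background = tifffile.imread(bgp) if os.path.exists(bgp) else None
    return FrameStack(
        frames=frames,
        modality=modality,
        pixel_size_um=pixel_size_um,
        timestamps_s=np.arange(frames.shape[0]) * dt_s,
        background=background,
    )
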