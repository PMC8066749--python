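"""End-to-end runs: simulate → process → analyze → count.

The helpers here wire the synthetic imager, the image pipeline and the
estimators together for the two fluidic modes, and are what the CLI,
the test suite and the acceptance script drive.  They are written so a
run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import imaging
from .analytes import analyte_table, compute_indices, IndexResult
from .counting import (
    CountingFactors,
    ConcentrationResult,
    concentration_focused,
    concentration_laminar,
    expected_laminar_count,
    laminar_factors,
    observed_volume_laminar,
    per_frame_counts,
    stable_window,
)
from .flow import VelocityField, capture_multiplicity, solve_rectangular_flow
from .geometry import ChannelGeometry, FlowConfig
from .optics import OpticalConstants
from .simulate import (
    DefocusSpec,
    FrameStack,
    NoiseSpec,
    PopulationParams,
    render_phase,
    render_transmission,
    sample_population,
    simulate_passage,
)

__all__ = [
    "process_transmission_stack",
    "process_phase_stack",
    "CountingRun",
    "simulate_laminar_counting",
    "simulate_focused_counting",
    "count_run",
    "AnalyteRun",
    "simulate_analyte_run",
    "analyze_run",
    "focused_stream_velocity",
]


# ---------------------------------------------------------------------------
# stack processing (the fixed §-order: background -> mask -> contour -> table)


def process_transmission_stack(
    stack: FrameStack,
    threshold_k: float = 4.0,
    threshold_floor_frac: float = 0.02,
) -> tuple[pd.DataFrame, dict]:
    """Background-correct, segment and featurize a transmission stack.

    The fixed segmentation threshold is derived once from the cell-free
    background frame (median minus max(k*SD, floor)) and applied to every
    corrected frame.  Returns the concatenated feature table (one row per
    object per frame, ``image_id`` = frame index) and the stage metadata
    (threshold, I0 estimate).
    """
    if stack.background is None:
        raise ValueError("transmission processing requires a background frame")
    i0 = float(np.median(stack.background))
    corrected = imaging.correct_background_transmission(stack.frames, stack.background)
    offset = float(np.median(np.asarray(stack.background, dtype=float)))
    # noise of a corrected frame (frame + background noise combined),
    # estimated robustly so sparse cells do not inflate it
    sigma = 1.4826 * float(np.median(np.abs(corrected[0] - np.median(corrected[0]))))
    threshold = offset - max(threshold_k * sigma, threshold_floor_frac * i0)
    tables = []
    for k in range(stack.n_frames):
        labels = imaging.segment(corrected[k], threshold, direction="below")
        tab = imaging.extract_features(
            labels,
            transmission=corrected[k],
            raw_transmission=stack.frames[k],
            pixel_size_um=stack.pixel_size_um,
            i0=i0,
            image_id=k,
        )
        tables.append(tab)
    nonempty = [t for t in tables if not t.empty]
    table = pd.concat(nonempty, ignore_index=True) if nonempty else tables[-1]
    return table, {"threshold": threshold, "i0": i0, "offset": offset}


def process_phase_stack(
    stack: FrameStack,
    n_ref: int = 11,
    threshold_k: float = 4.0,
    threshold_floor_rad: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Median-background-correct, segment and featurize a phase stack.

    The reference is the pixel-wise median of the first ``n_ref`` frames;
    the fixed threshold sits max(k*SD, floor) radians above the corrected
    background.  The first ``n_ref`` frames are processed too (they are
    cell-free by construction in synthetic runs).
    """
    corrected = imaging.correct_background_phase(stack.frames, n_ref=n_ref)
    threshold = imaging.auto_threshold(
        corrected[:n_ref], k=threshold_k, direction="above", floor=threshold_floor_rad
    )
    tables = []
    for k in range(stack.n_frames):
        labels = imaging.segment(corrected[k], threshold, direction="above")
        tab = imaging.extract_features(
            labels,
            phase=corrected[k],
            pixel_size_um=stack.pixel_size_um,
            image_id=k,
        )
        tables.append(tab)
    nonempty = [t for t in tables if not t.empty]
    table = pd.concat(nonempty, ignore_index=True) if nonempty else tables[-1]
    return table, {"threshold": threshold, "n_ref": n_ref}


# ---------------------------------------------------------------------------
# counting runs


def focused_stream_velocity(field_: VelocityField, wf_um: float | None = None) -> float:
    """Mean velocity of the (focused) center stream, mm/s.

    Averages the full-depth velocity profile over the stream width (the
    whole channel center when ``wf_um`` is None), i.e. the z-averaged
    velocity the sample stream actually experiences near the centerline.
    """
    g = field_.geometry
    half = (wf_um / 2.0) if wf_um else g.width / 2.0 - 2.0 * g.height
    x = np.linspace(g.width / 2.0 - half, g.width / 2.0 + half, 101)
    z = np.linspace(0.0, g.height, 101)
    u = np.asarray(field_.velocity(x[None, :], z[:, None]))
    return float(np.trapezoid(np.trapezoid(u, z, axis=0), x) / (g.height * 2.0 * half))


@dataclass
class CountingRun:
    """A simulated counting experiment with its ground truth."""

    stack: FrameStack
    placements: pd.DataFrame
    population: pd.DataFrame
    truth_cells_per_ul: float
    mode: str
    factors: CountingFactors | None
    flow_cfg: FlowConfig
    geom: ChannelGeometry
    extra: dict


def _entry_pad_s(flow_cfg: FlowConfig) -> float:
    # longer than any FOV transit so per-frame counts are stationary
    return 20.0 * flow_cfg.dt


def simulate_laminar_counting(
    truth_cells_per_ul: float,
    geom: ChannelGeometry | None = None,
    flow_cfg: FlowConfig | None = None,
    field_: VelocityField | None = None,
    params: PopulationParams | None = None,
    sheath_width_um: float = 1801.0,
    delta: float = 0.79,
    pixel_size_um: float = 0.688,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
) -> CountingRun:
    """Simulate a single-inlet counting run at a known concentration.

    The generator derives the FOV arrival rate from the target
    whole-blood concentration by inverting the laminar estimator with
    the module's own flow factors, so estimator and generator share one
    volume convention (see docs/methods.md); cells are then placed,
    advected and rendered physically.
    """
    geom = geom or ChannelGeometry()
    flow_cfg = flow_cfg or FlowConfig()
    field_ = field_ or solve_rectangular_flow(geom, flow_cfg.q_total)
    params = params or PopulationParams()
    rng = np.random.default_rng(seed)

    factors = laminar_factors(field_, geom, flow_cfg, sheath_width_um, delta)
    v_ul = observed_volume_laminar(factors, flow_cfg.n_frames)
    n_expected = expected_laminar_count(truth_cells_per_ul, factors, v_ul)

    # expected appearances per cell placed across the sheath:
    # placement density p(x) ∝ g(x) u(x); appearances lFOV/(u dt) inside FOV
    w = geom.width
    a = 3.0 * (1.0 - delta)
    x = np.linspace((w - sheath_width_um) / 2.0, (w + sheath_width_um) / 2.0, 2001)
    xi = 2.0 * (x - w / 2.0) / sheath_width_um
    g = 1.0 - a * xi**2
    u = np.asarray(field_.midheight_profile(x)) * 1000.0  # μm/s
    fov_lo = (w - geom.fov_width) / 2.0
    in_fov = (x >= fov_lo) & (x <= fov_lo + geom.fov_width)
    norm = np.trapezoid(g * u, x)
    app_per_cell = np.trapezoid(
        (g * u * (geom.fov_length / (u * flow_cfg.dt)))[in_fov], x[in_fov]
    ) / norm

    pad = _entry_pad_s(flow_cfg)
    t_entry = flow_cfg.duration + pad
    n_place = n_expected * t_entry / (flow_cfg.duration * app_per_cell)
    n_cells = int(rng.poisson(n_place))

    pop = sample_population(n_cells, params, rng, duration_s=flow_cfg.duration, lead_s=0.0)
    pop["entry_s"] = rng.uniform(-pad, flow_cfg.duration, n_cells)
    placements = simulate_passage(
        pop, field_, geom, flow_cfg, mode="laminar",
        sheath_width_um=sheath_width_um, delta=delta, seed=rng,
    )
    stack = render_transmission(
        placements, geom=geom, flow_cfg=flow_cfg,
        pixel_size_um=pixel_size_um, noise=noise, seed=rng,
    )
    return CountingRun(
        stack=stack, placements=placements, population=pop,
        truth_cells_per_ul=truth_cells_per_ul, mode="laminar",
        factors=factors, flow_cfg=flow_cfg, geom=geom,
        extra={"observed_volume_ul": v_ul, "expected_count": n_expected},
    )


def simulate_focused_counting(
    truth_cells_per_ul: float,
    geom: ChannelGeometry | None = None,
    flow_cfg: FlowConfig | None = None,
    field_: VelocityField | None = None,
    params: PopulationParams | None = None,
    pixel_size_um: float = 0.688,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
) -> CountingRun:
    """Simulate a hydrodynamic-focusing counting run.

    Cells arrive at the physical rate (n/D) * Q_i, spread uniformly over
    the focused stream width w_f = Q_i / (v_f h) computed from the flow
    model, and ride the laminar profile; the focusing estimator is
    flux-consistent, so no further convention is needed.
    """
    geom = geom or ChannelGeometry()
    flow_cfg = flow_cfg or FlowConfig(
        q_sample=0.017, q_sheath=0.11, frame_rate=20.0, n_frames=400,
        exposure_us=11.0, dilution=150.0,
    )
    field_ = field_ or solve_rectangular_flow(geom, flow_cfg.q_total)
    params = params or PopulationParams()
    rng = np.random.default_rng(seed)

    from .flow import focused_stream_width

    v_f = focused_stream_velocity(field_)
    wf = focused_stream_width(flow_cfg.q_sample, v_f, geom.height)
    qi_ul_s = flow_cfg.q_sample * 1000.0 / 60.0
    rate = truth_cells_per_ul / flow_cfg.dilution * qi_ul_s  # cells/s through stream

    pad = _entry_pad_s(flow_cfg)
    t_entry = flow_cfg.duration + pad
    n_cells = int(rng.poisson(rate * t_entry))
    pop = sample_population(n_cells, params, rng, duration_s=flow_cfg.duration)
    pop["entry_s"] = rng.uniform(-pad, flow_cfg.duration, n_cells)
    placements = simulate_passage(
        pop, field_, geom, flow_cfg, mode="focused", wf_um=wf, seed=rng
    )
    stack = render_transmission(
        placements, geom=geom, flow_cfg=flow_cfg,
        pixel_size_um=pixel_size_um, noise=noise, seed=rng,
    )
    # tau_c of the stream from the same flow model the generator used
    u_stream_mid = float(
        np.mean(np.asarray(field_.midheight_profile(
            np.linspace(geom.width / 2.0 - wf / 2.0, geom.width / 2.0 + wf / 2.0, 201)
        )))
    )
    tau_c = capture_multiplicity(geom.fov_length, u_stream_mid, flow_cfg.dt)
    return CountingRun(
        stack=stack, placements=placements, population=pop,
        truth_cells_per_ul=truth_cells_per_ul, mode="focused",
        factors=None, flow_cfg=flow_cfg, geom=geom,
        extra={"wf_um": wf, "tau_c": tau_c, "v_f_mm_s": v_f},
    )


def count_run(
    run: CountingRun,
    window_s: float | None = None,
    cv_threshold: float = 0.25,
    threshold_floor_frac: float = 0.25,
) -> ConcentrationResult:
    """Process a counting run's stack and apply the mode's estimator.

    Uses the counting filter (area cut + cluster multiplicity), selects
    the earliest stable window of per-frame counts (default length: the
    whole recording when shorter than the canonical 10 s laminar / 20 s
    focused windows) and converts the window count into cells/μL.

    Counting segments at a deep fixed threshold (default 25% of I0
    attenuation): RBC cores are essentially opaque at 425 nm, so the
    deep threshold keeps the geometric footprint of every cell —
    including strongly defocused ones — while ignoring shallow defocus
    halos that would otherwise bridge neighbouring cells into spurious
    clusters.  (Photometric runs use a shallow threshold instead; see
    :func:`process_transmission_stack`.)
    """
    table, _meta = process_transmission_stack(
        run.stack, threshold_floor_frac=threshold_floor_frac
    )
    filtered = imaging.counting_filter(table)
    counts = per_frame_counts(filtered, run.flow_cfg.n_frames)
    canonical_s = 10.0 if run.mode == "laminar" else 20.0
    if window_s is None:
        window_s = min(canonical_s, run.flow_cfg.duration)
    window = max(2, int(round(window_s / run.flow_cfg.dt)))
    window = min(window, run.flow_cfg.n_frames)
    span = stable_window(counts, window, cv_threshold)
    if span is None:
        # fall back to the full recording rather than fail the run
        span = (0, run.flow_cfg.n_frames)
    n_window = float(counts[span[0] : span[1]].sum())
    n_frames_window = span[1] - span[0]

    if run.mode == "laminar":
        v_ul = observed_volume_laminar(run.factors, n_frames_window)
        return concentration_laminar(n_window, run.factors, v_ul)
    return concentration_focused(
        n_window,
        run.flow_cfg.dilution,
        run.extra["wf_um"],
        run.geom.fov_width,
        run.extra["tau_c"],
        run.flow_cfg.q_sample,
        n_frames_window,
        run.flow_cfg.dt,
    )


# ---------------------------------------------------------------------------
# analyte runs (cellular HB + volume)


@dataclass
class AnalyteRun:
    """A simulated HB/volume experiment (both modalities)."""

    transmission: FrameStack
    phase: FrameStack
    placements: pd.DataFrame
    population: pd.DataFrame
    flow_cfg: FlowConfig
    geom: ChannelGeometry


def simulate_analyte_run(
    n_cells: int = 300,
    geom: ChannelGeometry | None = None,
    flow_cfg: FlowConfig | None = None,
    field_: VelocityField | None = None,
    params: PopulationParams | None = None,
    pixel_size_um: float = 0.344,
    noise: NoiseSpec | None = None,
    defocus: DefocusSpec | None = None,
    lead_frames: int = 11,
    seed: int | None = 0,
) -> AnalyteRun:
    """Simulate a dual-modality recording for HB/volume analysis.

    ``n_cells`` is the number of cells crossing the FOV strip; density is
    kept low (as in the cellular-HB experiments) so overlaps are rare.
    The first ``lead_frames`` frames are cell-free so the phase pipeline
    can take its median background from them.
    """
    geom = geom or ChannelGeometry()
    flow_cfg = flow_cfg or FlowConfig(n_frames=120)
    field_ = field_ or solve_rectangular_flow(geom, flow_cfg.q_total)
    params = params or PopulationParams()
    rng = np.random.default_rng(seed)

    lead_s = lead_frames * flow_cfg.dt
    pop = sample_population(
        n_cells, params, rng, duration_s=flow_cfg.duration, lead_s=lead_s
    )
    # confine to a stream narrower than the FOV so every cell is imaged
    placements = simulate_passage(
        pop, field_, geom, flow_cfg, mode="focused",
        wf_um=geom.fov_width * 0.9, seed=rng,
    )
    trans = render_transmission(
        placements, geom=geom, flow_cfg=flow_cfg,
        pixel_size_um=pixel_size_um, noise=noise, defocus=defocus, seed=rng,
    )
    phase = render_phase(
        placements, geom=geom, flow_cfg=flow_cfg,
        pixel_size_um=pixel_size_um, noise=noise, defocus=defocus, seed=rng,
    )
    return AnalyteRun(
        transmission=trans, phase=phase, placements=placements,
        population=pop, flow_cfg=flow_cfg, geom=geom,
    )


def analyze_run(
    run: AnalyteRun,
    modality: str = "phase",
    variant: str = "oh_max",
    optics: OpticalConstants | None = None,
) -> tuple[IndexResult, pd.DataFrame, dict]:
    """Process one modality of an analyte run into population indices.

    Applies the §-order pipeline, the modality's quality filter bank and
    the selected photometric variant; returns (indices, per-cell table,
    attrition bookkeeping with rows in/out of each stage).
    """
    optics = optics or OpticalConstants()
    if modality == "transmission":
        table, meta = process_transmission_stack(run.transmission)
        filtered = imaging.transmission_quality_filter(table[~table["border"]])
        analytes = analyte_table(
            filtered, "transmission", variant, optics,
            i0=meta["i0"], mask_threshold=meta["threshold"],
        )
    elif modality == "phase":
        table, meta = process_phase_stack(run.phase)
        filtered = imaging.phase_quality_filter(table[~table["border"]])
        analytes = analyte_table(
            filtered, "phase", variant, optics, mask_threshold=meta["threshold"]
        )
    else:
        raise ValueError(f"unknown modality {modality!r}")
    indices = compute_indices(analytes)
    book = {
        "detected": int(len(table)),
        "interior": int((~table["border"]).sum()) if len(table) else 0,
        "after_quality": int(len(filtered)),
        "threshold_meta": meta,
    }
    return indices, analytes, book
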