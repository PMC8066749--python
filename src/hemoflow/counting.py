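"""Cell-concentration estimation from per-frame object counts.

Two estimators convert the multiplicity-weighted count N recorded in a
stable time window into cells/μL of whole blood:

Laminar (single-inlet) mode — cells spread over the sheath width, only
a fraction passes the FOV, and a cell is imaged in several consecutive
frames:

    n = D * I_cells * delta
        * [ N/tau_c * (w - 2 r_s)/w + N/tau_s * 2 r_s/w ] / V,

with dilution D, image multiplication factor I_cells = w_sheath / w_FOV,
distribution factor delta (mean/max of the lateral count profile),
capture multiplicities tau_{c,s} = l_FOV / (u_{c,s} dt) of the center
and side velocity sections split at r_s, and the observed volume

    V = A_cs * l_FOV * (#frames / I_cells) * (u_c / u_fluid).

Hydrodynamic-focusing mode — all cells ride a focused stream of width
w_f, sampled every 1/tau_c frames:

    n = D * (w_f / w_FOV) * (N / tau_c) / V,   V = Q_i * #frames * dt.

The focused estimator is flux-consistent (V is exactly the pumped sample
volume).  The laminar observed volume is an instrument convention rather
than the pumped volume Q*T; `expected_laminar_count` provides the exact
inverse used by the synthetic generator so that round-trip runs are
self-consistent (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import (
    VelocityField,
    capture_multiplicity,
    section_boundary,
    section_mean_velocities,
)
from .geometry import ChannelGeometry, FlowConfig, UM3_PER_UL

__all__ = [
    "CountingFactors",
    "ConcentrationResult",
    "laminar_factors",
    "per_frame_counts",
    "stable_window",
    "observed_volume_laminar",
    "concentration_laminar",
    "concentration_focused",
    "expected_laminar_count",
]


@dataclass(frozen=True)
class CountingFactors:
    """Everything the laminar estimator needs besides the raw count."""

    dilution: float
    sheath_width_um: float
    fov_width_um: float
    fov_length_um: float
    channel_width_um: float
    cross_section_um2: float
    rs_um: float
    u_c_mm_s: float
    u_s_mm_s: float
    u_fluid_mm_s: float
    dt_s: float
    delta: float = 0.79

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")
        if self.rs_um >= self.channel_width_um / 2.0:
            raise ValueError("rs must be smaller than half the channel width")

    @property
    def i_cells(self) -> float:
        """Image multiplication factor I_cells = w_sheath / w_FOV."""
        return self.sheath_width_um / self.fov_width_um

    @property
    def tau_c(self) -> float:
        return capture_multiplicity(self.fov_length_um, self.u_c_mm_s, self.dt_s)

    @property
    def tau_s(self) -> float:
        return capture_multiplicity(self.fov_length_um, self.u_s_mm_s, self.dt_s)

    @property
    def center_fraction(self) -> float:
        return (self.channel_width_um - 2.0 * self.rs_um) / self.channel_width_um

    @property
    def side_fraction(self) -> float:
        return 2.0 * self.rs_um / self.channel_width_um


def laminar_factors(
    field_: VelocityField,
    geom: ChannelGeometry,
    flow_cfg: FlowConfig,
    sheath_width_um: float = 1801.0,
    delta: float = 0.79,
    rel_deviation: float = 0.025,
) -> CountingFactors:
    """Derive the full laminar factor set from the flow solution."""
    rs = section_boundary(field_, rel_deviation)
    u_c, u_s = section_mean_velocities(field_, rs)
    return CountingFactors(
        dilution=flow_cfg.dilution,
        sheath_width_um=sheath_width_um,
        fov_width_um=geom.fov_width,
        fov_length_um=geom.fov_length,
        channel_width_um=geom.width,
        cross_section_um2=geom.cross_section_um2,
        rs_um=rs,
        u_c_mm_s=u_c,
        u_s_mm_s=u_s,
        u_fluid_mm_s=field_.u_mean,
        dt_s=flow_cfg.dt,
        delta=delta,
    )


@dataclass(frozen=True)
class ConcentrationResult:
    """Cells/μL with the complete factor breakdown."""

    cells_per_ul: float
    observed_volume_ul: float
    total_count: float
    mode: str
    breakdown: dict

    def __post_init__(self) -> None:
        if self.observed_volume_ul <= 0:
            raise ValueError("observed volume must be positive")


def per_frame_counts(filtered: pd.DataFrame, n_frames: int) -> np.ndarray:
    """Multiplicity-weighted object count per frame (length n_frames).

    Expects a table that has passed the counting filter (so it carries a
    ``multiplicity`` column); frames without objects count zero.
    """
    counts = np.zeros(n_frames)
    if filtered.empty:
        return counts
    mult = filtered["multiplicity"] if "multiplicity" in filtered else pd.Series(
        1, index=filtered.index
    )
    per = filtered.assign(_m=mult).groupby("image_id")["_m"].sum()
    idx = per.index.to_numpy(dtype=int)
    ok = (idx >= 0) & (idx < n_frames)
    counts[idx[ok]] = per.to_numpy(dtype=float)[ok]
    return counts


def stable_window(
    series: np.ndarray, window: int, cv_threshold: float = 0.25
) -> tuple[int, int] | None:
    """Earliest window of ``window`` frames with a stable count rate.

    Stability means the rolling coefficient of variation (SD/mean of the
    per-frame counts) drops below ``cv_threshold``.  Returns the frame
    interval [start, stop) or None when no window qualifies.
    """
    s = np.asarray(series, dtype=float)
    if window <= 1 or window > s.size:
        raise ValueError("window must be in [2, len(series)]")
    roll = pd.Series(s).rolling(window)
    mean = roll.mean().to_numpy()
    sd = roll.std(ddof=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    ok = np.nonzero(cv[window - 1 :] < cv_threshold)[0]
    if ok.size == 0:
        return None
    start = int(ok[0])
    return start, start + window


def observed_volume_laminar(factors: CountingFactors, n_frames: int) -> float:
    """Observed blood-fluid volume V of the laminar mode, μL.

    V = A_cs * l_FOV * (#frames / I_cells) * (u_c / u_fluid).  Note this
    is the estimator's own volume convention, not the pumped volume Q*T.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    v_um3 = (
        factors.cross_section_um2
        * factors.fov_length_um
        * (n_frames / factors.i_cells)
        * (factors.u_c_mm_s / factors.u_fluid_mm_s)
    )
    return v_um3 / UM3_PER_UL


def concentration_laminar(
    total_count: float, factors: CountingFactors, observed_volume_ul: float
) -> ConcentrationResult:
    """Laminar-mode concentration from the stable-window count."""
    if observed_volume_ul <= 0:
        raise ValueError("observed volume must be positive")
    bracket = (
        total_count / factors.tau_c * factors.center_fraction
        + total_count / factors.tau_s * factors.side_fraction
    )
    n = factors.dilution * factors.i_cells * factors.delta * bracket / observed_volume_ul
    return ConcentrationResult(
        cells_per_ul=n,
        observed_volume_ul=observed_volume_ul,
        total_count=total_count,
        mode="laminar",
        breakdown={
            "dilution": factors.dilution,
            "i_cells": factors.i_cells,
            "delta": factors.delta,
            "tau_c": factors.tau_c,
            "tau_s": factors.tau_s,
            "rs_um": factors.rs_um,
            "center_fraction": factors.center_fraction,
            "side_fraction": factors.side_fraction,
            "bracket": bracket,
        },
    )


def expected_laminar_count(
    cells_per_ul: float, factors: CountingFactors, observed_volume_ul: float
) -> float:
    """Exact inverse of :func:`concentration_laminar` — the expected
    stable-window count N for a given whole-blood concentration."""
    per_count = concentration_laminar(1.0, factors, observed_volume_ul).cells_per_ul
    return cells_per_ul / per_count


def concentration_focused(
    total_count: float,
    dilution: float,
    wf_um: float,
    fov_width_um: float,
    tau_c: float,
    qi_ml_min: float,
    n_frames: int,
    dt_s: float,
) -> ConcentrationResult:
    """Hydrodynamic-focusing concentration, V = Q_i * #frames * dt.

    The w_f / w_FOV factor extrapolates to cells outside the FOV when the
    focused stream is wider than the FOV (applied as-is even when > 1).
    """
    if min(dilution, wf_um, fov_width_um, tau_c, qi_ml_min, dt_s) <= 0:
        raise ValueError("all factors must be positive")
    v_ul = qi_ml_min * 1000.0 / 60.0 * n_frames * dt_s  # mL/min -> μL/s
    if v_ul <= 0:
        raise ValueError("observed volume must be positive (n_frames > 0)")
    n = dilution * (wf_um / fov_width_um) * (total_count / tau_c) / v_ul
    return ConcentrationResult(
        cells_per_ul=n,
        observed_volume_ul=v_ul,
        total_count=total_count,
        mode="focused",
        breakdown={
            "dilution": dilution,
            "wf_um": wf_um,
            "fov_width_um": fov_width_um,
            "tau_c": tau_c,
            "qi_ml_min": qi_ml_min,
        },
    )
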