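"""Channel geometry and acquisition/flow configuration.

Length unit conventions used throughout the package:

* channel cross-section coordinates, FOV sizes, radii: micrometres (μm)
* velocities: millimetres per second (mm/s)
* volumetric flow rates at the API boundary: millilitres per minute (mL/min)
* time: seconds

The default geometry is a wide, shallow glass channel (2000 μm x 144 μm
cross-section, 1.56 cm long) observed through a 176 μm x 132 μm camera
field of view, with the 176 μm side across the flow and the 132 μm side
along the flow direction.
"""

from __future__ import annotations

from dataclasses import dataclass

#: μm³/s per mL/min  (1 mL = 1e12 μm³, 1 min = 60 s)
ML_PER_MIN_TO_UM3_PER_S = 1e12 / 60.0

#: μm³ per μL
UM3_PER_UL = 1e9


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microchannel and camera field of view.

    Parameters
    ----------
    width : float
        Channel width w across the flow, μm.
    height : float
        Channel height h (short dimension, coverslip to floor), μm.
    length_cm : float
        Channel length along the flow, cm (not used by the cross-section
        flow solution, kept for provenance).
    fov_width : float
        Field-of-view extent across the flow, μm. Must not exceed ``width``.
    fov_length : float
        Field-of-view extent along the flow, μm.
    """

    width: float = 2000.0
    height: float = 144.0
    length_cm: float = 1.56
    fov_width: float = 176.0
    fov_length: float = 132.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("channel width and height must be positive")
        if self.height / self.width >= 1.0:
            raise ValueError(
                "expected a shallow channel with aspect ratio h/w < 1; "
                f"got h/w = {self.height / self.width:.3f}"
            )
        if not (0 < self.fov_width <= self.width):
            raise ValueError("fov_width must satisfy 0 < fov_width <= width")
        if self.fov_length <= 0:
            raise ValueError("fov_length must be positive")

    @property
    def aspect_ratio(self) -> float:
        """h/w, small for a wide shallow channel."""
        return self.height / self.width

    @property
    def cross_section_um2(self) -> float:
        """Cross-sectional area w*h in μm²."""
        return self.width * self.height


@dataclass(frozen=True)
class FlowConfig:
    """Pump rates and frame timing for one acquisition.

    ``q_sample`` is the sample-inlet rate and ``q_sheath`` the combined rate
    of the two sheath inlets (zero for the single-inlet laminar mode), both
    in mL/min. ``dilution`` is the fold-dilution of whole blood in the
    sample syringe (e.g. 300 means 1:300).
    """

    q_sample: float = 0.06
    q_sheath: float = 0.0
    frame_rate: float = 100.0
    n_frames: int = 1000
    exposure_us: float = 20.0
    dilution: float = 300.0

    def __post_init__(self) -> None:
        if self.q_sample < 0 or self.q_sheath < 0:
            raise ValueError("flow rates must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")

    @property
    def q_total(self) -> float:
        """Total volumetric rate Q_sample + Q_sheath, mL/min."""
        return self.q_sample + self.q_sheath

    @property
    def dt(self) -> float:
        """Frame interval 1/frame_rate, s."""
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        """Total recording time n_frames * dt, s."""
        return self.n_frames * self.dt
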