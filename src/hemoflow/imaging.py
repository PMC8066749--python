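"""Image pipeline: background correction, segmentation, features, filters.

Processing order follows the acquisition software it models: background
correction, fixed-threshold binary mask, connected-component contour
detection, then per-object features (morphology, intensity, co-occurrence
texture, phase summaries) collected into one table row per object per
frame.  Three filter banks act on that table:

* a counting filter (area > 9.5 μm² to remove platelets, plus cluster
  multiplicity from the diameter-vs-area locus) used for concentration,
* a transmission quality bank and a phase quality bank selecting
  in-focus, artifact-free singlets for hemoglobin/volume analysis.

Several feature definitions (radius variance, mass-center shift,
sphericity, co-occurrence parameters) are stated interpretations; they
are documented at the point of computation and every threshold is
configurable through :class:`FilterSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology

__all__ = [
    "GreyMap",
    "FilterSpec",
    "TRANSMISSION_QUALITY_FILTER",
    "PHASE_QUALITY_FILTER",
    "correct_background_transmission",
    "correct_background_phase",
    "phase_to_grey",
    "auto_threshold",
    "segment",
    "extract_features",
    "counting_filter",
    "transmission_quality_filter",
    "phase_quality_filter",
    "apply_filter",
]


# ---------------------------------------------------------------------------
# background correction


def correct_background_transmission(
    stack: np.ndarray, background: np.ndarray, offset: float | None = None
) -> np.ndarray:
    """Subtract a single cell-free background image from each frame.

    Returns float frames ``frame - background + offset``; the default
    offset is the background median, which keeps values non-negative for
    dark-on-bright cells.  The raw frames (and the I0 estimate from the
    background) must be kept alongside for photometry.
    """
    stack = np.asarray(stack)
    background = np.asarray(background, dtype=float)
    if stack.shape[-2:] != background.shape:
        raise ValueError("background shape does not match frame shape")
    if offset is None:
        offset = float(np.median(background))
    return stack.astype(float) - background[None] + offset


def correct_background_phase(stack: np.ndarray, n_ref: int = 11) -> np.ndarray:
    """Subtract the pixel-wise median of the first ``n_ref`` frames.

    The median over the leading cell-free (or mostly cell-free) frames is
    robust to a transient cell crossing fewer than half of them.  The
    reference is subtracted from every frame, including the first
    ``n_ref`` themselves.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] < n_ref:
        raise ValueError(f"stack has {stack.shape[0]} frames, need >= {n_ref}")
    ref = np.median(stack[:n_ref], axis=0)
    return stack - ref[None]


@dataclass(frozen=True)
class GreyMap:
    """Invertible affine map between phase (radians) and grey values."""

    gain: float = 40.0  # grey per radian
    offset: float = 0.0

    def to_grey(self, phase):
        return np.asarray(phase) * self.gain + self.offset

    def to_phase(self, grey):
        return (np.asarray(grey) - self.offset) / self.gain


def phase_to_grey(phase_frame: np.ndarray, grey_map: GreyMap | None = None):
    """Convert phase-shift values to grey values with a recorded map.

    Returns ``(grey_frame, grey_map)`` so downstream optical-height
    summaries can always be expressed back in radians.
    """
    grey_map = grey_map or GreyMap()
    return grey_map.to_grey(phase_frame), grey_map


# ---------------------------------------------------------------------------
# segmentation


def auto_threshold(
    background_like: np.ndarray, k: float = 4.0, direction: str = "below", floor: float = 0.0
) -> float:
    """Fixed segmentation threshold from background statistics.

    ``median(bg) -/+ max(k * SD(bg), floor)`` for dark-object
    (``below``) or bright-object (``above``) segmentation.  ``floor``
    guards the noiseless limit where the background SD is zero.
    """
    bg = np.asarray(background_like, dtype=float)
    med = float(np.median(bg))
    spread = max(k * float(bg.std()), floor)
    return med - spread if direction == "below" else med + spread


def segment(
    frame: np.ndarray, threshold: float, direction: str = "below", min_size_px: int = 4
) -> np.ndarray:
    """Fixed-threshold binary mask -> 8-connected labels.

    ``direction="below"`` labels pixels darker than the threshold
    (transmission: dark cells on bright background); ``"above"`` labels
    brighter pixels (phase).  Connected components smaller than
    ``min_size_px`` pixels (isolated noise excursions) are discarded.
    Objects touching the frame border keep their labels and are flagged
    during feature extraction.
    """
    frame = np.asarray(frame)
    mask = frame < threshold if direction == "below" else frame > threshold
    if min_size_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_size_px - 1, connectivity=2)
    return measure.label(mask, connectivity=2)


# ---------------------------------------------------------------------------
# features


def _glcm_energy_dissimilarity(
    values: np.ndarray, mask: np.ndarray, grey_quantum: float, levels: int = 8
):
    """Co-occurrence energy and dissimilarity of in-object pixels.

    Both statistics come from the symmetric, normalized co-occurrence
    matrix at offset (0, 1) (1 px, 0°) restricted to pixel pairs inside
    the object.  Energy (sum p², in (0, 1]) uses ``levels`` bins over the
    in-object intensity range, making it contrast-invariant.
    Dissimilarity (sum p |i - j|) uses absolute grey levels — intensities
    scaled by ``grey_quantum`` grey units per intensity unit and rounded
    — because it acts as a lower bound on edge steepness in grey units:
    a defocused cell has shallow gradients and a small value.  A constant
    object yields energy 1, dissimilarity 0.
    """
    left = mask[:, :-1] & mask[:, 1:]
    v = values[mask]
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        qn = np.zeros_like(values, dtype=np.intp)
    else:
        qn = np.clip(((values - lo) / (hi - lo) * levels).astype(np.intp), 0, levels - 1)
    i = qn[:, :-1][left]
    j = qn[:, 1:][left]
    if i.size == 0:
        return 1.0, 0.0
    p = np.zeros((levels, levels))
    np.add.at(p, (i, j), 1.0)
    np.add.at(p, (j, i), 1.0)
    p /= p.sum()
    idx = np.arange(levels)
    energy = float((p**2).sum())

    grey = np.round(values * grey_quantum)
    gi = grey[:, :-1][left]
    gj = grey[:, 1:][left]
    dissim = float(np.abs(gi - gj).mean())
    return energy, dissim


def _contour_radius_stats(mask: np.ndarray, centroid_rc: tuple[float, float]):
    """Contour-point distances to the centroid: (mean, variance/mean)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.nan, np.nan
    pts = np.vstack(contours)
    d = np.hypot(pts[:, 0] - 1 - centroid_rc[0], pts[:, 1] - 1 - centroid_rc[1])
    mean = float(d.mean())
    if mean == 0:
        return 0.0, 0.0
    return mean, float(d.var() / mean)


def _sphericity(heights: np.ndarray, mask: np.ndarray, centroid_rc, equiv_radius_px: float):
    """Goodness of fit of the height profile to an ideal sphere chord.

    The in-object height map (phase shift, or absorbance for
    transmission-only runs) is compared with the chord profile
    2 sqrt(R² - rho²) of a sphere of the object's equivalent radius; the
    amplitude is fit by least squares and sphericity is defined as
    1 - RMS residual / RMS signal.  An in-focus rendered sphere scores
    close to 1; defocus blur flattens the profile and lowers the score.
    """
    rr, cc = np.nonzero(mask)
    rho2 = (rr - centroid_rc[0]) ** 2 + (cc - centroid_rc[1]) ** 2
    model = 2.0 * np.sqrt(np.maximum(equiv_radius_px**2 - rho2, 0.0))
    h = heights[mask]
    denom = float((model**2).sum())
    if denom == 0 or h.size == 0:
        return np.nan
    a = float((h * model).sum()) / denom
    resid = h - a * model
    rms_sig = float(np.sqrt((h**2).mean()))
    if rms_sig == 0:
        return np.nan
    return 1.0 - float(np.sqrt((resid**2).mean())) / rms_sig


def extract_features(
    labels: np.ndarray,
    transmission: np.ndarray | None = None,
    phase: np.ndarray | None = None,
    raw_transmission: np.ndarray | None = None,
    pixel_size_um: float = 0.344,
    i0: float | None = None,
    image_id: int = 0,
    grey_gain_per_rad: float = 40.0,
) -> pd.DataFrame:
    """Per-object feature table for one frame.

    ``transmission``/``phase`` are the background-corrected frames used
    for texture and phase summaries; ``raw_transmission`` (with its
    background level ``i0``) feeds the photometric intensities I_mean and
    I_min.  At least one modality frame must be supplied.

    Columns: image_id, cell_id, area_um2, diameter_um (equivalent),
    feret_um, aspect_ratio, circularity, radius_variance,
    mass_center_shift (px), energy, dissimilarity, sphericity, i_mean,
    i_min, grey_min (8-bit I/I0 scale), oh_mean, oh_max, oh_min (radians),
    ov (radian * μm²), centroid_row/col (px), border (bool).
    """
    if transmission is None and phase is None:
        raise ValueError("at least one modality frame is required")
    ny, nx = labels.shape
    px_area = pixel_size_um**2
    # intensity image used for weighting/texture: phase if present,
    # otherwise the transmission deficit (dark cells -> positive weight)
    if phase is not None:
        weight_img = np.asarray(phase, dtype=float)
        height_img = weight_img
        grey_quantum = grey_gain_per_rad  # grey units per radian
    else:
        t = np.asarray(transmission, dtype=float)
        weight_img = float(np.median(t)) - t
        height_img = weight_img
        level = i0 if i0 is not None else max(float(np.median(t)), 1.0)
        grey_quantum = 255.0 / level  # 8-bit grey per count

    records = []
    for rp in measure.regionprops(labels, intensity_image=weight_img):
        mask_local = rp.image
        sl = rp.slice
        area_um2 = rp.area * px_area
        diameter = 2.0 * np.sqrt(area_um2 / np.pi)
        minor = rp.axis_minor_length
        aspect = rp.axis_major_length / minor if minor > 0 else np.inf
        perim = rp.perimeter
        circ = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else np.nan
        cr, cc_ = rp.centroid_local
        _, rvar = _contour_radius_stats(mask_local, (cr, cc_))
        try:
            wr, wc = rp.centroid_weighted_local
            mshift = float(np.hypot(wr - cr, wc - cc_))
        except (ValueError, ZeroDivisionError):
            mshift = np.nan

        texture_img = height_img[sl]
        energy, dissim = _glcm_energy_dissimilarity(texture_img, mask_local, grey_quantum)
        equiv_r_px = np.sqrt(rp.area / np.pi)
        spher = _sphericity(texture_img, mask_local, (cr, cc_), equiv_r_px)

        rec = {
            "image_id": image_id,
            "cell_id": rp.label,
            "area_um2": area_um2,
            "diameter_um": diameter,
            "feret_um": rp.feret_diameter_max * pixel_size_um,
            "aspect_ratio": aspect,
            "circularity": circ,
            "radius_variance": rvar,
            "mass_center_shift": mshift,
            "energy": energy,
            "dissimilarity": dissim,
            "sphericity": spher,
            "centroid_row": rp.centroid[0],
            "centroid_col": rp.centroid[1],
            "border": bool(
                sl[0].start == 0 or sl[1].start == 0
                or sl[0].stop == ny or sl[1].stop == nx
            ),
        }

        if raw_transmission is not None:
            raw = np.asarray(raw_transmission, dtype=float)[sl][mask_local]
            rec["i_mean"] = float(raw.mean())
            rec["i_min"] = float(raw.min())
            level = i0 if i0 is not None else float(np.median(raw_transmission))
            rec["grey_min"] = float(raw.min()) / level * 255.0
            # integrated decadic absorbance over the object, OD·μm²;
            # additive across overlapping cells (transmittances multiply)
            od = -np.log10(np.maximum(raw, 0.5) / level)
            rec["od_integral_um2"] = float(od.sum()) * px_area
        else:
            rec["i_mean"] = np.nan
            rec["i_min"] = np.nan
            rec["grey_min"] = np.nan
            rec["od_integral_um2"] = np.nan

        if phase is not None:
            ph = np.asarray(phase, dtype=float)[sl][mask_local]
            rec["oh_mean"] = float(ph.mean())
            rec["oh_max"] = float(ph.max())
            rec["oh_min"] = float(ph.min())
            rec["ov"] = float(ph.sum()) * px_area
        else:
            rec["oh_mean"] = np.nan
            rec["oh_max"] = np.nan
            rec["oh_min"] = np.nan
            rec["ov"] = np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=[
            "image_id", "cell_id", "area_um2", "diameter_um", "feret_um",
            "aspect_ratio", "circularity", "radius_variance",
            "mass_center_shift", "energy", "dissimilarity", "sphericity",
            "centroid_row", "centroid_col", "border", "i_mean", "i_min",
            "grey_min", "od_integral_um2", "oh_mean", "oh_max", "oh_min", "ov",
        ]
    )


# ---------------------------------------------------------------------------
# filters


@dataclass(frozen=True)
class FilterSpec:
    """Named threshold bank; each entry maps a feature column to a
    (comparison, threshold) pair, with comparison one of "<" or ">"."""

    name: str
    rules: dict = field(default_factory=dict)

    def mask(self, table: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.rules if c not in table.columns]
        if missing:
            raise KeyError(f"filter {self.name!r}: missing feature columns {missing}")
        keep = pd.Series(True, index=table.index)
        for col, (op, thr) in self.rules.items():
            vals = table[col]
            keep &= (vals < thr) if op == "<" else (vals > thr)
        return keep


TRANSMISSION_QUALITY_FILTER = FilterSpec(
    "transmission_quality",
    {
        "aspect_ratio": ("<", 1.1),
        "area_um2": (">", 5.0),
        "circularity": (">", 0.83),
        "energy": (">", 0.15),
        "mass_center_shift": ("<", 1.25),
        "grey_min": ("<", 62.0),
        "radius_variance": ("<", 1.0),
    },
)

PHASE_QUALITY_FILTER = FilterSpec(
    "phase_quality",
    {
        "aspect_ratio": ("<", 1.1),
        "area_um2": ("<", 40.0),
        "circularity": (">", 0.85),
        "dissimilarity": (">", 3.2),
        "radius_variance": ("<", 0.5),
        "sphericity": (">", 0.95),
    },
)


def apply_filter(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Keep rows satisfying every rule of ``spec`` (pure row predicate)."""
    if table.empty:
        return table.copy()
    return table[spec.mask(table)].copy()


def transmission_quality_filter(
    table: pd.DataFrame, spec: FilterSpec = TRANSMISSION_QUALITY_FILTER
) -> pd.DataFrame:
    """In-focus singlet selection on transmission features."""
    return apply_filter(table, spec)


def phase_quality_filter(
    table: pd.DataFrame, spec: FilterSpec = PHASE_QUALITY_FILTER
) -> pd.DataFrame:
    """In-focus singlet selection on phase features."""
    return apply_filter(table, spec)


def counting_filter(
    table: pd.DataFrame,
    min_area_um2: float = 9.5,
    locus_tolerance: float = 0.35,
) -> pd.DataFrame:
    """Counting selection: area cut plus cluster multiplicity.

    Objects with area <= 9.5 μm² (platelets, debris) are dropped.  The
    remaining objects are compared with the single-cell locus in the
    diameter-vs-area plane: a circular singlet has
    area ≈ π (feret/2)², whereas merged clusters are elongated and fall
    below that locus.  Off-locus objects are assigned multiplicity
    round(area / median singlet area); on-locus objects count once.

    Shape alone cannot see a near-complete eclipse (two cells almost on
    top of each other stay compact and on-locus), so when the table
    carries the integrated absorbance — which is additive across
    overlapping cells — an object whose absorbance reaches a multiple of
    the in-focus singlet value raises its multiplicity to that multiple.
    The singlet reference is an upper quantile of the on-locus
    absorbances because defocus only ever *reduces* the integral.

    No focus filtering is applied — the aim is to count every passing
    cell.
    """
    if table.empty:
        out = table.copy()
        out["multiplicity"] = pd.Series(dtype=int)
        return out
    out = table[table["area_um2"] > min_area_um2].copy()
    if out.empty:
        out["multiplicity"] = pd.Series(dtype=int)
        return out
    locus_area = np.pi * (out["feret_um"] / 2.0) ** 2
    on_locus = out["area_um2"] >= (1.0 - locus_tolerance) * locus_area
    singles = out.loc[on_locus, "area_um2"]
    median_single = float(singles.median()) if len(singles) else float(out["area_um2"].median())
    mult = np.ones(len(out), dtype=int)
    off = ~on_locus.to_numpy()
    mult[off] = np.maximum(
        np.round(out.loc[~on_locus, "area_um2"].to_numpy() / median_single).astype(int), 1
    )
    if "od_integral_um2" in out.columns:
        od = out["od_integral_um2"].to_numpy(dtype=float)
        od_singles = od[on_locus.to_numpy() & np.isfinite(od)]
        if od_singles.size >= 10:
            od_ref = float(np.quantile(od_singles, 0.7))
            if od_ref > 0:
                od_mult = np.round(od / od_ref).astype(int)
                mult = np.maximum(mult, np.where(np.isfinite(od), od_mult, 1))
    out["multiplicity"] = np.maximum(mult, 1)
    return out
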