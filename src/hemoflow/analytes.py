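"""Per-cell hemoglobin concentration, volume, and population indices.

Transmission route (Beer–Lambert): cHB = -log10(I/I0) * M / (eps * d),
with I either the mean (``i_mean``) or minimum (``i_min``) in-cell
intensity and d the equivalent diameter from the segmented area.

Phase route: cHB = (1/beta) * (dPhi * lambda / (2 pi d) - n_HB0 + n_m),
with dPhi either the mean (``oh_mean``) or maximum (``oh_max``) optical
height; for the optical-volume route the mean index contrast follows
from dn = OV * lambda / (2 pi * V_sphere(d)), exact for an ideal sphere.

Cell volume is the sphere volume V = pi/6 d³ (1 μm³ = 1 fl).  Population
indices are the per-cell analogues of the red-cell indices: mean volume
(MCV analogue), mean cHB (CHCM analogue), and the distribution widths
RDW (SD of volume, fl) and HDW (SD of cHB, g/dL), plus a
volume-vs-concentration cytogram.

Concentrations are computed in g/mL and reported in g/dL (x100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import OpticalConstants

__all__ = [
    "IndexResult",
    "chb_transmission",
    "chb_transmission_mean",
    "chb_phase",
    "sphere_volume",
    "effective_epsilon",
    "analyte_table",
    "compute_indices",
    "slope1_fit",
]

#: cytogram gate lines (g/dL, fl) drawn on the reference instrument's plots
CYTOGRAM_CHB_GATES = (28.0, 41.0)
CYTOGRAM_VOLUME_GATES = (60.0, 120.0)


def chb_transmission(
    i,
    i0,
    d_um,
    optics: OpticalConstants | None = None,
    errors: str = "flag",
):
    """Beer–Lambert cellular hemoglobin concentration, g/dL.

    ``i`` is the in-cell intensity (mean or minimum variant), ``i0`` the
    cell-free background intensity and ``d_um`` the cell diameter.
    Out-of-domain intensities (I <= 0 or I > I0) are returned as NaN when
    ``errors="flag"`` (never clamped silently) or raise with
    ``errors="raise"``.
    """
    optics = optics or OpticalConstants()
    i = np.asarray(i, dtype=float)
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    bad = (i <= 0) | (i > i0)
    if errors == "raise" and np.any(bad):
        raise ValueError("intensity outside (0, I0]")
    with np.errstate(divide="ignore", invalid="ignore"):
        chb_g_ml = -np.log10(i / i0) * optics.molar_mass / (optics.epsilon * d)
    chb_g_ml = np.where(bad, np.nan, chb_g_ml)
    out = chb_g_ml * 100.0
    return float(out) if out.ndim == 0 else out


def _mean_sphere_transmittance(a, t: float = 0.0):
    """Mean transmittance of an absorbing sphere over its segmented disc.

    ``a`` is the central (natural-log) optical depth and ``t`` the
    optical depth at the segmentation boundary: the mask covers the disc
    out to the radius where the chord has depth ``t`` (t = 0 means the
    full disc).  With s0 = t/a,

        m(a) = 2 [(1 + t) e^(-t) - (1 + a) e^(-a)] / (a² (1 - s0²)).
    """
    a = np.asarray(a, dtype=float)
    small = a < max(1e-6, 2.0 * t)
    s0 = np.where(a > 0, np.minimum(t / np.maximum(a, 1e-300), 0.999), 0.0)
    with np.errstate(over="ignore", invalid="ignore"):
        full = (
            2.0
            * ((1.0 + t) * np.exp(-t) - (1.0 + a) * np.exp(-a))
            / (np.maximum(a, 1e-300) ** 2 * (1.0 - s0**2))
        )
    return np.where(small, 1.0 - np.maximum(a, t) / 3.0, full)


def chb_transmission_mean(
    i_mean,
    i0,
    d_um,
    optics: OpticalConstants | None = None,
    threshold_depth: float = 0.0,
):
    """Invert the mean in-cell intensity through the sphere model, g/dL.

    Because transmittance is exponential in the chord, the disc-averaged
    intensity is not Beer–Lambert with any fixed path; this solves the
    homogeneous-sphere mean-transmittance relation for the central
    optical depth instead and converts it to concentration.
    ``threshold_depth`` is the natural-log optical depth of the
    segmentation boundary, ln(I0/I_threshold): when given, both the
    truncation of the averaged disc and the resulting underestimate of
    the true diameter (d_um is the mask-equivalent diameter) are
    corrected through the sphere geometry.  Exact for a noiseless
    in-focus sphere; out-of-domain intensities flag as NaN.
    """
    from scipy.optimize import brentq

    optics = optics or OpticalConstants()
    t = max(float(threshold_depth), 0.0)
    m = np.atleast_1d(np.asarray(i_mean, dtype=float) / i0)
    d = np.atleast_1d(np.asarray(d_um, dtype=float)).astype(float)
    d = np.broadcast_to(d, m.shape)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.full(m.shape, np.nan)
    for idx in np.ndindex(m.shape):
        mi = m[idx]
        if not (0.0 < mi <= 1.0):
            continue
        if mi >= 1.0 - 1e-12:
            out[idx] = 0.0
            continue
        lo = max(1e-9, 2.0 * t + 1e-9)
        a = brentq(lambda a_: float(_mean_sphere_transmittance(a_, t)) - mi, lo, 300.0)
        s0 = t / a
        d_true = d[idx] / np.sqrt(max(1.0 - s0**2, 1e-12))
        absorb_per_um = a / (np.log(10.0) * d_true)
        out[idx] = absorb_per_um * optics.molar_mass / optics.epsilon * 100.0
    return float(out.ravel()[0]) if out.size == 1 and np.isscalar(i_mean) else out


def mask_corrected_diameter(d_mask_um, s0):
    """True sphere diameter from a threshold-truncated mask diameter.

    The segmentation boundary cuts the projected disc at the radius
    where the normalized chord equals s0, so the mask covers the
    fraction sqrt(1 - s0²) of the true diameter.
    """
    s0 = np.clip(np.asarray(s0, dtype=float), 0.0, 0.97)
    return np.asarray(d_mask_um, dtype=float) / np.sqrt(1.0 - s0**2)


def chb_phase(
    summary,
    d_um,
    optics: OpticalConstants | None = None,
    variant: str = "oh",
):
    """Phase-derived cellular hemoglobin concentration, g/dL.

    ``variant="oh"`` treats ``summary`` as an optical-height phase shift
    in radians (mean or maximum); ``variant="ov"`` treats it as the
    optical volume, the integral of phase over the object area
    (radian·μm²), and recovers the mean index contrast through the ideal
    sphere of diameter ``d_um``.
    """
    optics = optics or OpticalConstants()
    s = np.asarray(summary, dtype=float)
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    lam = optics.lambda_phase_um
    if variant == "oh":
        dn = s * lam / (2.0 * np.pi * d)
    elif variant == "ov":
        dn = s * lam / (2.0 * np.pi * sphere_volume(d))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    chb_g_ml = (dn - (optics.n_hb0 - optics.n_medium)) / optics.beta
    out = chb_g_ml * 100.0
    return float(out) if out.ndim == 0 else out


def sphere_volume(d_um):
    """Sphere volume V = pi/6 d³ in fl (1 μm³ = 1 fl)."""
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.pi / 6.0 * d**3
    return float(out) if out.ndim == 0 else out


def effective_epsilon(
    spectrum: "pd.DataFrame | None" = None,
    lambda_center_nm: float = 425.0,
    sigma_nm: float = 10.0,
    default: float = 116933.0,
) -> float:
    """LED-bandwidth-weighted molar attenuation coefficient.

    Averages a tabulated eps(lambda) spectrum of oxygenated hemoglobin
    with a Gaussian of mean ``lambda_center_nm`` and SD ``sigma_nm``
    (the LED bandwidth).  The table must cover lambda_center ± 3 sigma.
    With no table supplied the constant ``default`` is returned.
    """
    if spectrum is None:
        return default
    lam = np.asarray(spectrum["lambda_nm"], dtype=float)
    eps = np.asarray(spectrum["epsilon"], dtype=float)
    lo, hi = lambda_center_nm - 3.0 * sigma_nm, lambda_center_nm + 3.0 * sigma_nm
    if lam.min() > lo or lam.max() < hi:
        raise ValueError("spectrum table does not cover the LED band (center ± 3 sigma)")
    grid = np.linspace(lo, hi, 601)
    vals = np.interp(grid, lam, eps)
    wts = np.exp(-0.5 * ((grid - lambda_center_nm) / sigma_nm) ** 2)
    return float(np.trapezoid(vals * wts, grid) / np.trapezoid(wts, grid))


def analyte_table(
    features: pd.DataFrame,
    modality: str,
    variant: str,
    optics: OpticalConstants | None = None,
    i0: float | None = None,
    mask_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-cell volume and cHB from a (quality-filtered) feature table.

    ``variant`` selects the photometric summary: ``i_mean``/``i_min``
    for transmission (requires ``i0``), ``oh_mean``/``oh_max``/``ov``
    for phase.  The minimum-intensity / maximum-height summaries probe
    the central chord of the sphere; the mean summaries average over the
    segmented disc (mean chord 2/3 d for a full disc); the OV route goes
    through the sphere volume.

    ``mask_threshold`` is the fixed segmentation threshold the mask came
    from (radians for phase, absolute intensity for transmission).  When
    given, the sphere geometry of the threshold cut is corrected: the
    mask boundary sits where the normalized chord equals s0 (s0 =
    threshold / central signal), so the mask-equivalent diameter
    underestimates the true one by sqrt(1 - s0²) and the disc averages
    are truncated accordingly.  Returns image_id, cell_id, diameter_um
    (corrected), volume_fl, chb_g_dl, variant, modality.
    """
    optics = optics or OpticalConstants()
    d_mask = features["diameter_um"].to_numpy(dtype=float)
    if modality == "transmission":
        if variant not in ("i_mean", "i_min"):
            raise ValueError("transmission variants are i_mean / i_min")
        if i0 is None:
            raise ValueError("transmission photometry requires the background level i0")
        t_depth = (
            np.log(i0 / mask_threshold)
            if mask_threshold is not None and 0 < mask_threshold < i0
            else 0.0
        )
        if variant == "i_mean":
            # mean absorbance route: the in-contour mean optical density
            # is linear in concentration (mean chord of the truncated
            # disc is (2/3) d (1-s0³)/(1-s0²)), unlike the absorbance of
            # the mean intensity, which saturates for opaque cells
            od_mean = features["od_integral_um2"].to_numpy(dtype=float) / features[
                "area_um2"
            ].to_numpy(dtype=float)
            s0 = np.clip(
                t_depth / np.maximum(np.log(10.0) * od_mean * 1.5, 1e-12), 0.0, 0.97
            )
            d = mask_corrected_diameter(d_mask, s0)
            path = d * (2.0 / 3.0) * (1.0 - s0**3) / (1.0 - s0**2)
            chb = od_mean / path * optics.molar_mass / optics.epsilon * 100.0
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                a_center = np.log(i0 / np.clip(features[variant], 1e-12, None))
            s0 = np.clip(t_depth / np.maximum(a_center, 1e-12), 0.0, 0.97)
            d = mask_corrected_diameter(d_mask, s0)
            chb = chb_transmission(features[variant], i0, d, optics)
    elif modality == "phase":
        oh_max = features["oh_max"].to_numpy(dtype=float)
        if mask_threshold is not None and mask_threshold > 0:
            s0 = np.clip(mask_threshold / np.maximum(oh_max, 1e-12), 0.0, 0.97)
        else:
            s0 = np.zeros_like(oh_max)
        d = mask_corrected_diameter(d_mask, s0)
        if variant == "oh_max":
            chb = chb_phase(oh_max, d, optics, variant="oh")
        elif variant == "oh_mean":
            # mean chord over the truncated disc
            path = d * (2.0 / 3.0) * (1.0 - s0**3) / (1.0 - s0**2)
            chb = chb_phase(features[variant], path, optics, variant="oh")
        elif variant == "ov":
            # chord integral over the truncated disc is V_sphere (1 - s0³)
            ov_full = features["ov"].to_numpy(dtype=float) / (1.0 - s0**3)
            chb = chb_phase(ov_full, d, optics, variant="ov")
        else:
            raise ValueError("phase variants are oh_mean / oh_max / ov")
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return pd.DataFrame(
        {
            "image_id": features["image_id"],
            "cell_id": features["cell_id"],
            "diameter_um": d,
            "volume_fl": sphere_volume(np.clip(d, 1e-9, None)),
            "chb_g_dl": np.asarray(chb, dtype=float),
            "variant": variant,
            "modality": modality,
        }
    )


@dataclass(frozen=True)
class IndexResult:
    """Population indices with the cytogram.

    ``mean_volume_fl`` / ``mean_chb_g_dl`` are the MCV / CHCM analogues;
    ``rdw_fl`` / ``hdw_g_dl`` are the SDs of the per-cell volume and
    hemoglobin-concentration distributions in physical units.
    """

    mean_volume_fl: float
    mean_chb_g_dl: float
    rdw_fl: float
    hdw_g_dl: float
    n_cells: int
    cytogram: np.ndarray = field(repr=False)
    volume_edges_fl: np.ndarray = field(repr=False)
    chb_edges_g_dl: np.ndarray = field(repr=False)
    chb_gates_g_dl: tuple = CYTOGRAM_CHB_GATES
    volume_gates_fl: tuple = CYTOGRAM_VOLUME_GATES


def compute_indices(
    analytes: pd.DataFrame,
    volume_range_fl: tuple[float, float] = (0.0, 150.0),
    chb_range_g_dl: tuple[float, float] = (0.0, 50.0),
    bins: tuple[int, int] = (75, 50),
) -> IndexResult:
    """Means, distribution widths and cytogram of a per-cell table.

    Drops non-finite rows (flagged photometry) before aggregating; the
    cytogram is a 2D histogram of volume (fl) versus cHB (g/dL).
    """
    if analytes.empty:
        raise ValueError("cannot compute indices of an empty analyte table")
    v = analytes["volume_fl"].to_numpy(dtype=float)
    c = analytes["chb_g_dl"].to_numpy(dtype=float)
    ok = np.isfinite(v) & np.isfinite(c)
    v, c = v[ok], c[ok]
    if v.size == 0:
        raise ValueError("no finite analyte rows")
    hist, v_edges, c_edges = np.histogram2d(
        v, c, bins=bins, range=[volume_range_fl, chb_range_g_dl]
    )
    return IndexResult(
        mean_volume_fl=float(v.mean()),
        mean_chb_g_dl=float(c.mean()),
        rdw_fl=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        hdw_g_dl=float(c.std(ddof=1)) if c.size > 1 else 0.0,
        n_cells=int(v.size),
        cytogram=hist,
        volume_edges_fl=v_edges,
        chb_edges_g_dl=c_edges,
    )


def slope1_fit(measured, reference):
    """Fixed-slope-one linear fit and residual variation.

    Fits y = x + b by least squares (b = mean(measured - reference)) and
    reports the per-point percentage variation around the fit,
    100 |y - (x + b)| / x, as (intercept, mean_variation, sd_variation).
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise ValueError("measured and reference must have equal length")
    if m.size < 2:
        raise ValueError("need at least two points")
    b = float(np.mean(m - r))
    variation = 100.0 * np.abs(m - (r + b)) / r
    return b, float(variation.mean()), float(variation.std(ddof=1))
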