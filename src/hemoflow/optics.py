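"""Photometric constants for hemoglobin imaging.

Two modalities share one sphered-RBC forward model:

* transmission at 425 nm — hemoglobin absorbance attenuates the
  illumination following Beer–Lambert,
  I = I0 * 10^(-eps * (cHB / M) * d), with the molar attenuation
  coefficient eps and molar mass M of hemoglobin and the light path d
  through the cell;
* quantitative phase at 530 nm — the cell retards the wavefront by
  dPhi = (2 pi / lambda) * dn * d with dn = n_HB0 + beta * cHB - n_m,
  where beta is the refractive increment of hemoglobin solution and
  n_HB0 the RBC refractive index at zero hemoglobin.

Concentrations are in g/mL internally (1 g/mL = 100 g/dL).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelengths, hemoglobin photometry constants and depths of focus.

    Attributes
    ----------
    lambda_trans_nm, lambda_phase_nm : float
        Illumination wavelengths of the transmission and phase channels.
    epsilon : float
        Molar attenuation coefficient of (oxygenated) hemoglobin at the
        transmission wavelength, μm⁻¹/(mol/mL).
    molar_mass : float
        Molar mass of hemoglobin, g/mol.
    beta : float
        Refractive increment of hemoglobin solution at the phase
        wavelength, mL/g.
    n_hb0 : float
        Effective RBC refractive index at zero hemoglobin concentration.
    n_medium : float
        Refractive index of the suspension medium (PBS).
    dof_trans_um, dof_phase_um : float
        Depth of focus of the transmission and holographic channels, μm.
    led_bandwidth_nm : float
        Spectral bandwidth (SD of a Gaussian emission profile) of the LED.
    """

    lambda_trans_nm: float = 425.0
    lambda_phase_nm: float = 530.0
    epsilon: float = 116933.0
    molar_mass: float = 64458.0
    beta: float = 0.1497
    n_hb0: float = 1.337
    n_medium: float = 1.336
    dof_trans_um: float = 0.49
    dof_phase_um: float = 1.26
    led_bandwidth_nm: float = 10.0

    def __post_init__(self) -> None:
        vals = (
            self.lambda_trans_nm,
            self.lambda_phase_nm,
            self.epsilon,
            self.molar_mass,
            self.beta,
            self.n_hb0,
            self.n_medium,
            self.dof_trans_um,
            self.dof_phase_um,
            self.led_bandwidth_nm,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all optical constants must be positive")
        if self.n_hb0 <= self.n_medium:
            raise ValueError("n_hb0 must exceed the medium index")

    @property
    def lambda_phase_um(self) -> float:
        return self.lambda_phase_nm / 1000.0

    def delta_n(self, chb_g_ml: float):
        """Refractive-index contrast dn(cHB) = n_HB0 + beta*cHB - n_m."""
        return self.n_hb0 + self.beta * chb_g_ml - self.n_medium

    def absorbance_per_um(self, chb_g_ml: float):
        """Decadic absorbance per μm of path, eps * cHB / M."""
        return self.epsilon * chb_g_ml / self.molar_mass
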