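"""Centralised unit conversions.

Public interfaces use the lab's working units — micrometres for coordinates
and radii, nanometres for displacements, pascal for moduli, seconds and hertz
for time and frequency, N/m^3 for the volumetric force constant.  The physical
relations (Stokes drag, displacement-modulus relation) are evaluated in SI
internally; every conversion passes through this module so that unit bugs have
a single place to hide.
"""

from __future__ import annotations

import numpy as np

UM = 1e-6  # metres per micrometre
NM = 1e-9  # metres per nanometre


def um_to_m(x):
    return np.asarray(x, dtype=float) * UM


def nm_to_m(x):
    return np.asarray(x, dtype=float) * NM


def m_to_nm(x):
    return np.asarray(x, dtype=float) / NM


def displacement_amplitude_nm(fv: float, radius_um, gstar_pa) -> np.ndarray:
    """Oscillation amplitude A = 2 fv r^2 / (9 |G*|), returned in nm.

    ``fv`` is the volumetric force constant in N/m^3, ``radius_um`` the probe
    radius in micrometres and ``gstar_pa`` the absolute complex shear modulus
    in Pa.
    """
    r = um_to_m(radius_um)
    g = np.asarray(gstar_pa, dtype=float)
    if np.any(g <= 0):
        raise ValueError("gstar must be positive")
    return m_to_nm(2.0 * fv * r**2 / (9.0 * g))


def gstar_from_amplitude_pa(fv: float, radius_um, amplitude_nm) -> np.ndarray:
    """Invert the displacement-amplitude relation: |G*| = 2 fv r^2 / (9 A)."""
    a = nm_to_m(amplitude_nm)
    if np.any(np.asarray(a) <= np.finfo(float).eps):
        raise ValueError("amplitude too small: stiffness undefined")
    return 2.0 * fv * um_to_m(radius_um) ** 2 / (9.0 * a)


def calibration_amplitude_nm(fv: float, radius_um, eta_pa_s: float, f_hz: float) -> np.ndarray:
    """Viscous-oil oscillation amplitude 2 r^2 fv / (9 eta omega), in nm.

    This is the amplitude of the -cos(omega t) term of the Stokes-drag
    displacement solution for a sinusoidally forced sphere in a Newtonian
    fluid of dynamic viscosity ``eta_pa_s``.
    """
    if eta_pa_s <= 0:
        raise ValueError("viscosity must be positive")
    omega = 2.0 * np.pi * f_hz
    r = um_to_m(radius_um)
    return m_to_nm(2.0 * r**2 * fv / (9.0 * eta_pa_s * omega))


def fv_from_calibration_amplitude(amplitude_nm, radius_um, eta_pa_s: float, f_hz: float):
    """Invert the oil-calibration amplitude: fv = 9 eta omega A / (2 r^2)."""
    omega = 2.0 * np.pi * f_hz
    return 9.0 * eta_pa_s * omega * nm_to_m(amplitude_nm) / (2.0 * um_to_m(radius_um) ** 2)


def force_amplitude_n(fv: float, radius_um) -> float:
    """Magnetic force amplitude F = fv * (4/3) pi r^3 in newtons."""
    r = float(um_to_m(radius_um))
    return fv * (4.0 / 3.0) * np.pi * r**3
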