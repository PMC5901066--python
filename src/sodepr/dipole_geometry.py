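"""The point-dipole model: couplings from geometry and geometry from couplings.

Treating the Mn(II) electron spin and a ligand nucleus as point magnetic
dipoles separated by r, the dipolar coupling is axial with principal values
(-T, -T, +2T) where

    T = (mu0/4pi) * g_e*beta_e * g_n*beta_n / (h * r^3)

and the effective coupling for a field making angle theta_n with the
inter-spin vector is A_eff = A_iso + T*(3cos^2 theta_n - 1).  For 1H the
prefactor is about 79.1 MHz A^3 (computed from CODATA constants at
g_e = 2.0023, never hard-coded), so T = 3-4 MHz for the 2.6-2.9 A water
ligand protons of the SOD active site.  The r^-3 law makes the coupling an
exquisitely sensitive ruler: its first-order differential

    dr = r * dT / (3 T)

says a 100 kHz coupling shift at the H_w geometry corresponds to ~0.03 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    BOHR_MAGNETON,
    MU0_OVER_4PI,
    Nucleus,
    NUCLEAR_MAGNETON,
    PLANCK,
    G_ELECTRON,
    get_nucleus,
)

#: Protons closer than this to a Mn(II) ion are sterically impossible.
MIN_DISTANCE_A = 1.5


class DipoleError(ValueError):
    pass


@dataclass(frozen=True)
class ProtonGeometry:
    """Mn-nucleus distance (A) and angle theta_n (degrees) to the field."""

    r_a: float
    theta_deg: float

    def __post_init__(self) -> None:
        if self.r_a <= MIN_DISTANCE_A:
            raise DipoleError(f"r = {self.r_a} A below the {MIN_DISTANCE_A} A bound")
        if not 0.0 <= self.theta_deg <= 180.0:
            raise DipoleError("theta_n must lie in [0, 180] degrees")


def dipolar_prefactor_mhz_a3(nucleus: Nucleus | str = "1H", g_e: float = G_ELECTRON) -> float:
    """(mu0/4pi)*g_e*beta_e*g_n*beta_n/h in MHz * Angstrom^3."""
    nuc = get_nucleus(nucleus)
    value = (
        MU0_OVER_4PI
        * g_e
        * BOHR_MAGNETON
        * nuc.g_n
        * NUCLEAR_MAGNETON
        / (PLANCK * (1e-10) ** 3)
    )
    return value * 1e-6  # Hz -> MHz


def point_dipole_t(r_a: float, nucleus: Nucleus | str = "1H") -> float:
    """Axial dipolar parameter T (MHz) at Mn-nucleus distance ``r_a`` (A)."""
    if r_a <= MIN_DISTANCE_A:
        raise DipoleError(
            f"r = {r_a} A is below the {MIN_DISTANCE_A} A physical bound"
        )
    return dipolar_prefactor_mhz_a3(nucleus) / r_a**3


def t_to_principal(t_mhz: float) -> tuple:
    """Expand the single axial parameter into (-T, -T, +2T) principal values."""
    return (-t_mhz, -t_mhz, 2 * t_mhz)


def principal_to_t(values) -> float:
    """Collapse an axial (-T, -T, +2T) triple back to T, checking axiality."""
    v = sorted(values)
    if abs(v[0] - v[1]) > 1e-6 or abs(v[0] + v[1] + v[2]) > 1e-6:
        raise DipoleError(f"principal values {values} are not axial traceless")
    return v[2] / 2.0


def aeff_from_geometry(a_iso_mhz: float, t_mhz: float, theta_deg):
    """A_eff = A_iso + T*(3cos^2 theta_n - 1), MHz (vectorized in theta)."""
    c = np.cos(np.radians(theta_deg))
    return a_iso_mhz + t_mhz * (3 * c * c - 1)


def distance_from_t(t_mhz: float, nucleus: Nucleus | str = "1H") -> float:
    """Invert the r^-3 law: r = (prefactor / T)^(1/3), Angstrom."""
    if t_mhz <= 0:
        raise DipoleError("dipolar T must be positive to invert for distance")
    return (dipolar_prefactor_mhz_a3(nucleus) / t_mhz) ** (1.0 / 3.0)


def distance_sensitivity(r_a: float, t_mhz: float, dt_mhz: float) -> float:
    """First-order distance change dr = r*dT/(3T) for a coupling shift dT, A.

    This is the coupling reading of a spectral shift; a line-position shift
    dnu in manifold M_s corresponds to dT = dnu/|M_s| instead.
    """
    if t_mhz <= 0:
        raise DipoleError("dipolar T must be positive")
    return r_a * dt_mhz / (3.0 * t_mhz)
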