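"""Orientation selection and projection of hyperfine tensors onto the field.

At a fixed field position inside a broad S = 5/2 powder pattern, only
molecules whose zero-field frame makes the right angle with the applied field
are resonant, so double-resonance spectra taken there are direction specific.
At the extreme spectral edges the resonant set collapses to a single
orientation (field along D_zz at the low-field edge for D < 0, along D_yy at
the high-field edge).

The effective coupling of a nucleus for field direction n (unit vector in the
molecular frame) is the secular projection

    A_eff = A_iso + n^T . T_mol . n

with T_mol the traceless dipolar tensor rotated into the molecular frame.
Pseudo-secular terms are neglected: at 3.35 T the proton Larmor frequency
(79-185 MHz at the fields used here) dwarfs the <= 7 MHz couplings, so state
mixing is tiny.  The positive-branch ELDOR-NMR offset convention is

    offset = nu' - q*nu_NMR = -M_s * q * A_eff

which sends A_eff = 6.4 MHz in the M_s = -5/2 manifold to +16 MHz.

Euler angles are ZYZ intrinsic everywhere (see docs/methods.md for a worked
rotation example).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import Nucleus, get_nucleus
from .fieldsweep import PowderGrid, make_powder_grid
from .spin_core import (
    SpectrometerSettings,
    SpinModelError,
    ZFSParameters,
    _check_ms,
)


@dataclass(frozen=True)
class EulerAngles:
    """ZYZ intrinsic Euler angles (radians) relating two right-handed frames."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= math.pi + 1e-12:
            raise ValueError("beta must lie in [0, pi]")

    def as_matrix(self) -> np.ndarray:
        """Rotation matrix whose columns are the rotated frame's axes."""
        return Rotation.from_euler(
            "ZYZ", [self.alpha, self.beta, self.gamma]
        ).as_matrix()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "EulerAngles":
        a, b, g = Rotation.from_matrix(m).as_euler("ZYZ")
        return cls(a % (2 * math.pi), abs(b) if b >= 0 else -b, g % (2 * math.pi))

    @classmethod
    def from_degrees(cls, alpha: float, beta: float, gamma: float) -> "EulerAngles":
        return cls(math.radians(alpha), math.radians(beta), math.radians(gamma))

    def degrees(self) -> Tuple[float, float, float]:
        return (
            math.degrees(self.alpha),
            math.degrees(self.beta),
            math.degrees(self.gamma),
        )


def _rotate_to_molecular(principal: np.ndarray, frame: EulerAngles) -> np.ndarray:
    r = frame.as_matrix()
    return r @ np.diag(principal) @ r.T


@dataclass
class HyperfineTensor:
    """Per-nucleus coupling: A_iso + traceless dipolar part, MHz, with frame.

    ``t_principal`` are the three dipolar principal values (must sum to zero);
    ``frame`` rotates the principal axes into the molecular frame.
    """

    nucleus: Nucleus | str
    a_iso_mhz: float
    t_principal_mhz: Sequence[float]
    frame: EulerAngles = field(default_factory=EulerAngles)
    identity: str = ""

    def __post_init__(self) -> None:
        self.nucleus = get_nucleus(self.nucleus)
        self.t_principal_mhz = np.asarray(self.t_principal_mhz, dtype=float)
        if self.t_principal_mhz.shape != (3,):
            raise ValueError("t_principal_mhz must have three entries")
        if abs(self.t_principal_mhz.sum()) > 1e-6:
            raise ValueError(
                f"dipolar principal values must be traceless; trace = "
                f"{self.t_principal_mhz.sum():.2e} MHz"
            )
        if self.nucleus.spin not in (0.5, 1.0):
            raise ValueError("only I = 1/2 and I = 1 nuclei are supported")

    def dipolar_molecular(self) -> np.ndarray:
        """3x3 dipolar tensor in the molecular frame, MHz."""
        return _rotate_to_molecular(self.t_principal_mhz, self.frame)

    @property
    def t_axial_mhz(self) -> float:
        """Axial dipolar parameter T for a (-T, -T, +2T) tensor."""
        return float(self.t_principal_mhz[2] / 2.0)


@dataclass
class QuadrupoleTensor:
    """Traceless nuclear quadrupole tensor (MHz) for an I >= 1 nucleus."""

    p_principal_mhz: Sequence[float]
    frame: EulerAngles = field(default_factory=EulerAngles)

    def __post_init__(self) -> None:
        self.p_principal_mhz = np.asarray(self.p_principal_mhz, dtype=float)
        if self.p_principal_mhz.shape != (3,):
            raise ValueError("p_principal_mhz must have three entries")
        if abs(self.p_principal_mhz.sum()) > 1e-6:
            raise ValueError("quadrupole principal values must be traceless")

    def molecular(self) -> np.ndarray:
        return _rotate_to_molecular(self.p_principal_mhz, self.frame)

    def effective(self, direction: np.ndarray) -> float:
        """Secular projection P_eff = n^T . P_mol . n, MHz."""
        n = _unit(direction)
        return float(n @ self.molecular() @ n)


@dataclass
class EffectiveCoupling:
    """A field-direction-resolved coupling with its manifold and quantum order."""

    a_eff_mhz: float
    ms: float
    q: int = 1

    def __post_init__(self) -> None:
        if self.q < 1 or int(self.q) != self.q:
            raise ValueError("quantum order q must be an integer >= 1")

    @property
    def offset_mhz(self) -> float:
        """Positive-branch offset nu' - q*nu_NMR = -M_s*q*A_eff, MHz."""
        return -self.ms * self.q * self.a_eff_mhz


def _unit(direction: np.ndarray) -> np.ndarray:
    n = np.asarray(direction, dtype=float)
    if n.shape != (3,):
        raise SpinModelError("direction must be a 3-vector")
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-6:
        raise SpinModelError(f"direction must be a unit vector (|n| = {norm:.6f})")
    return n


def effective_coupling(
    hft: HyperfineTensor, direction: np.ndarray, ms: float, q: int = 1
) -> EffectiveCoupling:
    """Secular effective coupling of ``hft`` for field direction ``direction``."""
    _check_ms(ms)
    n = _unit(direction)
    a_eff = hft.a_iso_mhz + float(n @ hft.dipolar_molecular() @ n)
    return EffectiveCoupling(a_eff, ms, q)


def resonant_orientations(
    settings: SpectrometerSettings,
    zfs: ZFSParameters,
    field_mt: float,
    bandwidth_mhz: float,
    ms: float,
    grid: Optional[PowderGrid] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid orientations resonant within ``bandwidth_mhz`` of ``field_mt``.

    Returns (theta, phi, weights) of the contributing orientations.  At the
    extreme low-field edge (D < 0) only theta_zf ~ 0 survives; at the extreme
    high-field edge only theta_zf ~ pi/2, phi_zf ~ pi/2.
    """
    _check_ms(ms)
    if grid is None:
        grid = make_powder_grid()
    ct = np.cos(grid.theta)
    bracket = zfs.d_ghz * (3 * ct**2 - 1) + 3 * zfs.e_ghz * (1 - ct**2) * np.cos(
        2 * grid.phi
    )
    b_res = (settings.nu_obs_ghz - (ms + 0.5) * bracket) / settings.ghz_per_mt
    half_width_mt = (bandwidth_mhz * 1e-3) / settings.ghz_per_mt / 2.0
    sel = np.abs(b_res - field_mt) <= half_width_mt
    if not sel.any():
        raise SpinModelError(
            f"no orientations resonate at {field_mt:.1f} mT within "
            f"{bandwidth_mhz:.1f} MHz for M_s = {ms}"
        )
    return grid.theta[sel], grid.phi[sel], grid.weights[sel]
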