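"""First-order spin-Hamiltonian arithmetic for an S = 5/2 ion at high field.

A high-spin Mn(II) centre in a strong magnetic field (94 GHz / 3.35 T here)
has six electron-spin levels M_s = -5/2 ... +5/2 split dominantly by the
electron Zeeman interaction, with the zero-field interaction (axial parameter
D, rhombic parameter E) acting as a first-order perturbation.  For the
M_s <-> M_s+1 transition of a molecule whose D_zz axis makes polar angle
theta_zf with the field (azimuth phi_zf from D_xx), the transition frequency
is shifted from g*beta*B/h by

    (M_s + 1/2) * [ D*(3cos^2(theta) - 1) + 3E*sin^2(theta)*cos(2*phi) ]

so a powder spectrum shows edges and shoulders ("turning points") at the
canonical orientations (field along D_zz, D_xx or D_yy).  The four labelled
turning points (zz,-5/2), (zz,-3/2), (xx,-5/2) and (yy,-5/2) let D and E be
read off in closed form; this module provides that forward map and its exact
inverse, plus an exact 6x6 diagonalization used as a testing oracle and the
Boltzmann weighting that makes the low-M_s transitions dominate at 6 K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np

from .constants import BOHR_MAGNETON, BOLTZMANN, G_ELECTRON, ghz_per_mt

#: Lower manifolds M_s of the five allowed Delta M_s = 1 transitions.
MS_LOWER: Tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5)

#: All six M_s manifolds of S = 5/2.
MS_ALL: Tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)

#: The four turning points used for the (D, E) read-off.
READOFF_LABELS: Tuple[Tuple[str, float], ...] = (
    ("zz", -2.5),
    ("zz", -1.5),
    ("xx", -2.5),
    ("yy", -2.5),
)


class SpinModelError(ValueError):
    """Invalid spin-model input (labelled error per the package contract)."""


@dataclass(frozen=True)
class SpectrometerSettings:
    """Observation frequency (GHz), electronic g-value and temperature (K)."""

    nu_obs_ghz: float = 94.0
    g: float = G_ELECTRON
    temperature_k: float = 6.0

    def __post_init__(self) -> None:
        if self.nu_obs_ghz <= 0:
            raise SpinModelError("nu_obs must be positive")
        if not 1.5 <= self.g <= 2.5:
            raise SpinModelError(f"g = {self.g} outside the plausible [1.5, 2.5]")
        if self.temperature_k <= 0:
            raise SpinModelError("temperature must be positive")

    @property
    def ghz_per_mt(self) -> float:
        return ghz_per_mt(self.g)

    @property
    def center_field_mt(self) -> float:
        """Resonance field of a g-only spin, nu_obs*h/(g*beta), in mT."""
        return self.nu_obs_ghz / self.ghz_per_mt


@dataclass
class ZFSParameters:
    """Zero-field interaction: signed axial D and rhombic E, both in GHz.

    The standard convention 0 <= E <= |D|/3 is enforced; pass
    ``allow_noncanonical=True`` to carry values outside it (e.g. a raw
    read-off result that should be inspected rather than rejected).
    """

    d_ghz: float
    e_ghz: float = 0.0
    allow_noncanonical: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.allow_noncanonical:
            return
        if self.d_ghz == 0:
            raise SpinModelError("D must be non-zero")
        if self.e_ghz < -1e-12 or self.e_ghz > abs(self.d_ghz) / 3 + 1e-9:
            raise SpinModelError(
                f"E = {self.e_ghz} GHz violates 0 <= E <= |D|/3 for "
                f"D = {self.d_ghz} GHz; use canonicalize_zfs() first"
            )

    @property
    def rhombicity(self) -> float:
        return self.e_ghz / abs(self.d_ghz)


def canonicalize_zfs(d_ghz: float, e_ghz: float) -> ZFSParameters:
    """Map an arbitrary (D, E) pair to the standard 0 <= E <= |D|/3 frame.

    Works by rebuilding the three traceless principal values, assigning the
    unique axis to the largest-magnitude one and choosing the x/y order that
    makes E non-negative.  Identity on already-canonical input.
    """
    lam = np.array([-d_ghz / 3 + e_ghz, -d_ghz / 3 - e_ghz, 2 * d_ghz / 3])
    iz = int(np.argmax(np.abs(lam)))
    ix, iy = [i for i in range(3) if i != iz]
    d_new = 1.5 * lam[iz]
    e_new = abs(lam[ix] - lam[iy]) / 2
    if d_new == 0:
        raise SpinModelError("degenerate zero-field tensor (D = 0)")
    return ZFSParameters(float(d_new), float(e_new))


@dataclass(frozen=True)
class Orientation:
    """Field direction in the zero-field frame (polar from D_zz, azimuth from D_xx)."""

    theta_zf: float
    phi_zf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_zf <= math.pi + 1e-12:
            raise SpinModelError("theta_zf must lie in [0, pi]")
        if not 0.0 <= self.phi_zf < 2 * math.pi + 1e-12:
            raise SpinModelError("phi_zf must lie in [0, 2*pi)")


CANONICAL_ORIENTATIONS: Dict[str, Orientation] = {
    "zz": Orientation(0.0, 0.0),
    "xx": Orientation(math.pi / 2, 0.0),
    "yy": Orientation(math.pi / 2, math.pi / 2),
}


@dataclass(frozen=True)
class TransitionLabel:
    """One canonical turning point: lower manifold M_s and principal axis."""

    ms_lower: float
    axis: str

    def __post_init__(self) -> None:
        _check_ms(self.ms_lower)
        if self.axis not in ("xx", "yy", "zz"):
            raise SpinModelError(f"axis must be xx/yy/zz, got {self.axis!r}")


@dataclass
class TurningPointSet:
    """Labelled turning-point fields (mT) keyed by (axis, M_s lower)."""

    positions: Dict[Tuple[str, float], float]
    center_mt: float

    def __getitem__(self, key: Tuple[str, float]) -> float:
        return self.positions[key]

    def offset(self, key: Tuple[str, float]) -> float:
        """Field offset from the centre field, mT (sign preserved)."""
        return self.positions[key] - self.center_mt

    def require(self, labels: Iterable[Tuple[str, float]] = READOFF_LABELS) -> None:
        missing = [k for k in labels if k not in self.positions]
        if missing:
            raise SpinModelError(f"turning points missing labels: {missing}")


def _check_ms(ms: float) -> float:
    if ms not in MS_LOWER:
        raise SpinModelError(
            f"M_s = {ms} is not a valid lower manifold of a Delta M_s = 1 "
            f"transition; expected one of {MS_LOWER}"
        )
    return ms


def zfs_angular_factor(zfs: ZFSParameters, orient: Orientation) -> float:
    """The orientation bracket D*(3cos^2 t - 1) + 3E*sin^2 t*cos 2p, GHz.

    At theta = pi/2 this spans -D +/- 3E as phi varies, the equatorial span
    of the zero-field interaction.
    """
    ct = math.cos(orient.theta_zf)
    st2 = 1.0 - ct * ct
    return zfs.d_ghz * (3 * ct * ct - 1) + 3 * zfs.e_ghz * st2 * math.cos(
        2 * orient.phi_zf
    )


def firstorder_shift(zfs: ZFSParameters, orient: Orientation, ms: float) -> float:
    """First-order transition-frequency shift (GHz) for M_s <-> M_s + 1."""
    _check_ms(ms)
    return (ms + 0.5) * zfs_angular_factor(zfs, orient)


def resonance_field(
    settings: SpectrometerSettings,
    zfs: ZFSParameters,
    orient: Orientation,
    ms: float,
) -> float:
    """First-order resonance field B_res = (nu_obs - shift) / (g*beta/h), mT."""
    shift = firstorder_shift(zfs, orient, ms)
    b = (settings.nu_obs_ghz - shift) / settings.ghz_per_mt
    if b <= 0:
        raise SpinModelError(
            f"non-positive resonance field ({b:.1f} mT): unphysical "
            "zero-field / frequency combination"
        )
    return b


def canonical_positions(
    settings: SpectrometerSettings,
    zfs: ZFSParameters,
    manifolds: Iterable[float] = (-2.5, -1.5),
) -> TurningPointSet:
    """Turning-point fields at the canonical orientations for ``manifolds``."""
    positions = {
        (axis, ms): resonance_field(settings, zfs, orient, ms)
        for axis, orient in CANONICAL_ORIENTATIONS.items()
        for ms in manifolds
    }
    return TurningPointSet(positions, settings.center_field_mt)


def invert_turning_points(
    tp: TurningPointSet, settings: SpectrometerSettings
) -> ZFSParameters:
    """Read (D, E) off the four labelled turning points.

    The offsets obey dB(zz,-5/2) = 4D/(g beta/h), dB(zz,-3/2) = 2D/(g beta/h)
    and dB(xx,-5/2) - dB(yy,-5/2) = 12E/(g beta/h).  Both parameters are read
    from differences of turning-point fields (D from the two zz points, E
    from xx minus yy), so the inversion is exact on canonical positions and a
    rigid field shift of all four positions cancels out.  A recovered
    E/|D| > 1/3 indicates mislabelled features; it is returned flagged with a
    warning rather than rejected.
    """
    tp.require()
    conv = settings.ghz_per_mt  # GHz per mT
    d = conv * (tp[("zz", -2.5)] - tp[("zz", -1.5)]) / 2.0
    e = conv * (tp[("xx", -2.5)] - tp[("yy", -2.5)]) / 12.0
    if d == 0 or e < 0 or e > abs(d) / 3 + 1e-9:
        warnings.warn(
            f"recovered (D, E) = ({d:.3f}, {e:.3f}) GHz outside the canonical "
            "convention; returning non-canonical values",
            stacklevel=2,
        )
        return ZFSParameters(d, e, allow_noncanonical=True)
    return ZFSParameters(d, e)


def boltzmann_weights(
    settings: SpectrometerSettings, field_mt: float
) -> Dict[float, float]:
    """Relative populations of the six manifolds, Zeeman energies only."""
    x = (
        settings.g
        * BOHR_MAGNETON
        * (field_mt * 1e-3)
        / (BOLTZMANN * settings.temperature_k)
    )
    w = np.exp(-np.array(MS_ALL) * x)
    w /= w.sum()
    return dict(zip(MS_ALL, w))


def boltzmann_weight(
    settings: SpectrometerSettings, field_mt: float, ms: float
) -> float:
    """Population of manifold ``ms`` under E(M_s) = M_s * g * beta * B."""
    if ms not in MS_ALL:
        raise SpinModelError(f"M_s = {ms} is not a valid S=5/2 manifold")
    return boltzmann_weights(settings, field_mt)[ms]


# ---------------------------------------------------------------------------
# Exact-diagonalization oracle (testing only; the production path is the
# closed-form first-order arithmetic above).
# ---------------------------------------------------------------------------

def spin_matrices(s: float = 2.5) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian spin matrices (Sx, Sy, Sz) in the |s, m> basis, m descending."""
    m = np.arange(s, -s - 1, -1.0)
    n = len(m)
    sz = np.diag(m)
    sp = np.zeros((n, n))
    for i in range(1, n):
        sp[i - 1, i] = math.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    sm = sp.T
    sx = (sp + sm) / 2
    sy = (sp - sm) / (2j)
    return sx, sy.astype(complex), sz


def hamiltonian_ghz(
    settings: SpectrometerSettings,
    zfs: ZFSParameters,
    orient: Orientation,
    field_mt: float,
) -> np.ndarray:
    """Full 6x6 Zeeman + zero-field Hamiltonian, in GHz, field along ``orient``."""
    sx, sy, sz = spin_matrices()
    n = np.array(
        [
            math.sin(orient.theta_zf) * math.cos(orient.phi_zf),
            math.sin(orient.theta_zf) * math.sin(orient.phi_zf),
            math.cos(orient.theta_zf),
        ]
    )
    zeeman = settings.ghz_per_mt * field_mt * (n[0] * sx + n[1] * sy + n[2] * sz)
    s = 2.5
    h = (
        zeeman
        + zfs.d_ghz * (sz @ sz - s * (s + 1) / 3 * np.eye(6))
        + zfs.e_ghz * (sx @ sx - sy @ sy)
    )
    return h


def exact_transition_ghz(
    settings: SpectrometerSettings,
    zfs: ZFSParameters,
    orient: Orientation,
    field_mt: float,
    ms: float,
) -> float:
    """Exact M_s <-> M_s+1 transition frequency (GHz) at ``field_mt``.

    Eigenvalues are sorted ascending; at high field they map one-to-one onto
    M_s = -5/2 ... +5/2 because the Zeeman term dominates.
    """
    _check_ms(ms)
    ev = np.linalg.eigvalsh(hamiltonian_ghz(settings, zfs, orient, field_mt))
    idx = int(ms + 2.5)
    return float(ev[idx + 1] - ev[idx])
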