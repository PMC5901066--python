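"""Synthetic fixtures: toy active sites, tensor sets and noisy spectra.

No spectroscopic raw data are deposited for this system, so every stage of
the pipeline is exercised against synthetic inputs built here.  The toy
active site is an idealized trigonal-bipyramidal Mn(II) centre with the
ligand set of Mn/Fe superoxide dismutases: His26 nitrogen and a water on the
axial positions, Asp167 carboxylate oxygen plus the His81/His171 nitrogens
equatorial.  Heavy-atom distances follow the S. aureus Mn(Mn)SOD crystal
geometry (Mn-O_water 2.22 A, Mn-O_delta2 2.09 A); hydrogens are placed with
standard covalent geometry (O-H 0.97 A, H-O-H 104.5 deg, ring C-H 1.08 A
in-plane) because crystal structures of this resolution do not resolve them.
The water protons are oriented to sit near 2.62 and 2.91 A from the metal,
the geometry inferred for the H_w'/H_w pair.  The His171 imidazole ring
dihedral relative to the O_water-Mn-N_His26 axis is the variant switch:
+30 deg for the Mn-specific-like site, -60 deg for the Fe-specific-like one.

Hyperfine tensors are derived from the geometry through the point-dipole
model; 14N tensors and quadrupoles are parametric synthetic stand-ins (no
electronic-structure calculation is performed here), with magnitudes chosen
to give the His26 epsilon-nitrogen its 4 MHz maximal coupling along the
pseudo-symmetry axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .dipole_geometry import point_dipole_t, t_to_principal
from .fieldsweep import Spectrum
from .orientation_select import EulerAngles, HyperfineTensor, QuadrupoleTensor
from .frame_search import TensorSet
from .spin_core import SpinModelError

# Construction constants (Angstrom / degrees)
MN_O_WATER = 2.22
MN_O_ASP = 2.09
MN_N_HIS = 2.15
O_H_BOND = 0.97
H_O_H_ANGLE = 104.5
RING_BOND = 1.37
RING_CH = 1.08
WATER_H_TARGETS = (2.62, 2.91)  # Mn-H distances of H_w' and H_w

DEFAULT_AISO = {"H_w_prime": 0.0, "H_w": -0.45, "ring_h": 0.0}
#: Parametric 14N stand-in: A_iso + 2T = 4 MHz along the Mn-N bond.
N_HIS26_AISO = 2.0
N_HIS26_T = 1.0
N_QUAD_PZZ = 0.8  # synthetic placeholder magnitude


@dataclass
class ToySite:
    """3-D coordinates (A) of the model active site, Mn at the origin."""

    coords: Dict[str, np.ndarray]
    ring_dihedral_his171_deg: float
    variant: str
    rng_seed: int

    def distance(self, a: str, b: str = "Mn") -> float:
        return float(np.linalg.norm(self.coords[a] - self.coords[b]))

    def unit(self, a: str, b: str = "Mn") -> np.ndarray:
        v = self.coords[a] - self.coords[b]
        return v / np.linalg.norm(v)


def _water_hydrogens(o_pos: np.ndarray, phi0: float = 0.0) -> Dict[str, np.ndarray]:
    """Place the two water H so their Mn distances hit the target pair.

    The polar angle of each O-H bond from the O->Mn direction follows from
    the law of cosines; the azimuthal split is then fixed by the H-O-H angle.
    """
    d_mo = np.linalg.norm(o_pos)
    gammas = []
    for r in WATER_H_TARGETS:
        c = (d_mo**2 + O_H_BOND**2 - r**2) / (2 * d_mo * O_H_BOND)
        gammas.append(math.acos(max(-1.0, min(1.0, c))))
    g1, g2 = gammas
    chh = math.cos(math.radians(H_O_H_ANGLE))
    cdphi = (chh - math.cos(g1) * math.cos(g2)) / (math.sin(g1) * math.sin(g2))
    dphi = math.acos(max(-1.0, min(1.0, cdphi)))
    u = -o_pos / d_mo  # O -> Mn direction
    # orthonormal basis around u
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    out = {}
    for name, g, phi in (
        ("H_w_prime", g1, phi0),
        ("H_w", g2, phi0 + dphi),
    ):
        d = (
            math.cos(g) * u
            + math.sin(g) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        out[name] = o_pos + O_H_BOND * d
    return out


def _imidazole(
    u: np.ndarray, v: np.ndarray, d_mn_n: float, label: str
) -> Dict[str, np.ndarray]:
    """Planar regular-pentagon imidazole ligating through N_eps along ``u``.

    ``v`` is the in-plane direction perpendicular to the Mn-N bond (the ring
    dihedral rotates it).  Returns the ligating nitrogen and the two flanking
    CH protons (the H2/H5-type ring protons).
    """
    circum = RING_BOND / (2 * math.sin(math.pi / 5))
    center = (d_mn_n + circum) * u
    out = {f"N_eps_{label}": d_mn_n * u}
    for tag, ang_deg in (("H2", 108.0), ("H5", 252.0)):
        ang = math.radians(ang_deg)
        direction = math.cos(ang) * u + math.sin(ang) * v
        out[f"{tag}_{label}"] = center + (circum + RING_CH) * direction
    return out


def build_toy_site(
    variant: str = "MnSOD_like", seed: int = 0, jitter_a: float = 0.005
) -> ToySite:
    """Idealized SOD active site; the variant flag only moves the His171 ring.

    Molecular frame: z along Mn->N_His26 (the O_water-Mn-N_His26 pseudo
    symmetry axis), x along Mn->O_delta2(Asp167).  ``seed`` drives a small
    Gaussian jitter (sigma ``jitter_a``) so repeated builds are deterministic
    but distinct across seeds.
    """
    if variant not in ("MnSOD_like", "FeSOD_like"):
        raise SpinModelError(f"unknown variant {variant!r}")
    dihedral = 30.0 if variant == "MnSOD_like" else -60.0

    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    coords: Dict[str, np.ndarray] = {"Mn": np.zeros(3)}
    coords["N_eps_His26"] = MN_N_HIS * z
    coords["O_water"] = -MN_O_WATER * z
    coords["O_delta2_Asp167"] = MN_O_ASP * x
    coords.update(_water_hydrogens(coords["O_water"]))

    # His26 ring in the xz plane (its plane orientation is not a variant knob)
    coords.update(_imidazole(z, x, MN_N_HIS, "His26"))
    # equatorial histidines at +/-120 deg from Asp167 in the xy plane
    u81 = np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])
    u171 = np.array([math.cos(math.radians(-120)), math.sin(math.radians(-120)), 0.0])
    coords.update(_imidazole(u81, z, MN_N_HIS, "His81"))
    # His171 ring plane tilted by the variant dihedral relative to the z axis
    e2 = np.cross(u171, z)
    v171 = math.cos(math.radians(dihedral)) * z + math.sin(math.radians(dihedral)) * e2
    coords.update(_imidazole(u171, v171, MN_N_HIS, "His171"))

    rng = np.random.default_rng(seed)
    if jitter_a > 0:
        for name in coords:
            if name != "Mn":
                coords[name] = coords[name] + rng.normal(0.0, jitter_a, 3)

    site = ToySite(coords, dihedral, variant, seed)
    for a, b, lo in (("O_water", "Mn", 0.9), ("O_delta2_Asp167", "Mn", 0.9)):
        if site.distance(a, b) < lo:
            raise SpinModelError("degenerate toy-site geometry")
    return site


def _frame_along(u: np.ndarray) -> EulerAngles:
    """ZYZ Euler angles whose rotated z-axis points along unit vector ``u``."""
    theta = math.acos(max(-1.0, min(1.0, u[2])))
    phi = math.atan2(u[1], u[0]) % (2 * math.pi)
    return EulerAngles(phi, theta, 0.0)


RING_PROTONS = (
    "H2_His26",
    "H5_His26",
    "H2_His81",
    "H5_His81",
    "H2_His171",
    "H5_His171",
)


def tensors_from_site(
    site: ToySite, aiso_map: Optional[Dict[str, float]] = None
) -> TensorSet:
    """Point-dipole hyperfine tensors for every placed proton, plus the
    parametric His26 epsilon-nitrogen tensor and its synthetic quadrupole."""
    aiso = dict(DEFAULT_AISO)
    if aiso_map:
        aiso.update(aiso_map)

    hyperfine: Dict[str, HyperfineTensor] = {}
    for name in ("H_w_prime", "H_w", *RING_PROTONS):
        if name not in site.coords:
            raise SpinModelError(f"toy site is missing atom {name}")
        r = site.distance(name)
        t = point_dipole_t(r, "1H")
        a_iso = aiso.get(name, aiso["ring_h"] if name in RING_PROTONS else 0.0)
        hyperfine[name] = HyperfineTensor(
            nucleus="1H",
            a_iso_mhz=a_iso,
            t_principal_mhz=t_to_principal(t),
            frame=_frame_along(site.unit(name)),
            identity=name,
        )

    u_n = site.unit("N_eps_His26")
    hyperfine["N_eps_His26"] = HyperfineTensor(
        nucleus="14N",
        a_iso_mhz=N_HIS26_AISO,
        t_principal_mhz=t_to_principal(N_HIS26_T),
        frame=_frame_along(u_n),
        identity="N_eps_His26",
    )
    quadrupole = {
        "N_eps_His26": QuadrupoleTensor(
            (-N_QUAD_PZZ / 2, -N_QUAD_PZZ / 2, N_QUAD_PZZ), frame=_frame_along(u_n)
        )
    }
    return TensorSet(hyperfine, quadrupole, source="synthetic")


def add_noise(spec: Spectrum, snr: float, seed: int = 0) -> Spectrum:
    """Additive white Gaussian noise with sigma = max amplitude / snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.abs(spec.amplitude).max() / snr
    noisy = spec.amplitude + rng.normal(0.0, sigma, len(spec.amplitude))
    return Spectrum(spec.axis.copy(), noisy, kind=spec.kind,
                    meta={**spec.meta, "snr": snr, "noise_seed": seed})
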