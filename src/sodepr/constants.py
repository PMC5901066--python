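"""Physical constants (CODATA 2018) and the nucleus registry.

Unit conventions used throughout the package: zero-field and microwave
frequencies in GHz, nuclear couplings and frequency offsets in MHz, magnetic
fields in mT, distances in Angstrom, angles in radians internally (degrees at
all file/CLI boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

PLANCK = 6.62607015e-34  # J s
BOHR_MAGNETON = 9.2740100783e-24  # J/T
NUCLEAR_MAGNETON = 5.0507837461e-27  # J/T
BOLTZMANN = 1.380649e-23  # J/K
MU0_OVER_4PI = 1e-7  # T^2 m^3 / J

#: Default isotropic electronic g-value. High-spin Mn(II) is within ~1e-3 of
#: the free-electron value; using g = 2.00 instead changes the point-dipole
#: prefactor by < 0.2%, below every tolerance in this package.
G_ELECTRON = 2.0023


@dataclass(frozen=True)
class Nucleus:
    """An NMR-active isotope: spin quantum number and nuclear g-factor."""

    name: str
    spin: float
    g_n: float

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))

    def nmr_frequency_mhz(self, field_mT: float) -> float:
        """Nuclear Larmor frequency nu_NMR at ``field_mT``, in MHz."""
        field_T = field_mT * 1e-3
        return self.g_n * NUCLEAR_MAGNETON * field_T / PLANCK * 1e-6


#: Registry of the nuclei relevant to SOD ligand-sphere spectroscopy.
NUCLEI = {
    "1H": Nucleus("1H", 0.5, 5.5856946893),
    "14N": Nucleus("14N", 1.0, 0.4037610),
}


def get_nucleus(nucleus: "Nucleus | str") -> Nucleus:
    if isinstance(nucleus, Nucleus):
        return nucleus
    try:
        return NUCLEI[nucleus]
    except KeyError:
        raise KeyError(
            f"unknown nucleus {nucleus!r}; registered: {sorted(NUCLEI)}"
        ) from None


def ghz_per_mt(g: float) -> float:
    """Electron Zeeman conversion factor g*beta/h expressed in GHz per mT."""
    return g * BOHR_MAGNETON / PLANCK * 1e-12
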