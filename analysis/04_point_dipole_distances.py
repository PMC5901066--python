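"""Point-dipole geometry: couplings to Mn-H distances and the distance ruler.

Converts the water-proton dipolar couplings to metal-proton distances via
the r^-3 law and quantifies how sharp a ruler the coupling is: the
sensitivity dr = r*dT/(3T) turns the 100 kHz reproducibility of the H_w'
resonance position into a ~0.03 A bound on structural variation between the
active and inactive proteins.  Both readings of a 100 kHz spectral shift are
tabulated: as a coupling shift directly, and as a line-position shift that
scales down by |M_s| before reaching the coupling.
"""

from pathlib import Path

import pandas as pd

from sodepr.dipole_geometry import (
    aeff_from_geometry,
    distance_from_t,
    distance_sensitivity,
    point_dipole_t,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    rows = []
    for name, t_dft, theta, r_dft, a_iso in (
        ("H_w_prime", 4.1, 22.0, 2.62, 0.0),
        ("H_w", 3.3, 17.0, 2.91, -0.45),
    ):
        rows.append(
            {
                "proton": name,
                "T_dft_MHz": t_dft,
                "A_iso_MHz": a_iso,
                "r_dft_A": r_dft,
                "T_point_dipole_MHz": point_dipole_t(r_dft),
                "r_from_T_A": distance_from_t(t_dft),
                "A_eff_MHz": aeff_from_geometry(a_iso, t_dft, theta),
            }
        )
    df = pd.DataFrame(rows)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

    dr_coupling = distance_sensitivity(2.91, 3.3, 0.100)
    dr_line_52 = distance_sensitivity(2.91, 3.3, 0.100 / 2.5)
    print(
        f"\n100 kHz shift read as a coupling shift   -> dr = {dr_coupling:.3f} A"
        f"\n100 kHz shift read as a -5/2 line shift  -> dr = {dr_line_52:.3f} A"
    )
    df["dr_100kHz_A"] = dr_coupling
    out = ROOT / "results" / "point_dipole_distances.csv"
    df.to_csv(out, index=False, float_format="%.4f")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
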