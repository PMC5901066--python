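# sodepr

High-field EPR / ENDOR / ELDOR-NMR analysis of Mn(II)-substituted superoxide
dismutase (SOD) active sites.

Mn- and Fe-specific SODs bind either metal but are catalytically active only
with their own, and the structural cause is invisible at crystallographic
resolution. Two spectroscopic observables discriminate the proteins anyway:
the Mn(II) zero-field interaction (axial parameter *D*, rhombic parameter
*E*) read off 94 GHz powder field-swept echo spectra, and the ligand-proton
and nitrogen hyperfine couplings measured orientation-selectively by ENDOR
and ELDOR-detected NMR. This package implements that inference chain for
S = 5/2 Mn(II) as a tested library plus a set of narrative analysis scripts:

- **`spin_core`** — first-order spin-Hamiltonian arithmetic: the
  *M*<sub>s</sub> ↔ *M*<sub>s</sub>+1 transition shift
  (*M*<sub>s</sub> + ½)·[*D*(3cos²θ − 1) + 3*E* sin²θ cos 2φ], canonical
  turning-point fields, and their exact inversion back to (*D*, *E*); an
  exact 6×6 diagonalization serves as the testing oracle.
- **`fieldsweep`** — orientation-averaged (powder) simulation of the
  field-swept echo spectrum with 6 K Boltzmann weighting, and automated
  location/labelling of the four read-off turning points
  (*D*<sub>zz,−5/2</sub>, *D*<sub>zz,−3/2</sub>, *D*<sub>xx,−5/2</sub>,
  *D*<sub>yy,−5/2</sub>).
- **`orientation_select`** — which molecular orientations resonate at a
  chosen field, and the secular projection
  *A*<sub>eff</sub> = *A*<sub>iso</sub> + n̂ᵀ·T·n̂ of a hyperfine tensor onto
  the field direction.
- **`endor_eldor`** — single- and multi-quantum line positions on the
  positive branch (offset = −*M*<sub>s</sub>·*q*·*A*<sub>eff</sub>),
  first-order ¹⁴N quadrupole splitting (which cancels in single-nucleus DQ
  transitions), Gaussian-mixture synthesis, deterministic multi-start
  component fitting, and DQ combination edges.
- **`dipole_geometry`** — the point-dipole model
  *T* = (μ₀/4π)·g<sub>e</sub>β<sub>e</sub>g<sub>n</sub>β<sub>n</sub>/(h r³)
  (≈ 79.1 MHz·Å³ for ¹H), its inversion r(*T*), and the distance
  sensitivity dr = r·d*T*/(3*T*).
- **`frame_search`** — brute-force ZYZ Euler search orienting the zero-field
  frame in the molecular frame against measured couplings and an ENDOR
  window, with tensor symmetrization and clamped *A*<sub>iso</sub>
  adjustment.
- **`synthetic_data`** — a toy trigonal-bipyramidal Mn site with standard
  hydrogen geometry, point-dipole tensor sets with known frames, and seeded
  noise, so every stage is testable without any deposited data.

## Worked example

```python
import sodepr as s
from sodepr.presets import W_BAND, ZFS_PRESETS

spec = s.simulate_fieldsweep(W_BAND, ZFS_PRESETS["Mn(Mn)SOD"],
                             linewidth_mt=10.0, transitions=(-2.5, -1.5))
est = s.extract_zfs(spec, W_BAND, linewidth_mt=10.0)
print(f"D = {est.zfs.d_ghz:.2f} GHz, E = {est.zfs.e_ghz:.2f} GHz, "
      f"|D|+E = {abs(est.zfs.d_ghz) + est.zfs.e_ghz:.2f} GHz")
```

prints

```
D = -10.59 GHz, E = 0.63 GHz, |D|+E = 11.22 GHz
```

i.e. the simulated powder spectrum of the Mn-specific protein inverts back
to its generating zero-field parameters (−10.60, 0.63), and the |D| + E
activity marker lands above the 10.9 GHz threshold that separates active
Mn-loaded SODs from the inactive Fe-protein loaded with Mn.

The numbered scripts under `analysis/` run the full study in order:
simulate the three proteins' field sweeps (`01`), read (*D*, *E*) back off
them (`02`), work through the ELDOR-NMR line-position algebra at the
*D*<sub>zz,−5/2</sub> edge (`03`), convert couplings to Mn–H distances and
the 0.03 Å ruler (`04`), and orient the zero-field frame on the synthetic
site, recovering *D*<sub>zz</sub> along the Mn–N<sub>His26</sub>
pseudo-symmetry axis (`05`). Each writes its tables under `results/`. A
small `sodepr` CLI wraps the same stages for shell use (`sodepr --help`).

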