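# Methods

## Spin model and regime of validity

The electron spin is high-spin Mn(II), S = 5/2, in a strong field
(94.0 GHz / ~3.35 T). The Hamiltonian is the electron Zeeman term plus the
zero-field interaction,

    H = g β B·S + D [S_z² − S(S+1)/3] + E [S_x² − S_y²],

with |D| ≈ 10–11 GHz and E/|D| ≲ 0.06 for the SOD sites, i.e. the Zeeman
term dominates by an order of magnitude. All production computations are
first order in the zero-field interaction: the M_s ↔ M_s+1 transition at
field orientation (θ_zf, φ_zf) in the zero-field frame is shifted from
g β B/h by

    (M_s + ½) · [ D (3cos²θ_zf − 1) + 3E sin²θ_zf cos 2φ_zf ]   (GHz).

At θ_zf = π/2 the bracket spans −D ± 3E, the equatorial span of the
interaction. An exact 6×6 diagonalization is included for testing only.
Its verdict on the first-order arithmetic: at the three canonical
(turning-point) orientations the error stays below 5·D²/ν_obs (worst
empirical coefficient 3.44), while at arbitrary intermediate orientations
the second-order coefficient for the outer transitions reaches ≈ 14. The
read-off only ever evaluates canonical orientations, so the production
path operates where the approximation is tightest. No second-order
corrections, relaxation, or pulse-response (echo formation) physics are
modelled.

Unit conventions: GHz for electron-spin frequencies, MHz for nuclear
couplings and offsets, mT for fields, Å for distances; radians internally,
degrees at every file/CLI boundary. Conversions use CODATA constants with
g = 2.0023; using g = 2.00 would change the point-dipole prefactor by
< 0.2 %, below every tolerance used anywhere.

The zero-field convention is 0 ≤ E ≤ |D|/3 with signed D;
`canonicalize_zfs` maps any (D, E) pair into it by rebuilding the traceless
principal values. D < 0 throughout for these sites; the sign is taken from
the input or, in extraction, from which side of the spectrum carries the
weak zz step (the sign hypothesis test below).

## Powder simulation

`simulate_fieldsweep` sums, over a solid-angle-weighted orientation grid
and the requested ΔM_s = 1 transitions, Gaussian absorption lines centred
at the first-order resonance field. Line amplitude is solid-angle weight ×
Boltzmann population of the lower manifold under Zeeman-only energies
E(M_s) = M_s·gβB evaluated at each line's own resonance field — at 6 K
this makes the −5/2 ↔ −3/2 and −3/2 ↔ −1/2 transitions dominant, as
observed. Transition-moment factors |⟨M_s+1|S₊|M_s⟩|² are deliberately
omitted (echo amplitudes depend on pulse conditions that are out of scope);
this changes relative intensities but no line position, and the extraction
only uses positions.

Implementation: stick positions are histogrammed onto the field axis and
convolved once with the unit-area Gaussian line kernel — identical to the
explicit per-line sum to within half an axis step (default step =
linewidth/10). The default orientation grid is 501 × 721 over the
hemisphere: at the 91 × 181 that suffices for orientation-selection
queries, the histogram shows grid ripple above the linewidth scale that
floods the feature detector; at 501 × 721 the pattern is ripple-free and a
full simulation still takes ≈ 0.3 s. The default axis spans every canonical
position plus five linewidths of signal-free padding — the padding is also
what the noise-floor estimator (below) keys on. The ⁵⁵Mn hyperfine sextet
is cosmetic at this scale and is not simulated; the read-off uses envelope
positions.

## Turning-point location and (D, E) read-off

The four labelled turning points obey three exact first-order identities,
all used by the locator:

1. ΔB(zz,−3/2) = ΔB(zz,−5/2)/2 (offsets from the centre field ν_obs/gβ);
2. ΔB(xx,−5/2) + ΔB(yy,−5/2) = −ΔB(zz,−5/2);
3. every −3/2 feature replicates its −5/2 partner at exactly half offset.

Candidate features are amplitude peaks (powder divergences) and extrema of
the smoothed derivative (step edges — the inflection of a
Gaussian-broadened step sits exactly at the step). Smoothing is
Savitzky–Golay (quadratic, 21-point default window on a linewidth/10 axis);
prominence thresholds are the larger of a small fraction of the global
maximum (0.2 %) and a noise-adaptive floor, 4× the median absolute
deviation of the signal-free outer tenths of the axis. Both signs of D are
tried (or only sign(D) of a supplied guess):

- the zz,−5/2 step is the outermost weak edge near the sustained 5 %
  amplitude onset (a crossing must persist for three linewidths, so
  smoothing-correlated noise excursions cannot define the spectral end);
  its amplitude must stay below 35 % of the maximum, because the zz step is
  always the weakest labelled feature;
- the interior divergence (yy for D < 0, xx for D > 0) must be an amplitude
  peak comparable to the strongest off-centre peak, and the outer edge must
  lie at or beyond it; each (divergence, edge) pair is validated against
  its strong half-offset −3/2 replicas and, when the zz edge was found,
  against identity (2); ranking prefers the outermost supported edge;
- when the outer step is tall enough to govern the spectral end, its
  position is cross-checked against the sustained onset;
- zz positions not directly detectable (weak under noise) are implied from
  identity (2); a directly detected zz,−3/2 candidate is only trusted
  within one linewidth of its predicted half offset.

D is then read from the difference of the two zz points,
D = (gβ/h)(B_zz,−5/2 − B_zz,−3/2)/2, and E from
E = (gβ/h)(B_xx,−5/2 − B_yy,−5/2)/12 — both differences of fields, so a
rigid field offset cancels exactly. Reported uncertainties propagate half a
linewidth per located field through these linear relations.

Validated behaviour on synthetic spectra: exact recovery (≤ 0.01 GHz) for
all three protein parameter sets across three transition subsets; 50/50
random (D, E) in the SOD regime recovered within 2 % / 0.1 GHz noise-free;
150 SNR-20 noisy realizations across the three proteins all within 2.2 %
in D with zero sign confusions. Pure-noise input is rejected via its large
negative excursions (an absorption powder pattern has none).

## Orientation selection and effective couplings

At a fixed field inside the powder pattern only orientations whose
first-order resonance field falls within the excitation bandwidth
contribute; at the extreme low-field edge (D < 0) that set collapses to
θ_zf ≈ 0 and at the high-field edge to the D_yy direction. Hyperfine
tensors enter through the secular projection
A_eff = A_iso + n̂ᵀ·T_mol·n̂. Pseudo-secular terms are neglected: the ¹H
Larmor frequency at the fields used is 79–185 MHz against couplings
≤ 7 MHz, so state mixing is of order (T/ν_NMR)² ≲ 10⁻³. Euler angles are
ZYZ intrinsic everywhere; a worked example: (α, β, γ) = (φ, θ, 0) rotates
the laboratory z-axis onto the direction with spherical angles (θ, φ), so a
tensor whose unique axis points along a Mn–H bond carries frame
(azimuth, polar, 0) of that bond.

## ELDOR-NMR / ENDOR line algebra

On the positive branch (ν′ = ν_obs + qν_NMR), a transition of total quantum
order q = Σ|Δm_I| over participating nuclei sits at offset
Σ −M_s·Δm_I·A_eff,i. The inverse, A_eff = −offset/(M_s·q), is what turns
printed spectral positions into couplings. First-order ¹⁴N quadrupole
interaction adds ±(3/2)·n̂ᵀP n̂ to single-quantum lines and cancels exactly
in the single-nucleus double-quantum transition — hence the ¹⁴N DQ doublet
at 20/12 MHz is a clean ruler giving the same 4 MHz coupling from both
manifolds. Spectra are Gaussian mixtures; widths quoted like "5.3 (2.2)"
are interpreted as FWHM (the common spectroscopic convention; σ is
accepted via a converter). The distant-matrix signal is an ordinary
component with A_eff = 0, never an implicit background subtraction.
Manifold weights default to equal across the two manifolds contributing at
a turning-point field, with Boltzmann scaling available. Relative
multi-quantum transition probabilities, where needed, use an isolated,
swappable forbiddenness model ∝ (T/ν_NMR)^2q normalized within each q; no
quantitative claim rests on it.

Component fitting is nonlinear least squares (trust-region reflective)
with a fixed multi-start grid over A_eff seeds spaced 1 MHz inside the
bounds; the best residual wins and exact ties go to the smaller coupling
tuple, making the fit bit-reproducible. 1σ uncertainties come from the
Gauss–Newton covariance. Recovery: exact on noise-free mixtures, within
0.05 MHz over 50 seeds at SNR 15 (tested against a 0.3 MHz requirement).

## Point-dipole geometry

Treating electron and nuclear spins as point dipoles, T = C/r³ with
C = (μ₀/4π)g_eβ_e g_nβ_n/h computed from constants at runtime
(≈ 79.06 MHz·Å³ for ¹H). T denotes the axial parameter of a (−T, −T, +2T)
tensor; converters to/from explicit principal values are provided. The
model reproduces the quantum-chemically derived water-proton dipolar
couplings to within 10 % at their distances (4.40 vs 4.1 MHz at 2.62 Å;
3.21 vs 3.3 MHz at 2.91 Å) — the expected accuracy, since Mn(II) spin
density is not a point. The distance sensitivity dr = r·dT/(3T) is the
exact differential of the r⁻³ law; its linearization error is (2/3)(dT/T)
to leading order, so the implementation agrees with the finite difference
to 5 % for dT/T ≤ 0.075. A 100 kHz shift can be read two ways: as a
coupling shift (dr ≈ 0.029 Å at the H_w geometry — the headline reading)
or as a line-position shift, which scales the coupling shift down by |M_s|
(0.012 Å in the −5/2 manifold). Both are exposed.

## Zero-field frame search

The search orients the zero-field principal axes in the molecular frame by
exhaustive ZYZ scan, scoring each candidate frame by
w₁·RMS(A_eff mismatch at the candidate D_zz)/RMS(targets) +
w₂·relative spectral RMS of a synthesized ENDOR spectrum at the candidate
D_yy against a target window (default −10 to −5 MHz, evaluated through the
M_s = −3/2/−1/2 manifolds with 150 kHz display convolution; the comparison
axis is padded so lines just outside the window contribute their tails
consistently). Weights default to 1/1 with both terms non-dimensionalized.

Because 150 kHz lines make the sharp score basin far narrower than any
affordable grid cell, the scan is coarse-to-fine: the 5° grid is scored at
a 3 MHz comparison width (both sides of the comparison are brought to a
common width with area-normalized lines, so convolution commutes), the best
64 cells are re-scanned at 1° and 0.8 MHz width, and the best 8 fine
candidates receive a deterministic Nelder–Mead polish — competing basins
can only be ranked after each has been locally minimized. Every observable
is quadratic in the field direction, so the score is invariant under the
zero-field tensor's axis-inversion group (identity plus the three 180°
rotations); the full 4-member symmetry orbit is reported and the
recovery metric is the smallest rotation angle modulo that group.

Tensor conditioning mirrors measured-data practice: `symmetrize_tensor`
makes the dipolar part axial by averaging T_xx and T_yy, and `adjust_aiso`
shifts isotropic parts toward the fitted couplings, clamped at ±0.5 MHz
with a warning. On the synthetic site, the conditioned search against the
measured couplings (6.4/5.3/4.0 MHz) places D_zz 1.1° from the
Mn–N_His26 pseudo-symmetry axis and D_xx 1.1° from the Mn–O_Asp167 bond.

A note on identifiability: with only the three measured couplings and the
−10 to −5 MHz window (which contains just the two water-proton lines), a
random frame is genuinely under-determined — distant frames reproduce
those few numbers to within a couple of percent. The frame-recovery test
suite therefore scores against the full ±12 MHz ENDOR window; with it, all
20 random frames are recovered exactly (0.0° modulo symmetry). The narrow
window remains the default for matching measured spectra, where the
pseudo-symmetry-axis prior plays the same disambiguating role.

## Synthetic data: what it emulates and what it does not

`build_toy_site` constructs an idealized trigonal-bipyramidal site: Mn at
the origin, N_His26 on +z at 2.15 Å, water oxygen on −z at 2.22 Å,
O_δ2(Asp167) on +x at 2.09 Å, His81/His171 ε-nitrogens equatorial at
±120°. Hydrogens use standard covalent geometry (O–H 0.97 Å, H–O–H 104.5°,
ring C–H 1.08 Å in-plane, regular-pentagon imidazoles) because the crystal
structures do not resolve them; the water-proton azimuths are solved so the
Mn–H distances land at 2.62/2.91 Å. The His171 ring-plane dihedral relative
to the O_water–Mn–N_His26 axis is the variant switch: +30° (Mn-specific
crystal geometry) vs −60° (the global-optimum geometry associated with the
Fe-specific protein); nothing else differs between variants. A seeded
0.005 Å Gaussian jitter keeps builds deterministic per seed but distinct
across seeds.

Hyperfine tensors follow from the geometry through the point-dipole model
(axial, unique axis along Mn–H). Default isotropic parts: 0 for H_w′,
−0.45 MHz for H_w, 0 for ring protons — consistent with the < 1 MHz and
< 0.1 MHz bounds for these classes. The ring protons land at T ≈ 2.0 MHz,
inside the expected 1.8–2.4 MHz window. The ¹⁴N tensor is parametric, not
ab initio: A_iso = 2.0 and T = 1.0 MHz chosen so the coupling along the
pseudo-symmetry axis is the observed 4 MHz maximum, with a synthetic
placeholder quadrupole (|P_zz| = 0.8 MHz). Tensor sets carry
`source="synthetic"` precisely because no electronic-structure calculation
is performed here — passing tests demonstrate the spectroscopic machinery
is self-consistent, not that the toy site reproduces a real protein's
electronic structure, CM5 charges, or crystallographic detail.

Noise is additive white Gaussian with σ = max amplitude / SNR, seeded.

## Problem sizes and determinism

Default sizes — 501×721 powder grid on a linewidth/10 axis, 5° coarse
Euler grid with 64-cell fine refinement, 50-seed fit-recovery and 20-frame
recovery ensembles — run the full test suite in about six minutes and the
acceptance script in seconds on one core. Every stochastic element
(site jitter, noise realizations, ensemble draws) flows from explicit
integer seeds; fits and searches are deterministic by construction
(fixed multi-start grids, lexicographic tie-breaking), so repeated runs
are bit-identical.

## Known limitations

- First-order line positions only; second-order zero-field effects
  (≈ D²/ν) are quantified by the oracle but not corrected for.
- Echo intensities are schematic (no transition moments, relaxation or
  pulse response), so simulated amplitude ratios are not quantitative.
- The point-dipole model is knowingly ~10 % off for protons this close to
  the Mn(II) spin density; distances inferred from it inherit that bias
  (≈ 3 % in r).
- The ELDOR-NMR forbiddenness intensity model is a placeholder ordering,
  not a calibrated probability.
- The frame search is only as determined as its targets; narrow spectral
  windows require the pseudo-symmetry prior (see above).
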