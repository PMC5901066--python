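"""Orienting the zero-field frame in the molecular frame by brute force.

The double-resonance spectra are measured relative to the zero-field axes
(the field sits along D_zz at the low-field edge, along D_yy at the ENDOR
position), while externally supplied hyperfine/quadrupole tensors live in the
molecular frame.  The three ZYZ Euler angles relating the two frames are
found by exhaustively scanning a grid and scoring each candidate against two
measured constraints:

  (1) the effective couplings of the assigned nuclei with the field along the
      candidate D_zz must reproduce the fitted coupling components, and
  (2) the synthesized ENDOR spectrum with the field along the candidate D_yy
      must match the measured -10 to -5 MHz window.

Because every observable is quadratic in the field direction, the score is
invariant under the zero-field tensor's axis-inversion group (the identity
and the three 180-degree rotations about the frame axes); the full symmetry
orbit of the optimum is reported.

Tensor conditioning mirrors standard practice for Mn(II) ligand protons:
``symmetrize_tensor`` makes the dipolar part axial by averaging T_xx and
T_yy, and ``adjust_aiso`` applies small clamped shifts to the isotropic
parts so the predictions line up with the measured couplings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .fieldsweep import FWHM_TO_SIGMA, Spectrum
from .orientation_select import EulerAngles, HyperfineTensor, QuadrupoleTensor
from .spin_core import SpinModelError


@dataclass
class TensorSet:
    """Named hyperfine (and optional quadrupole) tensors in a common frame."""

    hyperfine: Dict[str, HyperfineTensor]
    quadrupole: Dict[str, QuadrupoleTensor] = field(default_factory=dict)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name, hft in self.hyperfine.items():
            if not hft.identity:
                hft.identity = name

    def __len__(self) -> int:
        return len(self.hyperfine)

    def require(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.hyperfine]
        if missing:
            raise SpinModelError(f"tensor set is missing nuclei: {missing}")


@dataclass
class SearchResult:
    best: EulerAngles
    score: float
    grid_step_deg: float
    symmetry_orbit: List[EulerAngles]
    aeff_rms_mhz: float
    spectral_rms: float
    landscape: Optional[np.ndarray] = None  # columns: alpha, beta, gamma, score (deg)


def symmetrize_tensor(hft: HyperfineTensor) -> HyperfineTensor:
    """Make the dipolar tensor axial by averaging T_xx and T_yy (idempotent)."""
    txx, tyy, tzz = hft.t_principal_mhz
    avg = (txx + tyy) / 2.0
    return HyperfineTensor(
        nucleus=hft.nucleus,
        a_iso_mhz=hft.a_iso_mhz,
        t_principal_mhz=(avg, avg, tzz),
        frame=hft.frame,
        identity=hft.identity,
    )


def adjust_aiso(
    tensors: TensorSet,
    measured: Dict[str, float],
    direction: np.ndarray,
    max_shift_mhz: float = 0.5,
) -> Tuple[TensorSet, Dict[str, float]]:
    """Shift each named tensor's A_iso to match a measured A_eff, clamped.

    ``measured`` maps nucleus identity to the fitted coupling (MHz) with the
    field along ``direction``.  Returns the adjusted set and the applied
    shifts; shifts that would exceed ``max_shift_mhz`` are clamped with a
    warning.
    """
    import warnings

    tensors.require(list(measured))
    n = np.asarray(direction, dtype=float)
    new_h = dict(tensors.hyperfine)
    shifts: Dict[str, float] = {}
    for name, target in measured.items():
        hft = tensors.hyperfine[name]
        predicted = hft.a_iso_mhz + float(n @ hft.dipolar_molecular() @ n)
        shift = target - predicted
        if abs(shift) > max_shift_mhz:
            warnings.warn(
                f"A_iso shift for {name} ({shift:+.2f} MHz) exceeds the "
                f"{max_shift_mhz} MHz clamp; clamped",
                stacklevel=2,
            )
            shift = math.copysign(max_shift_mhz, shift)
        new_h[name] = HyperfineTensor(
            nucleus=hft.nucleus,
            a_iso_mhz=hft.a_iso_mhz + shift,
            t_principal_mhz=tuple(hft.t_principal_mhz),
            frame=hft.frame,
            identity=hft.identity,
        )
        shifts[name] = shift
    return TensorSet(new_h, tensors.quadrupole, tensors.source), shifts


ENDOR_WINDOW_MHZ: Tuple[float, float] = (-10.0, -5.0)
ENDOR_CONVOLUTION_FWHM_MHZ = 0.15
ENDOR_MANIFOLDS: Tuple[float, ...] = (-1.5, -0.5)
#: Axis padding around the comparison window so that lines sitting just
#: outside it still contribute their tails consistently on both sides of the
#: comparison.
ENDOR_PAD_MHZ = 2.5


def _endor_axis(window: Tuple[float, float] = ENDOR_WINDOW_MHZ, step: float = 0.05):
    return np.arange(window[0] - ENDOR_PAD_MHZ, window[1] + ENDOR_PAD_MHZ + step, step)


def _aeff_matrix(tensors: TensorSet, names: Sequence[str], dirs: np.ndarray) -> np.ndarray:
    """A_eff for each direction (n, 3) x nucleus; returns (n, len(names))."""
    out = np.empty((dirs.shape[0], len(names)))
    for j, name in enumerate(names):
        hft = tensors.hyperfine[name]
        t_mol = hft.dipolar_molecular()
        out[:, j] = hft.a_iso_mhz + np.einsum("ni,ij,nj->n", dirs, t_mol, dirs)
    return out


#: Comparison widths for the spectral score term.  The display convolution is
#: 150 kHz, but scoring at that sharpness would give the Euler search a basin
#: far narrower than the grid cell; the coarse scan therefore compares at a
#: broad width (wide basin) and the 1-degree refinement at a sharper one,
#: with both sides of each comparison brought to the same width.
SCORE_WIDTH_FWHM_MHZ = 0.8
SCORE_WIDTH_COARSE_FWHM_MHZ = 3.0


def _endor_amplitudes(
    aeff: np.ndarray,
    axis: np.ndarray,
    fwhm_mhz: float = ENDOR_CONVOLUTION_FWHM_MHZ,
) -> np.ndarray:
    """Both-branch ENDOR Gaussian mixture for coupling matrix (n, k) -> (n, len(axis))."""
    sigma = fwhm_mhz * FWHM_TO_SIGMA
    n = aeff.shape[0]
    amp = np.zeros((n, len(axis)), dtype=np.float32)
    for ms in ENDOR_MANIFOLDS:
        for branch in (+1.0, -1.0):
            pos = branch * (-ms) * aeff  # (n, k)
            d = axis[None, None, :] - pos[:, :, None]
            amp += np.exp(-0.5 * (d / sigma) ** 2).sum(axis=1, dtype=np.float32)
    # area-normalized lines so that comparisons at different widths commute
    # with Gaussian convolution
    amp /= sigma * math.sqrt(2 * math.pi)
    return amp


def predict_constraints(
    tensors: TensorSet,
    euler: EulerAngles,
    names: Optional[Sequence[str]] = None,
    window: Tuple[float, float] = ENDOR_WINDOW_MHZ,
) -> Tuple[Dict[str, float], Spectrum]:
    """Predicted couplings at the D_zz edge and ENDOR spectrum at D_yy.

    ``euler`` rotates the zero-field principal axes into the molecular frame;
    the field direction is the candidate D_zz axis for the couplings and the
    candidate D_yy axis for the ENDOR spectrum, whose comparison ``window``
    defaults to the -10 to -5 MHz region (the axis is padded around it so
    boundary tails are represented).
    """
    if names is None:
        names = list(tensors.hyperfine)
    tensors.require(names)
    r = euler.as_matrix()
    d_zz, d_yy = r[:, 2], r[:, 1]
    aeff_zz = _aeff_matrix(tensors, names, d_zz[None, :])[0]
    couplings = dict(zip(names, map(float, aeff_zz)))
    axis = _endor_axis(window)
    aeff_yy = _aeff_matrix(tensors, names, d_yy[None, :])
    amp = _endor_amplitudes(aeff_yy, axis)[0]
    spec = Spectrum(axis, np.asarray(amp, dtype=float), kind="endor",
                    meta={"axis_unit": "MHz offset", "window": window})
    return couplings, spec


@dataclass
class SearchTargets:
    """Measured constraints: couplings at D_zz and the ENDOR window at D_yy."""

    aeff_mhz: Dict[str, float]
    endor: Optional[Spectrum] = None


_SYMMETRY_ROTATIONS = [
    np.eye(3),
    Rotation.from_euler("x", math.pi).as_matrix(),
    Rotation.from_euler("y", math.pi).as_matrix(),
    Rotation.from_euler("z", math.pi).as_matrix(),
]


def symmetry_orbit(euler: EulerAngles) -> List[EulerAngles]:
    """The four frame orientations indistinguishable to quadratic observables."""
    r = euler.as_matrix()
    return [EulerAngles.from_matrix(r @ c) for c in _SYMMETRY_ROTATIONS]


class _Scorer:
    """Precomputed two-criterion score evaluator at a fixed comparison width."""

    def __init__(
        self,
        tensors: TensorSet,
        targets: SearchTargets,
        weights: Tuple[float, float],
        score_width_mhz: float = SCORE_WIDTH_FWHM_MHZ,
    ) -> None:
        self.tensors = tensors
        self.weights = weights
        self.width = score_width_mhz
        self.names = list(targets.aeff_mhz)
        self.all_names = list(tensors.hyperfine)
        tensors.require(self.names)
        self.target_a = np.array([targets.aeff_mhz[n] for n in self.names])
        self.scale_a = max(float(np.sqrt(np.mean(self.target_a**2))), 1e-9)

        self.use_spec = targets.endor is not None and weights[1] != 0
        if self.use_spec:
            axis = targets.endor.axis
            t_amp = targets.endor.amplitude.astype(np.float32)
            # bring the (150 kHz-sharp) target to the scoring width
            extra = math.sqrt(
                max(score_width_mhz**2 - ENDOR_CONVOLUTION_FWHM_MHZ**2, 0.0)
            )
            if extra > 0:
                step = float(axis[1] - axis[0])
                sig = extra * FWHM_TO_SIGMA / step
                t_amp = gaussian_filter1d(
                    t_amp.astype(float), sig, mode="constant"
                ).astype(np.float32)
            # score on an axis just fine enough for the scoring width
            step_score = score_width_mhz / 4.0
            self.axis_score = np.arange(axis[0], axis[-1] + 1e-9, step_score)
            t_amp = np.interp(self.axis_score, axis, t_amp).astype(np.float32)
            window = targets.endor.meta.get("window", ENDOR_WINDOW_MHZ)
            in_win = (self.axis_score >= window[0]) & (self.axis_score <= window[1])
            if not in_win.any():
                in_win = np.ones(len(self.axis_score), dtype=bool)
            self.in_win = in_win
            self.t_amp = t_amp[in_win]
            self.scale_s = max(float(np.sqrt(np.mean(self.t_amp**2))), 1e-9)

    def __call__(self, angles: np.ndarray, chunk: int = 20000) -> np.ndarray:
        """columns (score, aeff_rms, spectral_rms) for (n, 3) ZYZ angles."""
        angles = np.atleast_2d(angles)
        n_total = angles.shape[0]
        a_rms = np.empty(n_total)
        s_rms = np.zeros(n_total)
        for start in range(0, n_total, chunk):
            sl = slice(start, min(start + chunk, n_total))
            mats = Rotation.from_euler("ZYZ", angles[sl]).as_matrix()
            d_zz = mats[:, :, 2]
            d_yy = mats[:, :, 1]
            pred_a = _aeff_matrix(self.tensors, self.names, d_zz)
            a_rms[sl] = np.sqrt(
                np.mean((pred_a - self.target_a[None, :]) ** 2, axis=1)
            )
            if self.use_spec:
                # the measured spectrum contains every nucleus, not only the
                # ones with fitted coupling targets
                aeff_yy = _aeff_matrix(self.tensors, self.all_names, d_yy)
                pred_s = _endor_amplitudes(aeff_yy, self.axis_score, self.width)[
                    :, self.in_win
                ]
                s_rms[sl] = (
                    np.sqrt(np.mean((pred_s - self.t_amp[None, :]) ** 2, axis=1))
                    / self.scale_s
                )
        scores = self.weights[0] * a_rms / self.scale_a + self.weights[1] * s_rms
        return np.column_stack([scores, a_rms, s_rms])


def _score_grid(
    tensors: TensorSet,
    targets: SearchTargets,
    alphas: np.ndarray,
    betas: np.ndarray,
    gammas: np.ndarray,
    weights: Tuple[float, float],
    score_width_mhz: float = SCORE_WIDTH_FWHM_MHZ,
) -> Tuple[np.ndarray, np.ndarray]:
    aa, bb, gg = np.meshgrid(alphas, betas, gammas, indexing="ij")
    angles = np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])
    return angles, _Scorer(tensors, targets, weights, score_width_mhz)(angles)


def euler_grid_search(
    tensors: TensorSet,
    targets: SearchTargets,
    grid_step_deg: float = 5.0,
    weights: Tuple[float, float] = (1.0, 1.0),
    refine: bool = True,
    refine_top: int = 64,
    keep_landscape: bool = False,
) -> SearchResult:
    """Exhaustive ZYZ Euler scan minimizing the two-criterion mismatch score.

    score = w1 * RMS(A_eff mismatch)/RMS(target) + w2 * relative spectral RMS
    in the ENDOR window.  Deterministic: ties are broken by the smallest
    (beta, alpha, gamma) lexicographically.  ``refine`` adds 1-degree local
    passes around the ``refine_top`` best coarse cells.
    """
    if 360.0 % grid_step_deg != 0:
        raise ValueError("grid_step_deg must divide 360")
    step = math.radians(grid_step_deg)
    alphas = np.arange(0.0, 2 * math.pi - 1e-9, step)
    betas = np.arange(0.0, math.pi + 1e-9, step)
    gammas = np.arange(0.0, 2 * math.pi - 1e-9, step)
    coarse_width = SCORE_WIDTH_COARSE_FWHM_MHZ if refine else SCORE_WIDTH_FWHM_MHZ
    coarse_scorer = _Scorer(tensors, targets, weights, coarse_width)
    fine_scorer = _Scorer(tensors, targets, weights, SCORE_WIDTH_FWHM_MHZ)
    aa, bb, gg = np.meshgrid(alphas, betas, gammas, indexing="ij")
    angles = np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])
    cols = coarse_scorer(angles)
    scores = cols[:, 0]
    order = np.lexsort((angles[:, 2], angles[:, 0], angles[:, 1], scores))
    ibest = order[0]
    best_angles = angles[ibest]
    best_cols = cols[ibest]

    if refine:
        # coarse-to-fine: the sharp-width basin is narrower than the coarse
        # cell, so refine the best broad-width cells at 1 degree and at the
        # sharp comparison width, keeping the overall winner
        fine = math.radians(1.0)
        candidates = []
        for idx in order[:refine_top]:
            a0, b0, g0 = angles[idx]
            f_alphas = np.unique(
                np.arange(a0 - step, a0 + step + 1e-9, fine) % (2 * math.pi)
            )
            f_betas = np.unique(
                np.clip(np.arange(b0 - step, b0 + step + 1e-9, fine), 0, math.pi)
            )
            f_gammas = np.unique(
                np.arange(g0 - step, g0 + step + 1e-9, fine) % (2 * math.pi)
            )
            fa, fb, fg = np.meshgrid(f_alphas, f_betas, f_gammas, indexing="ij")
            f_angles = np.column_stack([fa.ravel(), fb.ravel(), fg.ravel()])
            f_cols = fine_scorer(f_angles)
            f_order = np.lexsort(
                (f_angles[:, 2], f_angles[:, 0], f_angles[:, 1], f_cols[:, 0])
            )
            candidates.append((f_cols[f_order[0], 0], f_angles[f_order[0]]))
        # continuous polish of the best fine candidates: the sharp-width
        # basin floor is reached only off-lattice, so competing basins can
        # only be ranked after each has been locally minimized
        candidates.sort(key=lambda t: t[0])
        best_fine = None

        def fun(p):
            e = np.array(
                [p[0] % (2 * math.pi), np.clip(p[1], 0, math.pi),
                 p[2] % (2 * math.pi)]
            )
            return float(fine_scorer(e[None, :])[0, 0])

        for _, start in candidates[:8]:
            sol = minimize(fun, start, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-10,
                                    "maxiter": 200})
            pol = np.array([sol.x[0] % (2 * math.pi),
                            float(np.clip(sol.x[1], 0, math.pi)),
                            sol.x[2] % (2 * math.pi)])
            c = fine_scorer(pol[None, :])
            if best_fine is None or c[0, 0] < best_fine[1][0]:
                best_fine = (pol, c[0])
        if best_fine is not None:
            best_angles, best_cols = best_fine

    best = EulerAngles(*best_angles)
    landscape = None
    if keep_landscape:
        landscape = np.column_stack([np.degrees(angles), scores])
    return SearchResult(
        best=best,
        score=float(best_cols[0]),
        grid_step_deg=grid_step_deg,
        symmetry_orbit=symmetry_orbit(best),
        aeff_rms_mhz=float(best_cols[1]),
        spectral_rms=float(best_cols[2]),
        landscape=landscape,
    )


def frame_distance_deg(a: EulerAngles, b: EulerAngles) -> float:
    """Smallest rotation angle between two frames modulo the symmetry group."""
    ra = a.as_matrix()
    best = 180.0
    for rb in (c.as_matrix() for c in symmetry_orbit(b)):
        r_rel = ra.T @ rb
        cos_ang = (np.trace(r_rel) - 1.0) / 2.0
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cos_ang))))
        best = min(best, ang)
    return best
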