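"""ENDOR / ELDOR-NMR line positions, Gaussian synthesis and component fitting.

To first order, a nucleus with effective coupling A_eff coupled to the
electron spin in manifold M_s gives nuclear resonances at nu_NMR -/+ M_s*A_eff
(two branches).  Working on the positive branch with offsets defined as
nu' - q*nu_NMR, a single-quantum (q = 1) line sits at -M_s*A_eff, and a
multi-quantum transition involving participants with nuclear flips dm_I sits
at

    offset = sum_i ( -M_s * dm_I,i * A_eff,i )

For I = 1 nuclei the first-order nuclear quadrupole interaction splits each
SQ line by +/- (3/2) P_eff but cancels exactly in the single-nucleus DQ
transition, which is what makes the 14N DQ doublet a clean hyperfine ruler:
offsets of 20 MHz (M_s = -5/2) and 12 MHz (M_s = -3/2) both invert to
A_eff = 4 MHz.

Spectra are synthesized as Gaussian mixtures ("components"): each component
is an (A_eff, FWHM, amplitude) triple contributing one line per manifold, and
the matrix signal from distant nuclei is just a component with A_eff = 0.
Fitting is deterministic nonlinear least squares with a fixed multi-start
grid over A_eff seeds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .constants import Nucleus, get_nucleus
from .fieldsweep import FWHM_TO_SIGMA, Spectrum
from .orientation_select import QuadrupoleTensor
from .spin_core import SpinModelError, _check_ms


@dataclass
class SpectralLine:
    offset_mhz: float
    intensity: float = 1.0
    tag: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("line intensities must be non-negative")


LineList = List[SpectralLine]


@dataclass
class SpectralComponent:
    """One Gaussian coupling component: A_eff, FWHM width, relative amplitude."""

    a_eff_mhz: float
    width_mhz: float = 2.2
    amplitude: float = 1.0
    nucleus: str = "1H"
    manifolds: Tuple[float, ...] = (-2.5, -1.5)

    def __post_init__(self) -> None:
        if self.width_mhz <= 0:
            raise ValueError("component width must be positive")
        if self.amplitude < 0:
            raise ValueError("component amplitude must be non-negative")


def sq_frequencies(
    a_eff_mhz: float,
    nucleus: Nucleus | str,
    ms: float,
    quad: Optional[QuadrupoleTensor] = None,
    direction: Optional[np.ndarray] = None,
) -> LineList:
    """Single-quantum line offsets (both branches) for one nucleus.

    For I = 1/2 the lines sit at +/- |M_s*A_eff| with the positive branch at
    -M_s*A_eff; A_eff = 0 collapses both onto the matrix line at zero offset.
    For I = 1 each line is additionally split by +/- (3/2)*P_eff.
    """
    _check_ms(ms)
    nuc = get_nucleus(nucleus)
    if quad is not None and nuc.spin < 1:
        raise SpinModelError(
            f"quadrupole tensor supplied for spin-1/2 nucleus {nuc.name}"
        )
    pos = -ms * a_eff_mhz
    base = [pos] if pos == 0.0 else [pos, -pos]
    if quad is None or nuc.spin < 1:
        return [SpectralLine(o, tag=f"{nuc.name}/ms={ms}/q=1") for o in base]
    if direction is None:
        raise SpinModelError("a field direction is required to project the quadrupole")
    p_eff = quad.effective(direction)
    lines = []
    for o in base:
        for sgn in (+1.0, -1.0):
            lines.append(
                SpectralLine(o + sgn * 1.5 * p_eff, tag=f"{nuc.name}/ms={ms}/q=1")
            )
    return lines


def mq_frequencies(
    participants: Sequence[Tuple[float, Nucleus | str, int]], ms: float
) -> LineList:
    """Multi-quantum (q >= 2) positive-branch offset for a participant set.

    ``participants`` is a list of (A_eff, nucleus, dm_I).  The offset is the
    dm_I-weighted sum of the single-quantum offsets; a single-nucleus I = 1
    DQ transition (dm_I = 2) carries no first-order quadrupole shift.
    """
    _check_ms(ms)
    q = 0
    offset = 0.0
    tags = []
    for a_eff, nucleus, dm in participants:
        nuc = get_nucleus(nucleus)
        if abs(dm) > 2 * nuc.spin + 1e-9:
            raise SpinModelError(
                f"|dm_I| = {abs(dm)} exceeds 2I = {2 * nuc.spin} for {nuc.name}"
            )
        q += abs(int(dm))
        offset += -ms * dm * a_eff
        tags.append(f"{nuc.name}:dm={dm}")
    if q < 2:
        raise SpinModelError(f"multi-quantum transition needs q >= 2, got q = {q}")
    return [SpectralLine(offset, tag=f"{'+'.join(tags)}/ms={ms}/q={q}")]


def offset_to_aeff(offset_mhz: float, ms: float, q: int = 1) -> float:
    """Invert the positive-branch convention: A_eff = -offset / (M_s * q)."""
    if ms * q == 0:
        raise SpinModelError("offset-to-coupling inversion undefined for M_s*q = 0")
    return -offset_mhz / (ms * q)


def forbiddenness_weight(t_aniso_mhz: float, nu_nmr_mhz: float, q: int) -> float:
    """Simple relative ELDOR-NMR transition probability, ~ (T/nu_NMR)^(2q).

    The true probabilities are geometry sensitive; this isolated model only
    orders intensities within a given quantum order and is meant to be
    swapped out when a better calibration exists.
    """
    if nu_nmr_mhz <= 0:
        raise ValueError("nu_NMR must be positive")
    return float((abs(t_aniso_mhz) / nu_nmr_mhz) ** (2 * q))


def synthesize_spectrum(
    components: Sequence[SpectralComponent],
    axis_mhz: np.ndarray,
    kind: str = "eldor_sq",
) -> Spectrum:
    """Gaussian-mixture spectrum of ``components`` on ``axis_mhz``.

    ELDOR kinds use the positive branch only; the ENDOR kind places both
    branches.  Each component contributes one line per manifold in its
    ``manifolds`` with equal manifold weights.
    """
    if kind not in ("eldor_sq", "eldor_dq", "endor"):
        raise ValueError(f"unknown spectrum kind {kind!r}")
    axis = np.asarray(axis_mhz, dtype=float)
    amp = np.zeros_like(axis)
    clipped = False
    for comp in components:
        sigma = comp.width_mhz * FWHM_TO_SIGMA
        for ms in comp.manifolds:
            if kind == "eldor_dq":
                lines = mq_frequencies(
                    [(comp.a_eff_mhz, comp.nucleus, 2)], ms
                )
            else:
                lines = sq_frequencies(comp.a_eff_mhz, comp.nucleus, ms)
                if kind == "eldor_sq":
                    lines = [l for l in lines if l.offset_mhz == -ms * comp.a_eff_mhz]
            for line in lines:
                if not (
                    axis[0] <= line.offset_mhz - 3 * sigma
                    and line.offset_mhz + 3 * sigma <= axis[-1]
                ):
                    clipped = True
                amp += (
                    comp.amplitude
                    * line.intensity
                    * np.exp(-0.5 * ((axis - line.offset_mhz) / sigma) ** 2)
                )
    if clipped:
        import warnings

        warnings.warn("some lines extend beyond the spectrum axis", stacklevel=2)
    return Spectrum(axis, amp, kind=kind, meta={"axis_unit": "MHz offset"})


@dataclass
class ComponentFit:
    """Result of a Gaussian component fit with 1-sigma uncertainties."""

    components: List[SpectralComponent]
    a_eff_err_mhz: List[float]
    width_err_mhz: List[float]
    residual: float
    matrix_amplitude: float = 0.0


def _mixture_model(
    params: np.ndarray,
    axis: np.ndarray,
    n_components: int,
    manifolds: Tuple[float, ...],
    include_matrix: bool,
    matrix_width: float,
) -> np.ndarray:
    amp = np.zeros_like(axis)
    for i in range(n_components):
        a, w, h = params[3 * i : 3 * i + 3]
        sigma = w * FWHM_TO_SIGMA
        for ms in manifolds:
            amp += h * np.exp(-0.5 * ((axis + ms * a) / sigma) ** 2)
    if include_matrix:
        h0 = params[3 * n_components]
        sigma0 = matrix_width * FWHM_TO_SIGMA
        amp += h0 * np.exp(-0.5 * (axis / sigma0) ** 2)
    return amp


def fit_components(
    spec: Spectrum,
    n_components: int,
    manifolds: Tuple[float, ...] = (-2.5, -1.5),
    bounds_a_mhz: Tuple[float, float] = (0.5, 10.0),
    bounds_w_mhz: Tuple[float, float] = (0.5, 6.0),
    include_matrix: bool = True,
    matrix_width_mhz: float = 2.2,
    seed_spacing_mhz: float = 1.0,
) -> ComponentFit:
    """Deterministic multi-start least-squares decomposition of a spectrum.

    A_eff starting values are every ``seed_spacing_mhz``-spaced combination
    inside ``bounds_a_mhz``; the best residual wins and exact ties go to the
    smaller A_eff tuple, so the result is reproducible run to run.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    axis, target = spec.axis, spec.amplitude
    scale = np.abs(target).max()
    if scale == 0:
        raise SpinModelError("cannot fit an all-zero spectrum")

    seeds = np.arange(bounds_a_mhz[0], bounds_a_mhz[1] + 1e-9, seed_spacing_mhz)
    lo = [bounds_a_mhz[0], bounds_w_mhz[0], 0.0] * n_components
    hi = [bounds_a_mhz[1], bounds_w_mhz[1], np.inf] * n_components
    if include_matrix:
        lo.append(0.0)
        hi.append(np.inf)

    def resid(p):
        return (
            _mixture_model(
                p, axis, n_components, manifolds, include_matrix, matrix_width_mhz
            )
            - target
        )

    best = None
    for combo in itertools.combinations(seeds, n_components):
        p0 = []
        for a0 in combo:
            p0.extend([a0, 2.0, scale / 2.0])
        if include_matrix:
            p0.append(scale / 2.0)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        key = (round(sol.cost / scale**2, 9), tuple(sorted(combo)))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise SpinModelError("component fit failed to converge from any start")

    sol = best[1]
    # 1-sigma errors from the Gauss-Newton covariance
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * 2 * sol.cost / dof
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(n, np.nan)

    comps, a_err, w_err = [], [], []
    order = np.argsort([sol.x[3 * i] for i in range(n_components)])
    for i in order:
        a, w, h = sol.x[3 * i : 3 * i + 3]
        comps.append(SpectralComponent(float(a), float(w), float(h), manifolds=manifolds))
        a_err.append(float(perr[3 * i]))
        w_err.append(float(perr[3 * i + 1]))
    matrix_amp = float(sol.x[3 * n_components]) if include_matrix else 0.0
    return ComponentFit(
        components=comps,
        a_eff_err_mhz=a_err,
        width_err_mhz=w_err,
        residual=float(math.sqrt(2 * sol.cost / m)) ,
        matrix_amplitude=matrix_amp,
    )


def dq_edges(
    components: Sequence[SpectralComponent] | Sequence[float], ms: float
) -> Tuple[float, float]:
    """Extreme two-proton DQ combination offsets over a component set, MHz.

    Pairs are distinct components when two or more are supplied; a single
    component is combined with itself.  The high edge equals the sum of the
    two largest single-quantum positive-branch offsets at the same manifold.
    """
    _check_ms(ms)
    a_values = [
        c.a_eff_mhz if isinstance(c, SpectralComponent) else float(c)
        for c in components
    ]
    if len(a_values) == 0:
        raise ValueError("need at least one component")
    if len(a_values) == 1:
        pairs: Iterable[Tuple[float, float]] = [(a_values[0], a_values[0])]
    else:
        pairs = itertools.combinations(a_values, 2)
    offsets = [-ms * (a1 + a2) for a1, a2 in pairs]
    return (min(offsets), max(offsets))
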