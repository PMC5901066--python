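"""Plain-text file formats: spectra, spin-system parameters, tensor sets.

All formats are diff-able text.  Spectra are two-column numeric files
(whitespace or comma delimited) with ``# key: value`` comment headers;
spin-system parameters and tensor sets are YAML.  Angles are degrees at the
file boundary, radians internally.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np
import yaml

from .fileio_schemas import SPIN_SYSTEM_KEYS  # noqa: F401  (documented schema)
from .fileio_schemas import TENSOR_KEYS
from .fieldsweep import Spectrum
from .orientation_select import EulerAngles, HyperfineTensor, QuadrupoleTensor
from .frame_search import TensorSet
from .spin_core import SpectrometerSettings, ZFSParameters


class ParseError(ValueError):
    pass


def read_spectrum(path, kind: str = "fieldsweep") -> Spectrum:
    """Read a two-column axis/amplitude text file into a Spectrum."""
    meta: Dict[str, str] = {}
    axis, amp = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                axis.append(float(parts[0]))
                amp.append(float(parts[1]))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(axis) < 2:
        raise ParseError(f"{path}: fewer than two data rows")
    order = np.argsort(axis)
    axis_arr = np.asarray(axis)[order]
    amp_arr = np.asarray(amp)[order]
    if np.any(np.diff(axis_arr) == 0):
        dup = axis_arr[np.nonzero(np.diff(axis_arr) == 0)[0][0]]
        raise ParseError(f"{path}: duplicate axis value {dup}")
    meta.setdefault("kind", kind)
    return Spectrum(axis_arr, amp_arr, kind=meta.get("kind", kind), meta=meta)


def write_spectrum(path, spec: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {spec.kind}\n")
        for k, v in spec.meta.items():
            if k != "kind":
                fh.write(f"# {k}: {v}\n")
        for x, y in zip(spec.axis, spec.amplitude):
            fh.write(f"{x:.10g} {y:.10g}\n")


def read_spin_system(path) -> Tuple[SpectrometerSettings, ZFSParameters, list]:
    """Read a spin-system YAML file; unknown keys trigger a warning."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a key-value mapping")
    unknown = set(data) - SPIN_SYSTEM_KEYS
    if unknown:
        warnings.warn(f"{path}: ignoring unknown keys {sorted(unknown)}", stacklevel=2)
    settings = SpectrometerSettings(
        nu_obs_ghz=float(data.get("nu_obs_GHz", 94.0)),
        g=float(data.get("g", 2.0023)),
        temperature_k=float(data.get("temperature_K", 6.0)),
    )
    zfs = ZFSParameters(float(data["D_GHz"]), float(data.get("E_GHz", 0.0)))
    return settings, zfs, data.get("nuclei", [])


def write_spin_system(path, settings: SpectrometerSettings, zfs: ZFSParameters,
                      nuclei: list | None = None) -> None:
    data = {
        "nu_obs_GHz": settings.nu_obs_ghz,
        "g": settings.g,
        "temperature_K": settings.temperature_k,
        "D_GHz": zfs.d_ghz,
        "E_GHz": zfs.e_ghz,
        "nuclei": nuclei or [],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_tensor_set(path, trace_tol_mhz: float = 1e-3) -> TensorSet:
    """Read a YAML tensor set; near-traceless tensors are re-tracelessed."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "nuclei" not in data:
        raise ParseError(f"{path}: expected a mapping with a 'nuclei' list")
    hyperfine: Dict[str, HyperfineTensor] = {}
    quadrupole: Dict[str, QuadrupoleTensor] = {}
    for rec in data["nuclei"]:
        unknown = set(rec) - TENSOR_KEYS
        if unknown:
            warnings.warn(
                f"{path}: ignoring unknown tensor keys {sorted(unknown)}",
                stacklevel=2,
            )
        name = rec["id"]
        if name in hyperfine:
            raise ParseError(f"{path}: duplicate nucleus identity {name!r}")
        t = np.asarray(rec["t_principal_MHz"], dtype=float)
        trace = t.sum()
        if abs(trace) > trace_tol_mhz:
            raise ParseError(
                f"{path}: {name}: dipolar trace {trace:.4f} MHz exceeds the "
                f"{trace_tol_mhz} MHz tolerance"
            )
        if abs(trace) > 1e-9:
            warnings.warn(
                f"{path}: {name}: re-tracelessing dipolar tensor "
                f"(trace {trace:.2e} MHz)",
                stacklevel=2,
            )
            t = t - trace / 3.0
        euler = rec.get("euler_deg", [0.0, 0.0, 0.0])
        hyperfine[name] = HyperfineTensor(
            nucleus=rec.get("isotope", "1H"),
            a_iso_mhz=float(rec.get("a_iso_MHz", 0.0)),
            t_principal_mhz=tuple(t),
            frame=EulerAngles.from_degrees(*euler),
            identity=name,
        )
        if "quadrupole_MHz" in rec:
            p = np.asarray(rec["quadrupole_MHz"], dtype=float)
            p = p - p.sum() / 3.0 if abs(p.sum()) <= trace_tol_mhz else p
            q_euler = rec.get("quad_euler_deg", euler)
            quadrupole[name] = QuadrupoleTensor(
                tuple(p), frame=EulerAngles.from_degrees(*q_euler)
            )
    return TensorSet(hyperfine, quadrupole, source=data.get("source", "file"))


def write_tensor_set(path, tensors: TensorSet) -> None:
    records = []
    for name, hft in tensors.hyperfine.items():
        rec = {
            "id": name,
            "isotope": hft.nucleus.name,
            "a_iso_MHz": float(hft.a_iso_mhz),
            "t_principal_MHz": [float(v) for v in hft.t_principal_mhz],
            "euler_deg": [float(v) for v in hft.frame.degrees()],
        }
        if name in tensors.quadrupole:
            q = tensors.quadrupole[name]
            rec["quadrupole_MHz"] = [float(v) for v in q.p_principal_mhz]
            rec["quad_euler_deg"] = [float(v) for v in q.frame.degrees()]
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"source": tensors.source, "nuclei": records}, fh,
                       sort_keys=False)
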