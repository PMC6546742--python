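"""File formats: wide-CSV TA matrices, two-column traces, rate series and
spectra, plus the key-value kinetic-scheme config.

All files are UTF-8 with LF line endings, ``#``-prefixed comment/metadata
lines, and numerics written with 9 significant digits.  Units are explicit
in column headers (``time_ps``, ``T_K``); nothing is inferred from
magnitudes.  Decimal separators must be dots — decimal commas are
rejected with an explicit message.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .kinetics import IRFModel, KineticScheme
from .relaxation import DecayTrace, RateMeasurement, RateSeries
from .spectra import Spectrum
from .targetfit import TAMatrix
from .units import from_seconds, time_scale, to_seconds

__all__ = [
    "read_ta_csv",
    "write_ta_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_rate_series_csv",
    "write_rate_series_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "scheme_to_dict",
    "scheme_from_dict",
]

FMT = "%.9g"


def _format(x: float) -> str:
    return FMT % x


def _parse_float(token: str, path, lineno: int) -> float:
    token = token.strip()
    try:
        return float(token)
    except ValueError:
        hint = (
            " (decimal commas are not supported; use '.' as decimal separator)"
            if "," in token or token == ""
            else ""
        )
        raise ValueError(
            f"{path}:{lineno}: cannot parse {token!r} as a number{hint}"
        ) from None


def _split_lines(path):
    """Yield (lineno, kind, payload): kind is 'meta' or 'data'."""
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            yield lineno, "meta", line[1:].strip()
        else:
            yield lineno, "data", line


def _parse_meta(payload: str, metadata: dict):
    if ":" not in payload:
        return  # free comment
    key, _, value = payload.partition(":")
    key = key.strip()
    value = value.strip()
    if key == "truth":
        k, _, v = value.partition("=")
        try:
            parsed = json.loads(v)
        except json.JSONDecodeError:
            parsed = v
        metadata.setdefault("truth", {})[k.strip()] = parsed
    elif key:
        metadata[key] = value


def _meta_lines(metadata: dict, skip=()) -> list[str]:
    lines = []
    for key, value in metadata.items():
        if key in skip:
            continue
        if key == "truth" and isinstance(value, dict):
            for k, v in value.items():
                lines.append(f"#truth: {k}={json.dumps(v)}")
        else:
            lines.append(f"#{key}: {value}")
    return lines


def _time_header_unit(token: str, path, lineno: int) -> str:
    if not token.startswith("time_"):
        raise ValueError(
            f"{path}:{lineno}: first header column must be 'time_<unit>', got {token!r}"
        )
    unit = token[len("time_") :]
    try:
        time_scale(unit)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from None
    return unit


def read_ta_csv(path) -> TAMatrix:
    """Read a wide TA CSV: header ``time_<unit>,<nm>,...``; rows of
    time + dA values; ``#``-prefixed metadata lines."""
    metadata: dict = {}
    header = None
    times, rows = [], []
    ncol = None
    for lineno, kind, payload in _split_lines(path):
        if kind == "meta":
            _parse_meta(payload, metadata)
            continue
        fields = payload.split(",")
        if header is None:
            header = fields
            unit = _time_header_unit(fields[0], path, lineno)
            wavelengths = [
                _parse_float(f, path, lineno) for f in fields[1:]
            ]
            ncol = len(fields)
            continue
        if len(fields) != ncol:
            raise ValueError(
                f"{path}:{lineno}: ragged row — expected {ncol} fields, got {len(fields)}"
            )
        values = [_parse_float(f, path, lineno) for f in fields]
        times.append(values[0])
        rows.append(values[1:])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows found")
    times = np.asarray(times)
    wavelengths = np.asarray(wavelengths)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time grid is not strictly increasing")
    if wavelengths.size >= 2 and np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"{path}: wavelength grid is not strictly increasing")
    polarization = metadata.pop("polarization", "magic")
    return TAMatrix(
        times=to_seconds(times, unit),
        wavelengths=wavelengths,
        dA=np.asarray(rows),
        polarization=polarization,
        time_unit=unit,
        metadata=metadata,
    )


def write_ta_csv(ta: TAMatrix, path):
    lines = [f"#polarization: {ta.polarization}"]
    lines += _meta_lines(ta.metadata)
    header = f"time_{ta.time_unit}," + ",".join(_format(w) for w in ta.wavelengths)
    lines.append(header)
    times_out = from_seconds(ta.times, ta.time_unit)
    for t, row in zip(times_out, ta.dA):
        lines.append(_format(t) + "," + ",".join(_format(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_columns(path, expected_headers, min_cols, max_cols):
    metadata: dict = {}
    header = None
    rows = []
    for lineno, kind, payload in _split_lines(path):
        if kind == "meta":
            _parse_meta(payload, metadata)
            continue
        fields = [f.strip() for f in payload.split(",")]
        if header is None:
            header = fields
            if not (min_cols <= len(fields) <= max_cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {min_cols}-{max_cols} header "
                    f"columns, got {len(fields)}"
                )
            continue
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: ragged row — expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: empty file")
    return metadata, header, rows


def read_trace_csv(path) -> DecayTrace:
    """Two-column trace CSV: header ``time_<unit>,signal``."""
    metadata, header, rows = _read_columns(path, None, 2, 2)
    unit = _time_header_unit(header[0], path, 1)
    if len(rows) < 3:
        raise ValueError(f"{path}: a decay trace needs at least 3 points, got {len(rows)}")
    times = [_parse_float(f[0], path, ln) for ln, f in rows]
    signal = [_parse_float(f[1], path, ln) for ln, f in rows]
    return DecayTrace(
        times=to_seconds(np.asarray(times), unit),
        signal=np.asarray(signal),
        time_unit=unit,
        label=metadata.pop("label", ""),
        metadata=metadata,
    )


def write_trace_csv(trace: DecayTrace, path):
    lines = []
    if trace.label:
        lines.append(f"#label: {trace.label}")
    lines += _meta_lines(trace.metadata)
    lines.append(f"time_{trace.time_unit},signal")
    for t, y in zip(from_seconds(trace.times, trace.time_unit), trace.signal):
        lines.append(f"{_format(t)},{_format(y)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rate_series_csv(path) -> RateSeries:
    """Rate-series CSV: header ``T_K,k_per_s[,k_se[,condition]]``."""
    metadata, header, rows = _read_columns(path, None, 2, 4)
    if header[0] != "T_K" or header[1] != "k_per_s":
        raise ValueError(
            f"{path}: expected header starting 'T_K,k_per_s', got {','.join(header)}"
        )
    measurements = []
    for ln, fields in rows:
        T = _parse_float(fields[0], path, ln)
        k = _parse_float(fields[1], path, ln)
        k_se = _parse_float(fields[2], path, ln) if len(fields) > 2 and fields[2] else 0.0
        condition = fields[3] if len(fields) > 3 and fields[3] else "dark"
        measurements.append(RateMeasurement(k=k, T=T, k_se=k_se, condition=condition))
    return RateSeries(measurements=tuple(measurements))


def write_rate_series_csv(series: RateSeries, path):
    lines = ["T_K,k_per_s,k_se,condition"]
    for m in series.measurements:
        lines.append(
            f"{_format(m.T)},{_format(m.k)},{_format(m.k_se)},{m.condition}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum_csv(path) -> Spectrum:
    """Spectrum CSV: header ``wavelength_nm,absorbance``."""
    metadata, header, rows = _read_columns(path, None, 2, 2)
    if header[0] != "wavelength_nm":
        raise ValueError(
            f"{path}: expected first header column 'wavelength_nm', got {header[0]!r}"
        )
    wl = [_parse_float(f[0], path, ln) for ln, f in rows]
    ab = [_parse_float(f[1], path, ln) for ln, f in rows]
    return Spectrum(
        wavelengths=np.asarray(wl),
        absorbance=np.asarray(ab),
        label=metadata.pop("label", "mixture"),
        metadata=metadata,
    )


def write_spectrum_csv(spec: Spectrum, path):
    lines = [f"#label: {spec.label}"]
    lines += _meta_lines(spec.metadata)
    lines.append("wavelength_nm,absorbance")
    for w, a in zip(spec.wavelengths, spec.absorbance):
        lines.append(f"{_format(w)},{_format(a)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# kinetic-scheme config block


def _parse_quantity(value, default_unit="s") -> float:
    """'320 fs' / '10 ps' / 3.2e-13 -> seconds."""
    if isinstance(value, (int, float)):
        return float(value) * time_scale(default_unit)
    parts = str(value).split()
    if len(parts) == 2:
        return to_seconds(float(parts[0]), parts[1])
    if len(parts) == 1:
        if parts[0] in ("inf", "infinite", "none"):
            return float("inf")
        return float(parts[0]) * time_scale(default_unit)
    raise ValueError(f"cannot parse time quantity {value!r}")


def scheme_from_dict(d: dict) -> tuple[KineticScheme, IRFModel]:
    """Build (scheme, irf) from the key-value config block.

    Expected keys: ``compartments`` (ordered list), ``lifetimes`` (map of
    label to '<value> <unit>' or seconds; inf marks non-decaying),
    ``branching`` (list of {from, to, fraction}), optional ``initial`` map
    (defaults to first compartment = 1) and ``irf`` {t0, sigma}.
    """
    compartments = tuple(d["compartments"])
    lifetimes = d.get("lifetimes", {})
    rates = []
    for c in compartments:
        if c not in lifetimes:
            raise ValueError(f"no lifetime given for compartment {c!r}")
        tau = _parse_quantity(lifetimes[c])
        rates.append(0.0 if np.isinf(tau) else 1.0 / tau)
    branching = {}
    for edge in d.get("branching", []):
        branching[(edge["from"], edge["to"])] = float(edge["fraction"])
    initial_map = d.get("initial")
    if initial_map is None:
        initial = (1.0,) + (0.0,) * (len(compartments) - 1)
    else:
        initial = tuple(float(initial_map.get(c, 0.0)) for c in compartments)
    scheme = KineticScheme(
        compartments=compartments,
        rates=tuple(rates),
        branching=branching,
        initial=initial,
    )
    irf_cfg = d.get("irf", {})
    irf = IRFModel(
        t0=_parse_quantity(irf_cfg.get("t0", 0.0)),
        sigma=_parse_quantity(irf_cfg.get("sigma", "100 fs")),
    )
    return scheme, irf


def scheme_to_dict(scheme: KineticScheme, irf: IRFModel | None = None) -> dict:
    d = {
        "compartments": list(scheme.compartments),
        "lifetimes": {
            c: ("inf" if k == 0 else float(1.0 / k))
            for c, k in zip(scheme.compartments, scheme.rates)
        },
        "branching": [
            {"from": p, "to": c, "fraction": float(b)}
            for (p, c), b in scheme.branching.items()
        ],
        "initial": {
            c: float(x) for c, x in zip(scheme.compartments, scheme.initial)
        },
    }
    if irf is not None:
        d["irf"] = {"t0": float(irf.t0), "sigma": float(irf.sigma)}
    return d
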