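"""Time-unit handling.

All kinetics inside the package run in SI seconds; unit tokens appear only
at I/O boundaries (CSV headers, generator configs, fit reports).
"""

from __future__ import annotations

TIME_UNITS: dict[str, float] = {
    "fs": 1e-15,
    "ps": 1e-12,
    "ns": 1e-9,
    "us": 1e-6,
    "ms": 1e-3,
    "s": 1.0,
    "min": 60.0,
}


def to_seconds(value, unit: str):
    """Convert ``value`` expressed in ``unit`` to seconds."""
    return value * time_scale(unit)


def from_seconds(value, unit: str):
    """Convert ``value`` in seconds to ``unit``."""
    return value / time_scale(unit)


def time_scale(unit: str) -> float:
    try:
        return TIME_UNITS[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_UNITS)}"
        ) from None
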