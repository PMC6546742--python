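"""Absorption-band analysis: peak finding, isomer band separation, and
Beer-Lambert utilities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "BandSeparationResult",
    "find_lambda_max",
    "band_separation",
    "beer_lambert",
    "absorbance_from_epsilon",
]

#: relative height difference below which the two tallest maxima are
#: considered exchangeable and the primary assignment flagged ambiguous
AMBIGUITY_RTOL = 0.02


@dataclass(frozen=True)
class Spectrum:
    """Absorption spectrum on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = "mixture"  # Z | E | mixture
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.size != ab.size:
            raise ValueError("wavelength and absorbance grids differ in length")
        if wl.size >= 2 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite values")


@dataclass(frozen=True)
class BandSeparationResult:
    """Band separations between the Z maximum and the E maxima (nm).

    ``delta_primary`` uses the tallest E maximum, ``delta_red`` the
    red-most one.  ``ambiguous`` is set when the two tallest E maxima are
    within 2% in height, making the primary assignment borderline.
    """

    lambda_max_Z: float
    lambda_max_E_list: tuple[float, ...]  # ordered by height, tallest first
    delta_primary: float
    delta_red: float
    deltas: tuple[float, ...]
    ambiguous: bool = False


def find_lambda_max(
    spec: Spectrum, n_peaks: int | None = None, min_prominence: float = 0.0
) -> list[tuple[float, float]]:
    """Local absorption maxima as (wavelength, height), tallest first.

    Discrete maxima are refined by 3-point parabolic interpolation, which
    is adequate for ~1 nm grids without overfitting.  A flat or monotone
    spectrum yields an empty list.
    """
    wl, ab = spec.wavelengths, spec.absorbance
    if wl.size < 5:
        raise ValueError("need at least 5 grid points for peak detection")
    idx, _ = find_peaks(ab, prominence=min_prominence or None)
    peaks = []
    for i in idx:
        lam, height = _parabolic_refine(wl, ab, int(i))
        peaks.append((lam, height))
    peaks.sort(key=lambda p: p[1], reverse=True)
    if n_peaks is not None:
        peaks = peaks[:n_peaks]
    return peaks


def _parabolic_refine(wl, ab, i: int) -> tuple[float, float]:
    if i == 0 or i == len(wl) - 1:
        return float(wl[i]), float(ab[i])
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = ab[i - 1], ab[i], ab[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not concave; keep the grid point
        return float(x1), float(y1)
    xv = -b / (2 * a)
    if not x0 <= xv <= x2:
        return float(x1), float(y1)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def band_separation(z_max, e_maxima) -> BandSeparationResult:
    """Band separation between photo-isomers.

    ``z_max`` is a wavelength in nm or a Z ``Spectrum`` (its tallest
    maximum is used); ``e_maxima`` is a list of E-band wavelengths nm —
    tallest first — or an E ``Spectrum``.  Returns the separation of the
    tallest (``delta_primary``) and red-most (``delta_red``) E bands from
    the Z maximum, plus per-band ``deltas`` in the input order.
    """
    ambiguous = False
    if isinstance(z_max, Spectrum):
        z_peaks = find_lambda_max(z_max, n_peaks=1)
        if not z_peaks:
            raise ValueError("no maximum found in Z spectrum")
        z_lam = z_peaks[0][0]
    else:
        z_lam = float(z_max)
    if isinstance(e_maxima, Spectrum):
        peaks = find_lambda_max(e_maxima)
        if not peaks:
            raise ValueError("no maxima found in E spectrum")
        if len(peaks) >= 2 and peaks[1][1] > 0:
            if abs(peaks[0][1] - peaks[1][1]) <= AMBIGUITY_RTOL * peaks[0][1]:
                ambiguous = True
        e_list = [lam for lam, _ in peaks]
    else:
        e_list = [float(v) for v in e_maxima]
    if not e_list:
        raise ValueError("at least one E maximum is required")
    deltas = tuple(lam - z_lam for lam in e_list)
    return BandSeparationResult(
        lambda_max_Z=z_lam,
        lambda_max_E_list=tuple(e_list),
        delta_primary=e_list[0] - z_lam,
        delta_red=max(e_list) - z_lam,
        deltas=deltas,
        ambiguous=ambiguous,
    )


def beer_lambert(absorbance: float, concentration: float, path: float = 1.0) -> float:
    """Molar absorptivity epsilon = A / (c l) in L/(mol cm)."""
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    if path <= 0:
        raise ValueError(f"path length must be positive, got {path}")
    return absorbance / (concentration * path)


def absorbance_from_epsilon(
    epsilon: float, concentration: float, path: float = 1.0
) -> float:
    """Inverse Beer-Lambert: A = epsilon c l."""
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    if path <= 0:
        raise ValueError(f"path length must be positive, got {path}")
    return epsilon * concentration * path
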