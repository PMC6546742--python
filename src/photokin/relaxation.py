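"""Thermal relaxation kinetics and Eyring activation thermodynamics.

Half-lives from single-exponential decays, transition-state regression of
rate-vs-temperature series, Gibbs-energy/rate interconversion, photo-
acceleration ratios, and photostationary-state fractions.

Conventions: half-life t_half = ln2 / k everywhere; the transmission
coefficient kappa is fixed at 1; CODATA constants via scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import R, h, k as k_B
from scipy.optimize import least_squares

from .units import to_seconds

__all__ = [
    "DecayTrace",
    "RateMeasurement",
    "RateSeries",
    "EyringParams",
    "ExponentialFit",
    "fit_exponential_decay",
    "eyring_fit",
    "gibbs_at",
    "rate_from_gibbs",
    "gibbs_from_rate",
    "half_life_from_rate",
    "photo_acceleration",
    "pss_fraction",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecayTrace:
    """Single decay trace (times stored in seconds)."""

    times: np.ndarray
    signal: np.ndarray
    time_unit: str = "s"
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)
        if times.size != signal.size:
            raise ValueError("times and signal must have equal length")
        if times.size < 3:
            raise ValueError("a decay trace needs at least 3 points")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(signal))):
            raise ValueError("non-finite values in decay trace")


@dataclass(frozen=True)
class RateMeasurement:
    k: float  # 1/s
    T: float  # K
    k_se: float = 0.0
    condition: str = "dark"  # dark | irradiated

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError(f"rate must be positive, got {self.k}")
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.condition not in ("dark", "irradiated"):
            raise ValueError(f"condition must be dark|irradiated, got {self.condition!r}")


@dataclass(frozen=True)
class RateSeries:
    measurements: tuple[RateMeasurement, ...]

    def __post_init__(self):
        if len({m.T for m in self.measurements}) < 2:
            raise ValueError("Eyring fitting needs >= 2 distinct temperatures")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([m.T for m in self.measurements])

    @property
    def rates(self) -> np.ndarray:
        return np.array([m.k for m in self.measurements])

    @property
    def rate_se(self) -> np.ndarray:
        return np.array([m.k_se for m in self.measurements])


@dataclass(frozen=True)
class EyringParams:
    """Activation enthalpy (kJ/mol) and entropy (J/(K mol)), with covariance.

    ``covariance`` is the 2x2 matrix of (dH, dS) in those units; ``kappa``
    is the transmission coefficient, fixed at 1.
    """

    dH: float
    dS: float
    covariance: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2))
    )
    kappa: float = 1.0

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        if cov.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) < -1e-10):
            raise ValueError("covariance must be positive semidefinite")

    @property
    def dH_se(self) -> float:
        return float(np.sqrt(max(self.covariance[0, 0], 0.0)))

    @property
    def dS_se(self) -> float:
        return float(np.sqrt(max(self.covariance[1, 1], 0.0)))


@dataclass(frozen=True)
class ExponentialFit:
    """baseline + amplitude * exp(-k t) fit of a decay trace."""

    k: float
    t_half: float
    baseline: float
    amplitude: float
    k_se: float
    t_half_se: float
    baseline_se: float
    amplitude_se: float
    converged: bool
    rms: float


def fit_exponential_decay(trace: DecayTrace) -> ExponentialFit:
    """Least-squares single-exponential fit; times in seconds internally.

    Raises on a constant signal; non-convergence is flagged on the result.
    """
    t = trace.times
    y = trace.signal
    if t.size < 4:
        raise ValueError("exponential fit needs at least 4 points")
    if np.ptp(y) == 0:
        raise ValueError("signal is constant; nothing to fit")

    base0 = float(y[-1])
    amp0 = float(y[0] - base0)
    if amp0 == 0:
        amp0 = float(np.ptp(y)) or 1.0
    span = float(t[-1] - t[0])
    k0 = 1.0 / max(span / 3.0, 1e-30)
    # refine k0 from the log-linear slope when the signal allows it
    z = (y - base0) / amp0
    ok = z > 1e-3
    if np.sum(ok) >= 3:
        slope = np.polyfit(t[ok], np.log(z[ok]), 1)[0]
        if slope < 0:
            k0 = -slope

    def residuals(p):
        logk, base, amp = p
        return base + amp * np.exp(-np.exp(logk) * t) - y

    sol = least_squares(
        residuals, np.array([np.log(k0), base0, amp0]), x_scale="jac"
    )
    logk, base, amp = sol.x
    k = float(np.exp(logk))
    m, n = sol.jac.shape
    s2 = 2.0 * sol.cost / max(m - n, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    k_se = float(se[0] * k)  # delta method through log
    return ExponentialFit(
        k=k,
        t_half=LN2 / k,
        baseline=float(base),
        amplitude=float(amp),
        k_se=k_se,
        t_half_se=LN2 / k**2 * k_se,
        baseline_se=float(se[1]),
        amplitude_se=float(se[2]),
        converged=bool(sol.status > 0),
        rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def eyring_fit(series: RateSeries, weighted: bool = False) -> EyringParams:
    """Transition-state regression of ln(k/T) on 1/T.

    slope = -dH/R, intercept = ln(k_B/h) + dS/R.  With ``weighted=True``
    points are weighted by 1/se(ln k)^2 from the rate standard errors.
    """
    T = series.temperatures
    k = series.rates
    x = 1.0 / T
    y = np.log(k / T)
    if weighted:
        se = series.rate_se
        if np.any(se <= 0):
            raise ValueError("weighted fit requires positive rate standard errors")
        w = (k / se) ** 2  # se(ln k) = se_k / k
    else:
        w = np.ones_like(x)
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    slope, intercept = beta
    dH = -slope * R / 1000.0  # kJ/mol
    dS = (intercept - math.log(k_B / h)) * R  # J/(K mol)
    resid = y - X @ beta
    dof = len(T) - 2
    s2 = float(resid @ (w * resid) / dof) if dof > 0 else 0.0
    cov_beta = np.linalg.inv(XtWX) * s2
    J = np.array([[-R / 1000.0, 0.0], [0.0, R]])
    cov = J @ cov_beta @ J.T
    cov = (cov + cov.T) / 2.0
    return EyringParams(dH=float(dH), dS=float(dS), covariance=cov)


def gibbs_at(params: EyringParams, T: float) -> tuple[float, float]:
    """Activation Gibbs energy dG = dH - T dS at temperature T (kJ/mol).

    Error propagation includes the dH-dS covariance.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    dG = params.dH - T * params.dS / 1000.0
    g = np.array([1.0, -T / 1000.0])
    var = float(g @ params.covariance @ g)
    return float(dG), float(np.sqrt(max(var, 0.0)))


def rate_from_gibbs(dG: float, T: float, kappa: float = 1.0) -> float:
    """Eyring rate k = kappa (k_B T / h) exp(-dG / RT); dG in kJ/mol."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return kappa * (k_B * T / h) * math.exp(-dG * 1000.0 / (R * T))


def gibbs_from_rate(k: float, T: float, kappa: float = 1.0) -> float:
    """Inverse Eyring relation: dG (kJ/mol) from a rate constant."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if k <= 0:
        raise ValueError(f"rate must be positive, got {k}")
    return R * T * math.log(kappa * k_B * T / (h * k)) / 1000.0


def half_life_from_rate(k: float, unit: str = "s") -> float:
    """Convenience: t_half = ln2/k, reported in ``unit``."""
    if k <= 0:
        raise ValueError(f"rate must be positive, got {k}")
    return LN2 / k / to_seconds(1.0, unit)


def photo_acceleration(
    k_irr: RateMeasurement, k_dark: RateMeasurement
) -> tuple[float, float, str]:
    """Ratio k_irradiated / k_dark with propagated error.

    Returns (ratio, ratio_se, interpretation).  A ratio above 1 indicates
    light-accelerated back-isomerization (P-type behaviour on top of the
    thermal channel).
    """
    if k_irr.condition != "irradiated" or k_dark.condition != "dark":
        raise ValueError("expected one irradiated and one dark measurement")
    if abs(k_irr.T - k_dark.T) > 1e-9:
        raise ValueError(
            f"temperature mismatch: {k_irr.T} K vs {k_dark.T} K"
        )
    ratio = k_irr.k / k_dark.k
    rel = math.sqrt(
        (k_irr.k_se / k_irr.k) ** 2 + (k_dark.k_se / k_dark.k) ** 2
    )
    interp = (
        "photo-accelerated back-isomerization (P-type evidence)"
        if ratio > 1
        else "no photo-acceleration detected"
    )
    return float(ratio), float(ratio * rel), interp


def pss_fraction(integral_Z: float, integral_E: float) -> float:
    """Photostationary E-fraction from isomer integrals."""
    if integral_Z < 0 or integral_E < 0:
        raise ValueError("integrals must be nonnegative")
    total = integral_Z + integral_E
    if total == 0:
        raise ValueError("both integrals are zero")
    return integral_E / total
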