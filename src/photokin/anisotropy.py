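"""Pump-probe anisotropy from polarized transient-absorption pairs.

r(t) = (I_par - I_perp) / (I_par + 2 I_perp)
I_iso = (I_par + 2 I_perp) / 3
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .targetfit import TAMatrix

__all__ = [
    "AnisotropyTrace",
    "AnisotropyModel",
    "anisotropy",
    "isotropic",
    "fit_anisotropy",
]

#: hard upper bound on the decay lifetime, as a multiple of the trace span
DECAY_BOUND_FACTOR = 1e3
#: fitted decay lifetimes beyond this multiple of the span are reported as
#: unresolved (the trace is flat within the observation window)
DECAY_UNRESOLVED_FACTOR = 50.0


@dataclass(frozen=True)
class AnisotropyTrace:
    """Anisotropy r(t) with a validity mask.

    ``mask`` is True where the denominator I_par + 2 I_perp exceeded the
    threshold; r is NaN elsewhere.
    """

    times: np.ndarray
    r: np.ndarray
    mask: np.ndarray
    time_unit: str = "s"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.times) == len(self.r) == len(self.mask)):
            raise ValueError("times, r and mask must have equal length")

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(np.mean(self.mask))


@dataclass(frozen=True)
class AnisotropyModel:
    """Rise-times-decay parameterization of r(t).

    r(t) = [r_initial + (r_peak - r_initial)(1 - exp(-t/tau_rise))] * exp(-t/tau_decay)

    The functional form is a modeling choice of this package (experiments
    report timescales, not an equation); swap in another callable via
    ``fit_anisotropy(model_fn=...)`` if needed.
    """

    r_initial: float
    r_peak: float
    tau_rise: float
    tau_decay: float
    decay_at_bound: bool = False

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("anisotropy time constants must be positive")

    def __call__(self, t) -> np.ndarray:
        # before time zero the model holds its initial value
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        rise = self.r_initial + (self.r_peak - self.r_initial) * (
            1.0 - np.exp(-t / self.tau_rise)
        )
        return rise * np.exp(-t / self.tau_decay)


def _check_grids(par: TAMatrix, perp: TAMatrix):
    if par.times.shape != perp.times.shape or not np.allclose(
        par.times, perp.times
    ):
        raise ValueError("parallel/perpendicular time grids do not match")
    if par.wavelengths.shape != perp.wavelengths.shape or not np.allclose(
        par.wavelengths, perp.wavelengths
    ):
        raise ValueError("parallel/perpendicular wavelength grids do not match")
    if par.polarization != "parallel":
        raise ValueError(f"expected parallel matrix, got {par.polarization!r}")
    if perp.polarization != "perpendicular":
        raise ValueError(f"expected perpendicular matrix, got {perp.polarization!r}")


def anisotropy(
    par: TAMatrix,
    perp: TAMatrix,
    denom_threshold: float | None = None,
    band: tuple[float, float] | None = None,
) -> AnisotropyTrace:
    """Anisotropy trace from a polarized pair.

    With ``band=(lo, hi)`` the signals are integrated over that wavelength
    window before forming the ratio (single-wavelength anisotropy is
    noise-dominated); otherwise all wavelengths are averaged.  Points with
    ``|I_par + 2 I_perp|`` below ``denom_threshold`` are masked.  The
    default threshold is 5x a robust noise estimate of the denominator in
    the pre-time-zero region (or 0 when no such region exists).
    """
    _check_grids(par, perp)
    if band is not None:
        lo, hi = band
        sel = (par.wavelengths >= lo) & (par.wavelengths <= hi)
        if not np.any(sel):
            raise ValueError(f"no wavelengths inside band {band}")
    else:
        sel = slice(None)
    i_par = par.dA[:, sel].mean(axis=1)
    i_perp = perp.dA[:, sel].mean(axis=1)
    denom = i_par + 2.0 * i_perp
    if denom_threshold is None:
        denom_threshold = _default_denom_threshold(par.times, denom)
    mask = np.abs(denom) >= denom_threshold
    r = np.full_like(denom, np.nan)
    r[mask] = (i_par[mask] - i_perp[mask]) / denom[mask]
    return AnisotropyTrace(
        times=par.times,
        r=r,
        mask=mask,
        time_unit=par.time_unit,
        metadata={"denom_threshold": denom_threshold},
    )


def _default_denom_threshold(times: np.ndarray, denom: np.ndarray) -> float:
    pre = times < 0
    if np.sum(pre) >= 4:
        noise = 1.4826 * np.median(np.abs(denom[pre] - np.median(denom[pre])))
        return 5.0 * float(noise)
    return 0.0


def isotropic(par: TAMatrix, perp: TAMatrix) -> TAMatrix:
    """Isotropic matrix (I_par + 2 I_perp) / 3 from a polarized pair."""
    _check_grids(par, perp)
    iso = (par.dA + 2.0 * perp.dA) / 3.0
    return replace(par, dA=iso, polarization="isotropic")


def fit_anisotropy(
    trace: AnisotropyTrace,
    init: AnisotropyModel | None = None,
    model_fn=None,
) -> tuple[AnisotropyModel, dict[str, float]]:
    """Least-squares fit of the rise-times-decay anisotropy model.

    Returns the fitted model and a dict of standard errors.  A decay
    lifetime that runs into the upper bound (no decay resolved within the
    window) sets ``decay_at_bound`` on the returned model.
    """
    t = trace.times[trace.mask]
    r = trace.r[trace.mask]
    if t.size < 6:
        raise ValueError(f"need >= 6 unmasked points, got {t.size}")
    pos = t > 0
    t_fit, r_fit = t[pos], r[pos]
    if t_fit.size < 6:
        raise ValueError("need >= 6 unmasked points at t > 0")
    span = float(t_fit[-1] - t_fit[0])
    tau_max = DECAY_BOUND_FACTOR * span
    if init is None:
        init = AnisotropyModel(
            r_initial=float(r_fit[0]),
            r_peak=float(np.max(np.abs(r_fit)) * np.sign(np.mean(r_fit))),
            tau_rise=span / 50.0,
            tau_decay=span / 2.0,
        )

    def model(t, p):
        r0, rp, log_tr, log_td = p
        m = AnisotropyModel(
            r_initial=r0, r_peak=rp, tau_rise=np.exp(log_tr), tau_decay=np.exp(log_td)
        )
        return m(t) if model_fn is None else model_fn(t, m)

    x0 = np.array(
        [init.r_initial, init.r_peak, np.log(init.tau_rise), np.log(init.tau_decay)]
    )
    lo = [-np.inf, -np.inf, -np.inf, -np.inf]
    hi = [np.inf, np.inf, np.inf, np.log(tau_max)]
    sol = least_squares(
        lambda p: model(t_fit, p) - r_fit, x0, bounds=(lo, hi), x_scale="jac"
    )
    r0, rp, log_tr, log_td = sol.x
    at_bound = np.exp(log_td) >= DECAY_UNRESOLVED_FACTOR * span
    fitted = AnisotropyModel(
        r_initial=float(r0),
        r_peak=float(rp),
        tau_rise=float(np.exp(log_tr)),
        tau_decay=float(np.exp(log_td)),
        decay_at_bound=bool(at_bound),
    )
    stderr = _stderr(sol)
    return fitted, stderr


def _stderr(sol) -> dict[str, float]:
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return {
        "r_initial": float(se[0]),
        "r_peak": float(se[1]),
        "tau_rise": float(se[2] * np.exp(sol.x[2])),
        "tau_decay": float(se[3] * np.exp(sol.x[3])),
    }
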