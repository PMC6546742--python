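"""Global/target analysis of transient-absorption matrices.

Variable projection: the nonlinear kinetic parameters (log-lifetimes,
time zero, IRF width, logit branch fractions) are optimized with a
trust-region least-squares solver while the species-associated difference
spectra (SADS) are eliminated analytically at every iteration by linear
least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    ConcentrationProfiles,
    IRFModel,
    KineticScheme,
    exp_gauss,
    solve_scheme,
)

__all__ = [
    "TAMatrix",
    "SADSet",
    "FitResult",
    "svd_rank",
    "project_sads",
    "fit_target",
    "fit_das",
    "branch_yield",
]

POLARIZATIONS = ("parallel", "perpendicular", "magic", "isotropic")


@dataclass(frozen=True)
class TAMatrix:
    """Difference-absorbance matrix over a time x wavelength grid.

    ``times`` are stored in seconds; ``time_unit`` records the display
    unit used at the I/O boundary.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    dA: np.ndarray
    polarization: str = "magic"
    time_unit: str = "s"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        wavelengths = np.asarray(self.wavelengths, dtype=float)
        dA = np.asarray(self.dA, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wavelengths", wavelengths)
        object.__setattr__(self, "dA", dA)
        if dA.shape != (times.size, wavelengths.size):
            raise ValueError(
                f"dA shape {dA.shape} does not match grids "
                f"({times.size} times, {wavelengths.size} wavelengths)"
            )
        if not np.all(np.isfinite(dA)):
            raise ValueError("dA contains non-finite entries")
        if self.polarization not in POLARIZATIONS:
            raise ValueError(
                f"polarization must be one of {POLARIZATIONS}, got {self.polarization!r}"
            )


@dataclass(frozen=True)
class SADSet:
    """Per-compartment difference spectra on a common wavelength grid."""

    labels: tuple[str, ...]
    wavelengths: np.ndarray
    spectra: np.ndarray  # shape (n_wavelengths, n_components)
    spectra_se: np.ndarray | None = None

    def __post_init__(self):
        spectra = np.asarray(self.spectra, dtype=float)
        object.__setattr__(self, "spectra", spectra)
        if spectra.shape != (len(self.wavelengths), len(self.labels)):
            raise ValueError("SADS matrix shape does not match labels/wavelengths")

    def spectrum(self, label: str) -> np.ndarray:
        return self.spectra[:, self.labels.index(label)]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a global/target fit."""

    params: dict[str, float]
    stderr: dict[str, float]
    sads: SADSet
    profiles: ConcentrationProfiles
    residual: np.ndarray
    rms: float
    converged: bool
    n_iter: int
    message: str = ""
    scheme: KineticScheme | None = None
    irf: IRFModel | None = None
    diagnostics: dict = field(default_factory=dict)


def svd_rank(ta: TAMatrix, threshold_strategy=None) -> tuple[int, np.ndarray]:
    """Estimate the number of spectrotemporal components by SVD.

    The default strategy counts singular values exceeding 3x the median of
    the trailing half of the spectrum (a robust noise-floor estimate).  A
    custom ``threshold_strategy`` receives the singular values and returns
    the threshold.
    """
    if ta.dA.size == 0:
        raise ValueError("empty TA matrix")
    s = np.linalg.svd(ta.dA, compute_uv=False)
    if threshold_strategy is None:
        tail = s[len(s) // 2 :]
        noise_floor = 3.0 * np.median(tail)
        # numerical floor keeps noiseless matrices from reporting eps-level
        # singular values as components
        eps_floor = s[0] * max(ta.dA.shape) * np.finfo(float).eps * 10
        threshold = max(noise_floor, eps_floor)
    else:
        threshold = float(threshold_strategy(s))
    rank = int(np.sum(s > threshold))
    return rank, s


def project_sads(ta: TAMatrix, profiles: ConcentrationProfiles) -> SADSet:
    """Linear least-squares extraction of component spectra.

    Solves ``dA ~= C S^T`` per wavelength — the inner (linear) step of
    variable projection.  Raises on collinear concentration profiles,
    naming the offending compartments.
    """
    if profiles.c.shape[0] != ta.times.size:
        raise ValueError("concentration profiles not on the TA time grid")
    C = profiles.c
    _check_collinearity(C, profiles.labels)
    S, *_ = np.linalg.lstsq(C, ta.dA, rcond=None)
    # per-wavelength standard errors from the normal-equation covariance
    resid = ta.dA - C @ S
    dof = max(C.shape[0] - C.shape[1], 1)
    sigma2 = np.sum(resid**2, axis=0) / dof
    diag_cinv = np.diag(np.linalg.inv(C.T @ C))
    se = np.sqrt(np.outer(sigma2, diag_cinv))
    return SADSet(
        labels=profiles.labels,
        wavelengths=ta.wavelengths,
        spectra=S.T,
        spectra_se=se,
    )


def _check_collinearity(C: np.ndarray, labels: tuple[str, ...]):
    norms = np.linalg.norm(C, axis=0)
    if np.any(norms == 0):
        dead = [l for l, nv in zip(labels, norms) if nv == 0]
        raise ValueError(f"zero concentration profile(s): {dead}")
    G = (C / norms).T @ (C / norms)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(G[i, j]) > 1.0 - 1e-10:
                raise ValueError(
                    f"collinear concentration profiles: {labels[i]!r} and {labels[j]!r}"
                )
    if np.linalg.matrix_rank(C) < n:
        raise ValueError(f"rank-deficient profile matrix over {labels}")


# ---------------------------------------------------------------------------
# parameter transforms: lifetimes and sigma on log scale, branch fractions
# through a logit, t0 untransformed — keeps the optimizer unconstrained.


def _encode(name: str, value: float, t_scale: float = 1.0) -> float:
    if name.startswith("tau:") or name == "sigma":
        return math.log(value)
    if name.startswith("phi:"):
        v = min(max(value, 1e-12), 1 - 1e-12)
        return math.log(v / (1 - v))
    if name == "t0":
        # raw t0 is measured in units of the data time span so that
        # finite-difference steps stay inside the measurement window
        return value / t_scale
    return value


def _decode(name: str, raw: float, t_scale: float = 1.0) -> float:
    if name.startswith("tau:") or name == "sigma":
        return math.exp(raw)
    if name.startswith("phi:"):
        r = min(max(raw, -700.0), 700.0)
        return 1.0 / (1.0 + math.exp(-r))
    if name == "t0":
        return raw * t_scale
    return raw


def _decode_grad(name: str, raw: float, t_scale: float = 1.0) -> float:
    """d(value)/d(raw) for delta-method standard errors."""
    if name.startswith("tau:") or name == "sigma":
        return math.exp(raw)
    if name.startswith("phi:"):
        r = min(max(raw, -700.0), 700.0)
        p = 1.0 / (1.0 + math.exp(-r))
        return p * (1 - p)
    if name == "t0":
        return t_scale
    return 1.0


def _apply_params(
    scheme: KineticScheme, irf: IRFModel, values: dict[str, float]
) -> tuple[KineticScheme, IRFModel]:
    rates = list(scheme.rates)
    idx = scheme.index
    branching = dict(scheme.branching)
    for name, v in values.items():
        if name.startswith("tau:"):
            rates[idx[name[4:]]] = 1.0 / v
        elif name.startswith("phi:"):
            parent, child = name[4:].split("->")
            old_total = sum(b for (p, _), b in scheme.branching.items() if p == parent)
            others = [
                (p, c)
                for (p, c) in scheme.branching
                if p == parent and c != child
            ]
            rest_old = sum(scheme.branching[e] for e in others)
            branching[(parent, child)] = v
            # remaining siblings rescaled to keep the parent's total flux share
            if others:
                scale = (old_total - v) / rest_old if rest_old > 0 else 0.0
                for e in others:
                    branching[e] = scheme.branching[e] * scale
    new_scheme = replace(scheme, rates=tuple(rates), branching=branching)
    new_irf = IRFModel(
        t0=values.get("t0", irf.t0), sigma=values.get("sigma", irf.sigma)
    )
    return new_scheme, new_irf


def _default_free(scheme: KineticScheme) -> tuple[str, ...]:
    free = [
        f"tau:{c}"
        for c, k in zip(scheme.compartments, scheme.rates)
        if k > 0
    ]
    return tuple(free)


def fit_target(
    ta: TAMatrix,
    scheme: KineticScheme,
    irf: IRFModel,
    free: tuple[str, ...] | None = None,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed_sads: dict[str, np.ndarray] | None = None,
) -> FitResult:
    """Variable-projection fit of a compartmental scheme to a TA matrix.

    Parameters
    ----------
    free
        Names of the nonlinear parameters to optimize: ``"tau:<label>"``
        for lifetimes, ``"phi:<parent>-><child>"`` for branch fractions
        (siblings rescaled to preserve the parent's total flux), ``"t0"``
        and ``"sigma"`` for the IRF.  Defaults to all finite lifetimes.
    init
        Starting values in natural units; parameters absent from ``init``
        start at the values carried by ``scheme``/``irf``.
    bounds
        Natural-scale box constraints per parameter.
    fixed_sads
        Spectra (on the TA wavelength grid) of compartments whose SADS are
        known a priori — e.g. a photoproduct difference spectrum measured
        independently on a slower timescale.  Fixing a spectrum makes the
        branch fraction feeding that compartment identifiable; with all
        SADS free the branching only rescales spectra and is structurally
        unidentifiable.

    Non-convergence is reported through ``FitResult.converged``; only
    invalid input raises.
    """
    if free is None:
        free = _default_free(scheme)
    free = tuple(free)
    t_scale = float(ta.times[-1] - ta.times[0])
    current = _current_values(scheme, irf, free)
    if init:
        for name, v in init.items():
            if name not in free:
                raise ValueError(f"init given for non-free parameter {name!r}")
            current[name] = v
    lo, hi = _encoded_bounds(free, bounds, t_scale)
    x0 = np.array([_encode(n, current[n], t_scale) for n in free])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial values lie outside the given bounds")

    n_free = len(free)
    if ta.times.size < n_free + len(scheme.compartments):
        raise ValueError("fewer time points than free parameters + compartments")
    fixed_idx: list[int] = []
    fixed_S: np.ndarray | None = None
    if fixed_sads:
        unknown = set(fixed_sads) - set(scheme.compartments)
        if unknown:
            raise ValueError(f"fixed_sads for unknown compartments: {sorted(unknown)}")
        fixed_idx = [scheme.compartments.index(c) for c in fixed_sads]
        fixed_S = np.column_stack(
            [np.asarray(fixed_sads[c], dtype=float) for c in fixed_sads]
        )
        if fixed_S.shape[0] != ta.wavelengths.size:
            raise ValueError("fixed SADS not on the TA wavelength grid")

    def build(x: np.ndarray) -> tuple[KineticScheme, IRFModel]:
        values = {n: _decode(n, xi, t_scale) for n, xi in zip(free, x)}
        return _apply_params(scheme, irf, values)

    def split_solve(C: np.ndarray) -> np.ndarray:
        """Full SADS matrix (n_wl x n_comp), fixed columns imposed."""
        n_comp = C.shape[1]
        if fixed_S is None:
            S, *_ = np.linalg.lstsq(C, ta.dA, rcond=None)
            return S.T
        free_cols = [j for j in range(n_comp) if j not in fixed_idx]
        data = ta.dA - C[:, fixed_idx] @ fixed_S.T
        S_free, *_ = np.linalg.lstsq(C[:, free_cols], data, rcond=None)
        S_full = np.empty((ta.wavelengths.size, n_comp))
        for pos, j in enumerate(fixed_idx):
            S_full[:, j] = fixed_S[:, pos]
        for pos, j in enumerate(free_cols):
            S_full[:, j] = S_free[pos]
        return S_full

    def residuals(x: np.ndarray) -> np.ndarray:
        sch, ir = build(x)
        C = solve_scheme(sch, ir, ta.times).c
        S = split_solve(C)
        return (ta.dA - C @ S.T).ravel()

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac")

    sch, ir = build(sol.x)
    profiles = solve_scheme(sch, ir, ta.times)
    S_full = split_solve(profiles.c)
    sads = SADSet(
        labels=scheme.compartments, wavelengths=ta.wavelengths, spectra=S_full
    )
    residual = ta.dA - profiles.c @ S_full.T
    rms = float(np.sqrt(np.mean(residual**2)))

    params = {n: _decode(n, xi, t_scale) for n, xi in zip(free, sol.x)}
    stderr = _asymptotic_stderr(sol, free, t_scale)
    converged = bool(sol.status > 0)
    return FitResult(
        params=params,
        stderr=stderr,
        sads=sads,
        profiles=profiles,
        residual=residual,
        rms=rms,
        converged=converged,
        n_iter=int(sol.nfev),
        message=sol.message,
        scheme=sch,
        irf=ir,
        diagnostics={"cost": float(sol.cost), "status": int(sol.status)},
    )


def _current_values(
    scheme: KineticScheme, irf: IRFModel, free: tuple[str, ...]
) -> dict[str, float]:
    idx = scheme.index
    out: dict[str, float] = {}
    for name in free:
        if name.startswith("tau:"):
            label = name[4:]
            if label not in idx:
                raise ValueError(f"unknown compartment in {name!r}")
            k = scheme.rates[idx[label]]
            if k == 0:
                raise ValueError(f"cannot free the lifetime of non-decaying {label!r}")
            out[name] = 1.0 / k
        elif name.startswith("phi:"):
            edge = tuple(name[4:].split("->"))
            if edge not in scheme.branching:
                raise ValueError(f"unknown branching edge in {name!r}")
            out[name] = scheme.branching[edge]
        elif name == "t0":
            out[name] = irf.t0
        elif name == "sigma":
            out[name] = irf.sigma
        else:
            raise ValueError(f"unknown parameter name {name!r}")
    return out


def _encoded_bounds(free, bounds, t_scale: float = 1.0):
    lo = np.full(len(free), -np.inf)
    hi = np.full(len(free), np.inf)
    if bounds:
        for i, name in enumerate(free):
            if name in bounds:
                a, b = bounds[name]
                lo[i] = _encode(name, a, t_scale)
                hi[i] = _encode(name, b, t_scale)
    return lo, hi


def _asymptotic_stderr(sol, free, t_scale: float = 1.0) -> dict[str, float]:
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * sol.cost / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(JtJ) * s2
        raw_se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        raw_se = np.full(n, np.nan)
    return {
        name: float(raw_se[i] * abs(_decode_grad(name, sol.x[i], t_scale)))
        for i, name in enumerate(free)
    }


def fit_das(
    ta: TAMatrix,
    n_components: int,
    init: dict[str, float] | list[float] | None = None,
    irf: IRFModel | None = None,
    fit_irf: bool = False,
) -> FitResult:
    """Decay-associated-spectra fit: parallel unbranched multi-exponentials.

    Lifetimes are reported sorted ascending with labels ``DAS1..DASn``
    assigned in that order.  A fit requesting more components than the
    matrix supports is flagged ill-conditioned, not raised.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if irf is None:
        irf = IRFModel(t0=0.0, sigma=_default_sigma(ta))
    taus = _das_init(ta, n_components, init)
    labels = tuple(f"DAS{i + 1}" for i in range(n_components))
    free = [f"tau:{l}" for l in labels]
    if fit_irf:
        free += ["t0", "sigma"]
    t_scale = float(ta.times[-1] - ta.times[0])

    def build_profiles(x, times):
        vals = {n: _decode(n, xi, t_scale) for n, xi in zip(free, x)}
        ir = IRFModel(
            t0=vals.get("t0", irf.t0), sigma=vals.get("sigma", irf.sigma)
        )
        C = np.column_stack(
            [exp_gauss(1.0 / vals[f"tau:{l}"], ir, times) for l in labels]
        )
        return C, ir

    def residuals(x):
        C, _ = build_profiles(x, ta.times)
        S, *_ = np.linalg.lstsq(C, ta.dA, rcond=None)
        return (ta.dA - C @ S).ravel()

    x0 = [_encode(f"tau:{l}", tau) for l, tau in zip(labels, taus)]
    if fit_irf:
        x0 += [_encode("t0", irf.t0, t_scale), _encode("sigma", irf.sigma)]
    sol = least_squares(residuals, np.array(x0), method="trf", x_scale="jac")

    vals = {n: _decode(n, xi, t_scale) for n, xi in zip(free, sol.x)}
    order = np.argsort([vals[f"tau:{l}"] for l in labels])
    sorted_taus = [vals[f"tau:{labels[i]}"] for i in order]

    C, ir = build_profiles(sol.x, ta.times)
    C = C[:, order]
    ill_conditioned = False
    try:
        _check_collinearity(C, labels)
    except ValueError:
        ill_conditioned = True
    S, *_ = np.linalg.lstsq(C, ta.dA, rcond=None)
    profiles = ConcentrationProfiles(times=ta.times, labels=labels, c=C)
    sads = SADSet(labels=labels, wavelengths=ta.wavelengths, spectra=S.T)
    residual = ta.dA - C @ S
    rms = float(np.sqrt(np.mean(residual**2)))

    stderr_raw = _asymptotic_stderr(sol, free, t_scale)
    params = {f"tau:{l}": tau for l, tau in zip(labels, sorted_taus)}
    stderr = {
        f"tau:{labels[i]}": stderr_raw[f"tau:{labels[int(pi)]}"]
        for i, pi in enumerate(order)
    }
    for extra in ("t0", "sigma"):
        if extra in vals:
            params[extra] = vals[extra]
            stderr[extra] = stderr_raw[extra]
    cond = float(np.linalg.cond(C))
    if cond > 1e8:
        ill_conditioned = True
    data_rank, _ = svd_rank(ta)
    if n_components > data_rank:
        ill_conditioned = True
    return FitResult(
        params=params,
        stderr=stderr,
        sads=sads,
        profiles=profiles,
        residual=residual,
        rms=rms,
        converged=bool(sol.status > 0) and not ill_conditioned,
        n_iter=int(sol.nfev),
        message=sol.message if not ill_conditioned else "ill-conditioned DAS fit",
        irf=ir,
        diagnostics={
            "cost": float(sol.cost),
            "condition_number": cond,
            "data_rank": data_rank,
            "ill_conditioned": ill_conditioned,
        },
    )


def _default_sigma(ta: TAMatrix) -> float:
    dt = np.diff(ta.times)
    return float(np.min(dt[dt > 0]) / 2.0)


def _das_init(ta, n, init):
    if init is None:
        span = ta.times[-1] - ta.times[0]
        base = max(span / 100.0, 1e-18)
        return list(np.geomspace(base, span, n))
    if isinstance(init, dict):
        return [init[f"tau:DAS{i + 1}"] for i in range(n)]
    if len(init) != n:
        raise ValueError("init must provide one lifetime per component")
    return list(init)


def branch_yield(fit: FitResult) -> tuple[float, float]:
    """Fitted branching fraction into the photoproduct, with standard error.

    This is a kinetic-branching surrogate for an actinometric quantum
    yield: it reports the fraction of excited-state decay that feeds the
    persistent product compartment in the fitted scheme.
    """
    phis = [n for n in fit.params if n.startswith("phi:")]
    if not phis:
        raise ValueError("fit does not contain a free branching fraction")
    if len(phis) > 1:
        raise ValueError(f"ambiguous branching parameters: {phis}")
    name = phis[0]
    return fit.params[name], fit.stderr[name]
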