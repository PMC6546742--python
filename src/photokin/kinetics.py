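"""First-order branching photokinetics convolved with a Gaussian IRF.

Compartmental schemes are restricted to feed-forward (acyclic) networks of
first-order decays.  Concentration profiles are computed analytically as
superpositions of exponential-times-Gaussian convolution terms; a numeric
ODE fallback handles near-degenerate rate pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import erfc, erfcx

__all__ = [
    "IRFModel",
    "KineticScheme",
    "ConcentrationProfiles",
    "exp_gauss",
    "solve_scheme",
    "isomerization_scheme",
]

#: relative rate difference below which the analytic cascade is abandoned
#: in favour of numeric ODE integration (near-degenerate denominators).
DEGENERACY_RTOL = 1e-9

_SQRT2 = math.sqrt(2.0)
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: centre ``t0`` and width ``sigma`` (s)."""

    t0: float = 0.0
    sigma: float = 1e-13

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"IRF sigma must be positive, got {self.sigma}")

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma


@dataclass(frozen=True)
class KineticScheme:
    """Feed-forward compartmental scheme of first-order decays.

    Parameters
    ----------
    compartments
        Ordered compartment labels.
    rates
        Decay constant ``k_i`` (1/s) per compartment, in compartment order.
        ``k = 0`` marks a non-decaying (persistent) compartment.
    branching
        Mapping ``(parent, child) -> fraction`` of the parent's decay flux
        feeding the child.  Per-parent fractions must sum to at most 1; the
        remainder is loss to a spectrally silent ground state.
    initial
        Initial (photoexcited) population per compartment.
    """

    compartments: tuple[str, ...]
    rates: tuple[float, ...]
    branching: dict[tuple[str, str], float] = field(default_factory=dict)
    initial: tuple[float, ...] = ()

    def __post_init__(self):
        n = len(self.compartments)
        if len(set(self.compartments)) != n:
            raise ValueError("compartment labels must be unique")
        if len(self.rates) != n:
            raise ValueError("one rate per compartment required")
        if any(k < 0 for k in self.rates):
            raise ValueError("rates must be nonnegative")
        if not self.initial:
            object.__setattr__(
                self, "initial", (1.0,) + (0.0,) * (n - 1) if n else ()
            )
        if len(self.initial) != n:
            raise ValueError("one initial population per compartment required")
        idx = {c: i for i, c in enumerate(self.compartments)}
        sums: dict[str, float] = {}
        for (p, c), b in self.branching.items():
            if p not in idx or c not in idx:
                raise ValueError(f"branching references unknown compartment in {(p, c)}")
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"branching fraction b[{p}->{c}]={b} outside [0, 1]")
            sums[p] = sums.get(p, 0.0) + b
        for p, s in sums.items():
            if s > 1.0 + 1e-12:
                raise ValueError(f"branching fractions out of {p} sum to {s} > 1")
        self._toposort()  # raises on cycles

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.compartments)}

    def children(self, parent: str) -> list[tuple[str, float]]:
        return [(c, b) for (p, c), b in self.branching.items() if p == parent]

    def parents(self, child: str) -> list[tuple[str, float]]:
        return [(p, b) for (p, c), b in self.branching.items() if c == child]

    def _toposort(self) -> list[str]:
        order: list[str] = []
        mark: dict[str, int] = {}

        def visit(node: str):
            state = mark.get(node, 0)
            if state == 1:
                raise ValueError("cyclic kinetic scheme: feed-forward networks only")
            if state == 2:
                return
            mark[node] = 1
            for child, _ in self.children(node):
                visit(child)
            mark[node] = 2
            order.append(node)

        for c in self.compartments:
            visit(c)
        order.reverse()
        return order

    def rate_matrix(self) -> np.ndarray:
        """Transfer matrix A with dc/dt = A c (no IRF source)."""
        n = len(self.compartments)
        idx = self.index
        A = np.zeros((n, n))
        for i, k in enumerate(self.rates):
            A[i, i] = -k
        for (p, c), b in self.branching.items():
            A[idx[c], idx[p]] += b * self.rates[idx[p]]
        return A

    def lifetimes(self) -> dict[str, float]:
        return {
            c: (math.inf if k == 0 else 1.0 / k)
            for c, k in zip(self.compartments, self.rates)
        }


@dataclass(frozen=True)
class ConcentrationProfiles:
    """Per-compartment populations on a common time grid (seconds)."""

    times: np.ndarray
    labels: tuple[str, ...]
    c: np.ndarray  # shape (n_times, n_compartments)

    def __post_init__(self):
        if self.c.shape != (len(self.times), len(self.labels)):
            raise ValueError("profile matrix shape does not match grids")


def exp_gauss(k: float, irf: IRFModel, t) -> np.ndarray:
    """Exponential decay convolved with a unit-area Gaussian IRF.

    Returns the closed-form convolution of ``H(t - t0) exp(-k (t - t0))``
    with a Gaussian of width ``irf.sigma`` centred at ``irf.t0``:

        0.5 * exp(b^2/2 - b u) * erfc((b - u) / sqrt(2))

    with ``u = (t - t0)/sigma`` and ``b = k sigma``.  Evaluated through the
    scaled complementary error function where the plain form would
    overflow (``b`` can exceed 20 when ms-scale rates meet fs grids).
    """
    if k < 0:
        raise ValueError(f"decay rate must be nonnegative, got {k}")
    t = np.asarray(t, dtype=float)
    u = (t - irf.t0) / irf.sigma
    b = k * irf.sigma
    arg = (b - u) / _SQRT2
    out = np.empty_like(u)
    pos = arg >= 0
    # erfcx form: erfc(arg) * exp(b^2/2 - b u) == erfcx(arg) * exp(-u^2/2)
    out[pos] = 0.5 * erfcx(arg[pos]) * np.exp(-0.5 * u[pos] ** 2)
    neg = ~pos
    # here b^2/2 - b u = (u-b)^2/2 - u^2/2 < 0, so the direct form is safe
    out[neg] = 0.5 * np.exp(0.5 * b * b - b * u[neg]) * erfc(arg[neg])
    return out


def _analytic_coefficients(scheme: KineticScheme) -> np.ndarray | None:
    """Coefficients a[i, j] with c_i(t) = sum_j a[i, j] E_j(t), E_j the
    IRF-convolved exponential at compartment j's rate.

    Returns None when two rates along a feed path are nearly degenerate,
    signalling the caller to fall back to numeric integration.
    """
    n = len(scheme.compartments)
    idx = scheme.index
    rates = np.asarray(scheme.rates)
    kmax = max(rates.max(), 1.0)
    a = np.zeros((n, n))
    for i, x0 in enumerate(scheme.initial):
        a[i, i] += x0
    for label in scheme._toposort():
        i = idx[label]
        for child, b in scheme.children(label):
            j = idx[child]
            kj = rates[j]
            for m in range(n):
                if a[i, m] == 0.0:
                    continue
                km = rates[m]
                if abs(kj - km) <= DEGENERACY_RTOL * kmax:
                    return None
                w = b * rates[i] * a[i, m] / (kj - km)
                a[j, m] += w
                a[j, j] -= w
    return a


def _numeric_profiles(
    scheme: KineticScheme, irf: IRFModel, times: np.ndarray
) -> np.ndarray:
    """ODE integration with the IRF as a Gaussian source term."""
    A = scheme.rate_matrix()
    x0 = np.asarray(scheme.initial, dtype=float)
    s = irf.sigma

    def rhs(t, c):
        g = math.exp(-0.5 * ((t - irf.t0) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        return A @ c + g * x0

    t_start = min(times[0], irf.t0 - 8 * s)
    sol = solve_ivp(
        rhs,
        (t_start, times[-1]),
        np.zeros_like(x0),
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        max_step=max(s, (times[-1] - t_start) / 50),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def solve_scheme(
    scheme: KineticScheme, irf: IRFModel, times
) -> ConcentrationProfiles:
    """IRF-convolved concentration profiles of a feed-forward scheme.

    Uses the analytic cascade of ``exp_gauss`` terms; switches to numeric
    ODE integration when two rates on a feed path differ by less than
    ``DEGENERACY_RTOL`` relative.
    """
    times = np.asarray(times, dtype=float)
    coeff = _analytic_coefficients(scheme)
    if coeff is None:
        c = _numeric_profiles(scheme, irf, times)
    else:
        basis = np.column_stack([exp_gauss(k, irf, times) for k in scheme.rates])
        c = basis @ coeff.T
    return ConcentrationProfiles(times=times, labels=scheme.compartments, c=c)


def isomerization_scheme(
    tau_S2: float, tau_S1: float, phi_E: float, tau_cool: float
) -> KineticScheme:
    """Branching photo-isomerization scheme S2 -> S1 -> {hot Z, E}.

    S2 converts internally to S1; S1 decays with branch fraction ``phi_E``
    into the persistent E photoproduct and ``1 - phi_E`` into the hot Z
    ground state, which cools into the (spectrally silent) relaxed Z with
    lifetime ``tau_cool``.  E does not decay on the fs-ps window.
    """
    for name, tau in (("tau_S2", tau_S2), ("tau_S1", tau_S1), ("tau_cool", tau_cool)):
        if tau <= 0:
            raise ValueError(f"{name} must be positive, got {tau}")
    if not 0.0 <= phi_E <= 1.0:
        raise ValueError(f"phi_E must lie in [0, 1], got {phi_E}")
    return KineticScheme(
        compartments=("S2", "S1", "hotZ", "E"),
        rates=(1.0 / tau_S2, 1.0 / tau_S1, 1.0 / tau_cool, 0.0),
        branching={
            ("S2", "S1"): 1.0,
            ("S1", "hotZ"): 1.0 - phi_E,
            ("S1", "E"): phi_E,
        },
        initial=(1.0, 0.0, 0.0, 0.0),
    )
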