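"""Synthetic data generation for every stage of the analysis chain.

Each generator embeds its ground truth in the output metadata so recovery
tests can compare fitted against generating parameters.  All randomness
flows through the mandatory seed in :class:`GeneratorConfig`; identical
config and seed give bit-identical output.

Noise model: additive i.i.d. Gaussian on absorbance-like signals,
multiplicative log-normal on rate constants.  Absorption bands are
Gaussian in wavelength — a modeling choice, band shapes are otherwise
unconstrained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .anisotropy import AnisotropyModel
from .kinetics import IRFModel, KineticScheme, solve_scheme
from .relaxation import LN2, DecayTrace, RateMeasurement, RateSeries
from .spectra import Spectrum
from .targetfit import SADSet, TAMatrix
from .units import to_seconds

__all__ = [
    "GeneratorConfig",
    "make_ta_dataset",
    "make_polarized_pair",
    "make_decay_trace",
    "make_rate_series",
    "make_absorption_spectrum",
    "make_nmr_series",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded generator settings.

    ``time_grid`` values are interpreted in ``time_unit`` and converted to
    seconds internally; ``wavelength_grid`` is in nm.
    """

    seed: int
    noise_sd: float = 0.0
    time_grid: np.ndarray | None = None
    time_unit: str = "s"
    wavelength_grid: np.ndarray | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        for name, grid in (
            ("time_grid", self.time_grid),
            ("wavelength_grid", self.wavelength_grid),
        ):
            if grid is not None:
                arr = np.asarray(grid, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.size >= 2 and np.any(np.diff(arr) <= 0):
                    raise ValueError(f"{name} must be strictly increasing")
        # validate unit token eagerly
        to_seconds(1.0, self.time_unit)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def times_s(self) -> np.ndarray:
        if self.time_grid is None:
            raise ValueError("config has no time grid")
        return to_seconds(self.time_grid, self.time_unit)


def make_ta_dataset(
    scheme: KineticScheme,
    sads: SADSet,
    irf: IRFModel,
    cfg: GeneratorConfig,
) -> TAMatrix:
    """Forward-model a TA matrix: dA = C(t) SADS^T + Gaussian noise."""
    if tuple(sads.labels) != tuple(scheme.compartments):
        raise ValueError(
            f"scheme compartments {scheme.compartments} do not match "
            f"SADS components {sads.labels}"
        )
    if cfg.time_grid is None or cfg.time_grid.size == 0:
        raise ValueError("config time grid is empty")
    if cfg.wavelength_grid is None or cfg.wavelength_grid.size == 0:
        raise ValueError("config wavelength grid is empty")
    if len(sads.wavelengths) != len(cfg.wavelength_grid):
        raise ValueError("SADS wavelength grid does not match config grid")
    times = cfg.times_s
    profiles = solve_scheme(scheme, irf, times)
    dA = profiles.c @ sads.spectra.T
    if cfg.noise_sd > 0:
        dA = dA + cfg.rng().normal(0.0, cfg.noise_sd, size=dA.shape)
    truth = {
        "lifetimes_s": scheme.lifetimes(),
        "branching": {f"{p}->{c}": b for (p, c), b in scheme.branching.items()},
        "irf_t0_s": irf.t0,
        "irf_sigma_s": irf.sigma,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    return TAMatrix(
        times=times,
        wavelengths=cfg.wavelength_grid,
        dA=dA,
        polarization="isotropic",
        time_unit=cfg.time_unit,
        metadata={"truth": truth},
    )


def make_polarized_pair(
    iso: TAMatrix, r_model: AnisotropyModel
) -> tuple[TAMatrix, TAMatrix]:
    """Split an isotropic matrix into I_par = I(1+2r), I_perp = I(1-r)."""
    r = r_model(iso.times)
    if np.any(r < -0.2) or np.any(r > 0.4):
        raise ValueError("anisotropy model leaves the physical range [-0.2, 0.4]")
    par = iso.dA * (1.0 + 2.0 * r)[:, None]
    perp = iso.dA * (1.0 - r)[:, None]
    meta = dict(iso.metadata)
    meta["truth_anisotropy"] = {
        "r_initial": r_model.r_initial,
        "r_peak": r_model.r_peak,
        "tau_rise_s": r_model.tau_rise,
        "tau_decay_s": r_model.tau_decay,
    }
    return (
        replace(iso, dA=par, polarization="parallel", metadata=meta),
        replace(iso, dA=perp, polarization="perpendicular", metadata=meta),
    )


def make_decay_trace(
    t_half: float,
    amplitude: float,
    baseline: float,
    cfg: GeneratorConfig,
    t_half_unit: str | None = None,
    label: str = "",
) -> DecayTrace:
    """baseline + amplitude 2^(-t/t_half) + Gaussian noise.

    ``t_half`` is read in ``t_half_unit`` (defaults to the config time
    unit).
    """
    if t_half <= 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    if cfg.time_grid is None:
        raise ValueError("config has no time grid")
    t = cfg.times_s
    t_half_s = to_seconds(t_half, t_half_unit or cfg.time_unit)
    signal = baseline + amplitude * np.exp(-LN2 * t / t_half_s)
    if cfg.noise_sd > 0:
        signal = signal + cfg.rng().normal(0.0, cfg.noise_sd, size=signal.shape)
    return DecayTrace(
        times=t,
        signal=signal,
        time_unit=cfg.time_unit,
        label=label,
        metadata={
            "truth": {
                "t_half_s": t_half_s,
                "k_per_s": LN2 / t_half_s,
                "amplitude": amplitude,
                "baseline": baseline,
                "noise_sd": cfg.noise_sd,
                "seed": cfg.seed,
            }
        },
    )


def make_rate_series(
    dH: float,
    dS: float,
    temperatures,
    cfg: GeneratorConfig,
    rel_noise: float = 0.0,
) -> RateSeries:
    """Eyring-consistent k(T) = (k_B T/h) exp(-dH/RT + dS/R).

    ``dH`` in kJ/mol, ``dS`` in J/(K mol).  ``rel_noise`` applies
    multiplicative log-normal noise (sigma of log = rel_noise).
    """
    from scipy.constants import R, h, k as k_B

    temperatures = np.asarray(temperatures, dtype=float)
    if np.any(temperatures <= 0):
        raise ValueError("temperatures must be positive")
    k = (k_B * temperatures / h) * np.exp(
        -dH * 1000.0 / (R * temperatures) + dS / R
    )
    rng = cfg.rng()
    measurements = []
    for T, ki in zip(temperatures, k):
        if rel_noise > 0:
            ki = ki * math.exp(rng.normal(0.0, rel_noise))
        measurements.append(
            RateMeasurement(k=float(ki), T=float(T), k_se=float(ki * rel_noise))
        )
    return RateSeries(measurements=tuple(measurements))


def make_absorption_spectrum(
    bands: list[tuple[float, float, float]],
    cfg: GeneratorConfig,
    label: str = "mixture",
) -> Spectrum:
    """Sum of Gaussian bands (center nm, width nm, height) plus noise."""
    if cfg.wavelength_grid is None:
        raise ValueError("config has no wavelength grid")
    wl = cfg.wavelength_grid
    ab = np.zeros_like(wl)
    for center, width, height in bands:
        if width <= 0:
            raise ValueError(f"band width must be positive, got {width}")
        ab = ab + height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if cfg.noise_sd > 0:
        ab = ab + cfg.rng().normal(0.0, cfg.noise_sd, size=ab.shape)
    return Spectrum(
        wavelengths=wl,
        absorbance=ab,
        label=label,
        metadata={"truth": {"bands": list(bands), "seed": cfg.seed}},
    )


def make_nmr_series(
    pss_fraction: float,
    t_half: float,
    phases: tuple[float, float],
    cfg: GeneratorConfig,
    tau_approach: float | None = None,
    total_integral: float = 1.0,
) -> tuple[DecayTrace, DecayTrace]:
    """Z and E NMR-integral series across an irradiation + dark sequence.

    During irradiation (duration ``phases[0]``, config time units) the
    E-fraction relaxes toward ``pss_fraction`` with approach time constant
    ``tau_approach`` (default: a tenth of the irradiation phase); in the
    dark phase it decays exponentially with half-life ``t_half``.  Z and E
    integrals sum to ``total_integral`` at every point.
    """
    if not 0.0 <= pss_fraction <= 1.0:
        raise ValueError(f"pss_fraction must lie in [0, 1], got {pss_fraction}")
    if t_half <= 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    if cfg.time_grid is None:
        raise ValueError("config has no time grid")
    t = cfg.times_s
    irr_s = to_seconds(phases[0], cfg.time_unit)
    t_half_s = to_seconds(t_half, cfg.time_unit)
    if tau_approach is None:
        tau_app_s = irr_s / 10.0 if irr_s > 0 else t_half_s / 10.0
    else:
        tau_app_s = to_seconds(tau_approach, cfg.time_unit)
    f_e = np.empty_like(t)
    in_irr = t <= irr_s
    if irr_s > 0:
        f_e[in_irr] = pss_fraction * (1.0 - np.exp(-t[in_irr] / tau_app_s))
        f_irr_end = pss_fraction * (1.0 - math.exp(-irr_s / tau_app_s))
    else:
        # no irradiation window recorded: the series starts at the PSS
        # (sample switched before acquisition) and only the dark decay
        # is observed
        f_e[in_irr] = pss_fraction
        f_irr_end = pss_fraction
    dark = ~in_irr
    f_e[dark] = f_irr_end * np.exp(-LN2 * (t[dark] - irr_s) / t_half_s)
    e_signal = total_integral * f_e
    z_signal = total_integral * (1.0 - f_e)
    if cfg.noise_sd > 0:
        rng = cfg.rng()
        e_signal = e_signal + rng.normal(0.0, cfg.noise_sd, size=t.shape)
        z_signal = z_signal + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    truth = {
        "pss_fraction": pss_fraction,
        "t_half_s": t_half_s,
        "irradiation_s": irr_s,
        "tau_approach_s": tau_app_s,
        "total_integral": total_integral,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    mk = lambda sig, lab: DecayTrace(
        times=t,
        signal=sig,
        time_unit=cfg.time_unit,
        label=lab,
        metadata={"truth": truth},
    )
    return mk(z_signal, "Z"), mk(e_signal, "E")
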