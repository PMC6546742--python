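"""Ready-made demonstration model: an excited-state cascade photoswitch.

One place for the reference parameter set used by the examples, tests and
the acceptance script: internal conversion well below the IRF, excited-
state decay of 320 fs branching 6% into a persistent photoproduct,
vibrational cooling of 10 ps, IRF sigma 60 fs.  The SADS shapes are
arbitrary smooth bands (Gaussian in wavelength) chosen to be linearly
independent.
"""

from __future__ import annotations

import numpy as np

from .anisotropy import AnisotropyModel
from .kinetics import IRFModel, KineticScheme, isomerization_scheme
from .synthkit import GeneratorConfig, make_ta_dataset
from .targetfit import SADSet, TAMatrix

__all__ = [
    "CASCADE_TRUTH",
    "cascade_scheme",
    "cascade_irf",
    "cascade_sads",
    "cascade_ta",
    "cascade_anisotropy_model",
]

CASCADE_TRUTH = {
    "tau_S2_s": 50e-15,
    "tau_S1_s": 320e-15,
    "phi_E": 0.06,
    "tau_cool_s": 10e-12,
    "irf_sigma_s": 60e-15,
}


def cascade_scheme(
    tau_S2: float = CASCADE_TRUTH["tau_S2_s"],
    tau_S1: float = CASCADE_TRUTH["tau_S1_s"],
    phi_E: float = CASCADE_TRUTH["phi_E"],
    tau_cool: float = CASCADE_TRUTH["tau_cool_s"],
) -> KineticScheme:
    return isomerization_scheme(tau_S2, tau_S1, phi_E, tau_cool)


def cascade_irf(sigma: float = CASCADE_TRUTH["irf_sigma_s"]) -> IRFModel:
    return IRFModel(t0=0.0, sigma=sigma)


def cascade_sads(wavelengths: np.ndarray) -> SADSet:
    """Linearly independent demonstration SADS on ``wavelengths`` (nm)."""
    wl = np.asarray(wavelengths, dtype=float)
    band = lambda c, w, h: h * np.exp(-0.5 * ((wl - c) / w) ** 2)
    spectra = np.column_stack(
        [
            band(480, 60, 1.0),                       # S2: broad ESA
            band(520, 80, 0.9),                       # S1: broad, red-shifted ESA
            band(460, 40, 0.3),                       # hot Z: narrower hot band
            band(530, 25, 0.1) - band(430, 25, 0.08), # E: product difference spectrum
        ]
    )
    return SADSet(
        labels=("S2", "S1", "hotZ", "E"), wavelengths=wl, spectra=spectra
    )


def cascade_ta(
    seed: int,
    noise_frac: float = 0.0,
    n_times: int = 200,
    n_wavelengths: int = 64,
    t_max_ps: float = 500.0,
) -> TAMatrix:
    """Synthetic TA matrix from the cascade model.

    ``noise_frac`` is the Gaussian noise SD as a fraction of the peak
    |dA|.  The time grid is linear through time zero and logarithmic out
    to ``t_max_ps``.
    """
    n_lin = n_times // 2
    time_grid = np.concatenate(
        [
            np.linspace(-0.5, 2.0, n_lin),
            np.geomspace(2.1, t_max_ps, n_times - n_lin),
        ]
    )
    wl = np.linspace(420, 700, n_wavelengths)
    scheme = cascade_scheme()
    irf = cascade_irf()
    sads = cascade_sads(wl)
    clean_cfg = GeneratorConfig(
        seed=seed, noise_sd=0.0, time_grid=time_grid,
        time_unit="ps", wavelength_grid=wl,
    )
    if noise_frac == 0.0:
        return make_ta_dataset(scheme, sads, irf, clean_cfg)
    peak = float(np.abs(make_ta_dataset(scheme, sads, irf, clean_cfg).dA).max())
    cfg = GeneratorConfig(
        seed=seed, noise_sd=noise_frac * peak, time_grid=time_grid,
        time_unit="ps", wavelength_grid=wl,
    )
    return make_ta_dataset(scheme, sads, irf, cfg)


def cascade_anisotropy_model(
    tau_rise: float = 300e-15, tau_decay: float = 14e-12
) -> AnisotropyModel:
    """Anisotropy with a few-hundred-fs rise and a ~14 ps decay."""
    return AnisotropyModel(
        r_initial=0.1, r_peak=0.35, tau_rise=tau_rise, tau_decay=tau_decay
    )
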