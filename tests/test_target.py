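"""Unit tests for global/target analysis (SVD, variable projection, DAS)."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from photokin import (
    ConcentrationProfiles,
    GeneratorConfig,
    IRFModel,
    KineticScheme,
    SADSet,
    TAMatrix,
    branch_yield,
    exp_gauss,
    fit_das,
    fit_target,
    isomerization_scheme,
    make_ta_dataset,
    project_sads,
    solve_scheme,
    svd_rank,
)
from photokin.presets import cascade_sads, cascade_ta


def _three_component_ta(noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 10, 80)
    wl = np.linspace(400, 600, 40)
    C = np.column_stack(
        [np.exp(-t / 0.5), np.exp(-t / 2.0), np.exp(-t / 8.0)]
    )
    S = np.column_stack(
        [
            np.exp(-0.5 * ((wl - 450) / 30) ** 2),
            np.exp(-0.5 * ((wl - 500) / 40) ** 2),
            np.exp(-0.5 * ((wl - 550) / 25) ** 2),
        ]
    )
    dA = C @ S.T
    if noise_sd:
        dA = dA + rng.normal(0, noise_sd, dA.shape)
    return TAMatrix(times=t, wavelengths=wl, dA=dA, polarization="magic")


class TestSvdRank:
    def test_rank_one_outer_product(self):
        t = np.linspace(0, 5, 30)
        wl = np.linspace(400, 500, 20)
        dA = np.outer(np.exp(-t), np.sin(wl / 50))
        ta = TAMatrix(times=t, wavelengths=wl, dA=dA, polarization="magic")
        rank, s = svd_rank(ta)
        assert rank == 1
        assert len(s) == 20

    def test_noiseless_three_component(self):
        rank, _ = svd_rank(_three_component_ta())
        assert rank == 3

    def test_three_component_with_one_percent_noise(self):
        ta = _three_component_ta(noise_sd=0.01, seed=1)
        rank, _ = svd_rank(ta)
        assert rank == 3

    def test_custom_strategy(self):
        ta = _three_component_ta()
        rank, s = svd_rank(ta, threshold_strategy=lambda sv: sv[0] / 2)
        assert rank == 1


class TestProjectSads:
    def test_exact_linear_inverse(self, ta_clean, scheme, irf, sads):
        profiles = solve_scheme(scheme, irf, ta_clean.times)
        got = project_sads(ta_clean, profiles)
        np.testing.assert_allclose(got.spectra, sads.spectra, atol=1e-10)

    def test_collinear_profiles_raise_with_names(self):
        t = np.linspace(0, 5, 30)
        c = np.exp(-t)
        profiles = ConcentrationProfiles(
            times=t, labels=("A", "B"), c=np.column_stack([c, 2 * c])
        )
        ta = TAMatrix(
            times=t,
            wavelengths=np.array([500.0]),
            dA=c[:, None],
            polarization="magic",
        )
        with pytest.raises(ValueError, match="'A' and 'B'"):
            project_sads(ta, profiles)

    def test_grid_mismatch_raises(self, ta_clean, scheme, irf):
        profiles = solve_scheme(scheme, irf, ta_clean.times[:-5])
        with pytest.raises(ValueError, match="time grid"):
            project_sads(ta_clean, profiles)

    def test_standard_errors_shrink_with_time_points(self):
        """Monte-Carlo: per-wavelength SE scales ~ 1/sqrt(n_times)."""
        rng = np.random.default_rng(42)
        wl = np.array([500.0])
        s_true = 1.0

        def mean_se(n_times, n_rep=40):
            t = np.linspace(0, 5, n_times)
            c = np.exp(-t)
            prof = ConcentrationProfiles(times=t, labels=("A",), c=c[:, None])
            ses = []
            for _ in range(n_rep):
                dA = c[:, None] * s_true + rng.normal(0, 0.05, (n_times, 1))
                ta = TAMatrix(times=t, wavelengths=wl, dA=dA, polarization="magic")
                ses.append(project_sads(ta, prof).spectra_se[0, 0])
            return np.mean(ses)

        ratio = mean_se(50) / mean_se(200)
        assert ratio == pytest.approx(2.0, rel=0.25)


class TestFitTarget:
    def test_fixed_point_noiseless(self, ta_clean, scheme, irf):
        fit = fit_target(
            ta_clean, scheme, irf, free=("tau:S1", "tau:hotZ", "t0")
        )
        assert fit.rms < 1e-12
        assert fit.params["tau:S1"] == pytest.approx(320e-15, rel=1e-6)
        assert fit.params["tau:hotZ"] == pytest.approx(10e-12, rel=1e-6)

    def test_recovery_from_doubled_lifetimes_noiseless(self, ta_clean, irf):
        init = isomerization_scheme(50e-15, 2 * 320e-15, 0.06, 2 * 10e-12)
        fit = fit_target(ta_clean, init, irf, free=("tau:S1", "tau:hotZ", "t0"))
        assert fit.converged
        assert fit.params["tau:S1"] == pytest.approx(320e-15, rel=1e-4)
        assert fit.params["tau:hotZ"] == pytest.approx(10e-12, rel=1e-4)

    def test_residual_matches_definition(self, ta_noisy, scheme, irf):
        fit = fit_target(ta_noisy, scheme, irf, free=("tau:S1", "tau:hotZ"))
        recomputed = ta_noisy.dA - fit.profiles.c @ fit.sads.spectra.T
        np.testing.assert_allclose(fit.residual, recomputed, atol=1e-14)
        assert all(se >= 0 for se in fit.stderr.values())

    def test_residual_orthogonal_to_profiles(self, ta_noisy, scheme, irf):
        """Normal equations: fitted residual is orthogonal to the fitted
        concentration profiles at every wavelength."""
        fit = fit_target(ta_noisy, scheme, irf, free=("tau:S1", "tau:hotZ"))
        gram = fit.profiles.c.T @ fit.residual
        scale = np.linalg.norm(fit.profiles.c, axis=0)[:, None] * np.abs(
            fit.residual
        ).max()
        np.testing.assert_allclose(gram / scale, 0.0, atol=1e-8)

    def test_init_outside_bounds_raises(self, ta_clean, scheme, irf):
        with pytest.raises(ValueError, match="outside"):
            fit_target(
                ta_clean,
                scheme,
                irf,
                free=("tau:S1",),
                init={"tau:S1": 1e-12},
                bounds={"tau:S1": (1e-14, 5e-13)},
            )

    def test_branch_yield_fixed_point(self, ta_clean, scheme, irf, sads):
        fit = fit_target(
            ta_clean,
            scheme,
            irf,
            free=("tau:S1", "tau:hotZ", "phi:S1->E"),
            fixed_sads={"E": sads.spectrum("E")},
        )
        phi, _ = branch_yield(fit)
        assert phi == pytest.approx(0.06, abs=1e-6)

    def test_branch_yield_zero_branch(self, wavelengths, irf):
        scheme = isomerization_scheme(50e-15, 320e-15, 0.0, 10e-12)
        sads = cascade_sads(wavelengths)
        tgrid = np.concatenate(
            [np.linspace(-0.5, 2, 60), np.geomspace(2.1, 500, 60)]
        )
        cfg = GeneratorConfig(
            seed=5,
            noise_sd=1e-5,
            time_grid=tgrid,
            time_unit="ps",
            wavelength_grid=wavelengths,
        )
        ta = make_ta_dataset(scheme, sads, irf, cfg)
        fit = fit_target(
            ta,
            isomerization_scheme(50e-15, 320e-15, 0.01, 10e-12),
            irf,
            free=("phi:S1->E",),
            fixed_sads={"E": sads.spectrum("E")},
        )
        phi, _ = branch_yield(fit)
        assert phi < 1e-3  # below the noise floor

    def test_branch_yield_recovery_under_noise(self, wavelengths, irf):
        """phi=0.05, 1% noise, 20 seeds: mean estimate within [0.04, 0.06]."""
        scheme = isomerization_scheme(50e-15, 320e-15, 0.05, 10e-12)
        sads = cascade_sads(wavelengths)
        tgrid = np.concatenate(
            [np.linspace(-0.5, 2, 60), np.geomspace(2.1, 500, 60)]
        )
        peak_cfg = GeneratorConfig(
            seed=0, time_grid=tgrid, time_unit="ps", wavelength_grid=wavelengths
        )
        peak = np.abs(make_ta_dataset(scheme, sads, irf, peak_cfg).dA).max()
        phis = []
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed,
                noise_sd=0.01 * peak,
                time_grid=tgrid,
                time_unit="ps",
                wavelength_grid=wavelengths,
            )
            ta = make_ta_dataset(scheme, sads, irf, cfg)
            fit = fit_target(
                ta,
                scheme,
                irf,
                free=("tau:S1", "tau:hotZ", "phi:S1->E"),
                fixed_sads={"E": sads.spectrum("E")},
            )
            phis.append(fit.params["phi:S1->E"])
        assert 0.04 <= np.mean(phis) <= 0.06

    def test_branch_yield_requires_branch_parameter(self, ta_clean, scheme, irf):
        fit = fit_target(ta_clean, scheme, irf, free=("tau:S1",))
        with pytest.raises(ValueError, match="branching"):
            branch_yield(fit)

    def test_too_few_time_points_raise(self, scheme, irf, wavelengths):
        ta = TAMatrix(
            times=np.linspace(0, 1e-12, 5),
            wavelengths=wavelengths,
            dA=np.zeros((5, wavelengths.size)),
            polarization="magic",
        )
        with pytest.raises(ValueError, match="time points"):
            fit_target(ta, scheme, irf, free=("tau:S1", "tau:hotZ"))


class TestVarProEquivalence:
    def test_matches_brute_force_joint_fit(self):
        """Variable projection reaches the same minimum as optimizing the
        nonlinear parameters and all spectra jointly."""
        rng = np.random.default_rng(7)
        t = np.linspace(-0.2, 8, 40)
        wl = np.linspace(450, 550, 5)
        irf = IRFModel(t0=0.0, sigma=0.05)
        scheme = KineticScheme(
            compartments=("A", "B"),
            rates=(1 / 0.8, 1 / 3.0),
            branching={("A", "B"): 1.0},
        )
        S_true = np.column_stack(
            [np.linspace(1, 2, 5), np.linspace(2, 0.5, 5)]
        )
        C = solve_scheme(scheme, irf, t).c
        dA = C @ S_true.T + rng.normal(0, 0.01, (t.size, wl.size))
        ta = TAMatrix(times=t, wavelengths=wl, dA=dA, polarization="magic")

        init = KineticScheme(
            compartments=("A", "B"),
            rates=(1 / 1.2, 1 / 2.2),
            branching={("A", "B"): 1.0},
        )
        fit = fit_target(ta, init, irf, free=("tau:A", "tau:B"))
        varpro_cost = np.sum(fit.residual**2)

        def joint_residuals(p):
            tauA, tauB = np.exp(p[:2])
            S = p[2:].reshape(5, 2)
            sch = KineticScheme(
                compartments=("A", "B"),
                rates=(1 / tauA, 1 / tauB),
                branching={("A", "B"): 1.0},
            )
            Cj = solve_scheme(sch, irf, t).c
            return (dA - Cj @ S.T).ravel()

        # start the joint fit at the varpro solution: if varpro were not a
        # minimum of the full problem, the joint optimizer would descend
        x0 = np.concatenate(
            [
                np.log([fit.params["tau:A"], fit.params["tau:B"]]),
                fit.sads.spectra.ravel(),
            ]
        )
        joint = least_squares(joint_residuals, x0, x_scale="jac")
        assert varpro_cost - 2 * joint.cost <= 1e-8

        # and a joint fit from a perturbed start does not find a lower one
        x1 = np.concatenate(
            [np.log([1.2, 2.2]), np.ones(10)]
        )
        joint2 = least_squares(joint_residuals, x1, x_scale="jac")
        assert 2 * joint2.cost >= varpro_cost - 1e-8


class TestFitDas:
    def test_single_exponential(self):
        t = np.linspace(0, 10, 100)
        wl = np.linspace(400, 500, 10)
        irf = IRFModel(t0=0.0, sigma=0.01)
        s_true = np.linspace(1, 0.2, 10)
        dA = np.outer(exp_gauss(1 / 2.5, irf, t), s_true)
        ta = TAMatrix(times=t, wavelengths=wl, dA=dA, polarization="magic")
        fit = fit_das(ta, 1, init=[1.0], irf=irf)
        assert fit.params["tau:DAS1"] == pytest.approx(2.5, rel=1e-6)
        np.testing.assert_allclose(fit.sads.spectra[:, 0], s_true, atol=1e-8)

    def test_sequential_data_das_lifetimes_are_eigenrates(self):
        """A->B->ground fitted with 2 DAS: lifetimes equal the scheme's
        eigenrates (1/kA, 1/kB)."""
        kA, kB = 1 / 0.7, 1 / 4.0
        irf = IRFModel(t0=0.0, sigma=0.02)
        scheme = KineticScheme(
            compartments=("A", "B"),
            rates=(kA, kB),
            branching={("A", "B"): 1.0},
        )
        t = np.linspace(-0.3, 20, 150)
        wl = np.linspace(450, 550, 8)
        C = solve_scheme(scheme, irf, t).c
        S = np.column_stack([np.linspace(1, 2, 8), np.linspace(1.5, 0.5, 8)])
        ta = TAMatrix(
            times=t, wavelengths=wl, dA=C @ S.T, polarization="magic"
        )
        fit = fit_das(ta, 2, init=[0.5, 5.0], irf=irf)
        taus = sorted([fit.params["tau:DAS1"], fit.params["tau:DAS2"]])
        assert taus[0] == pytest.approx(1 / kA, rel=1e-5)
        assert taus[1] == pytest.approx(1 / kB, rel=1e-5)

    def test_overfitted_das_flagged_ill_conditioned(self):
        t = np.linspace(0, 10, 60)
        wl = np.linspace(400, 500, 6)
        irf = IRFModel(t0=0.0, sigma=0.01)
        dA = np.outer(exp_gauss(1.0, irf, t), np.linspace(1, 0.5, 6))
        ta = TAMatrix(times=t, wavelengths=wl, dA=dA, polarization="magic")
        fit = fit_das(ta, 3, init=[0.9, 1.0, 1.1], irf=irf)
        assert fit.diagnostics["ill_conditioned"]
        assert not fit.converged

    def test_invalid_component_count(self, ta_clean):
        with pytest.raises(ValueError, match="n_components"):
            fit_das(ta_clean, 0)


class TestSimulateFitRoundTrip:
    def test_round_trip_reproduces_matrix_to_noise_level(self, wavelengths, irf):
        ta = cascade_ta(seed=11, noise_frac=0.005)
        init = isomerization_scheme(50e-15, 500e-15, 0.06, 15e-12)
        fit = fit_target(ta, init, irf, free=("tau:S1", "tau:hotZ", "t0"))
        model = fit.profiles.c @ fit.sads.spectra.T
        noise_sd = ta.metadata["truth"]["noise_sd"]
        # fitted surface deviates from the noisy data by ~the noise level
        assert np.sqrt(np.mean((ta.dA - model) ** 2)) < 1.1 * noise_sd
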