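import math

import numpy as np
import pytest
from scipy import stats

from forkspeed import (
    CoverageTrack,
    GenomeGeometry,
    ReplisomeModel,
    abundance_varspeed_D0,
    correlate_profiles,
    fit_constant,
    fit_cosine_profile,
    fit_oscillatory,
    loglik_multinomial,
    select_model,
)
from forkspeed.presets import reference_k, reference_model


class TestMultinomialLoglik:
    def test_matches_exact_log_pmf_differences_on_toy(self):
        """Dropped constants cancel in likelihood differences, so differences
        must agree with the exact multinomial log-pmf on a 5-bin example."""
        counts = np.array([3, 7, 1, 5, 4])
        f1 = np.array([0.1, 0.3, 0.1, 0.3, 0.2])
        f2 = np.array([0.25, 0.25, 0.2, 0.15, 0.15])
        ours = loglik_multinomial(counts, f1) - loglik_multinomial(counts, f2)
        exact = stats.multinomial.logpmf(counts, counts.sum(), f1) - \
            stats.multinomial.logpmf(counts, counts.sum(), f2)
        assert ours == pytest.approx(float(exact), abs=1e-10)

    def test_proportional_fractions_maximize(self, rng):
        counts = rng.integers(10, 500, 12).astype(float)
        best = counts / counts.sum()
        ll_best = loglik_multinomial(counts, best)
        for _ in range(20):
            perturbed = best * rng.lognormal(0, 0.2, 12)
            perturbed /= perturbed.sum()
            assert loglik_multinomial(counts, perturbed) <= ll_best + 1e-9

    def test_uniform_fractions_value(self):
        counts = np.array([10.0, 20.0, 30.0, 40.0])
        n_bins, total = 4, 100.0
        assert loglik_multinomial(counts, np.full(4, 0.25)) == pytest.approx(
            -total * math.log(n_bins)
        )

    def test_zero_fraction_with_observed_reads_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            loglik_multinomial(np.array([1.0, 5.0]), np.array([0.0, 1.0]))

    def test_mask_restricts_and_renormalizes(self):
        counts = np.array([5.0, 5.0, 99.0])
        fractions = np.array([0.25, 0.25, 0.5])
        mask = np.array([True, True, False])
        assert loglik_multinomial(counts, fractions, mask) == pytest.approx(
            -10.0 * math.log(2.0)
        )


def _direct_track(geometry, model, k, n_reads, seed):
    profile = abundance_varspeed_D0(geometry, model, k)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, profile.bin_fractions())
    return CoverageTrack(geometry, counts, phase="corrected")


class TestFitConstant:
    def test_recovers_speed_within_two_percent(self, full_geometry):
        k, vbar = reference_k(37), 970.0
        track = _direct_track(full_geometry, ReplisomeModel(vbar=vbar), k,
                              5_000_000, seed=3)
        fit = fit_constant(track, k)
        assert fit.model.vbar == pytest.approx(vbar, rel=0.02)
        assert fit.n_params == 1

    def test_count_scaling_leaves_argmax_unchanged(self, full_geometry):
        k = reference_k(37)
        track = _direct_track(full_geometry, ReplisomeModel(vbar=800.0), k,
                              500_000, seed=4)
        scaled = CoverageTrack(full_geometry, track.counts * 10, phase="corrected")
        assert fit_constant(track, k).model.vbar == pytest.approx(
            fit_constant(scaled, k).model.vbar, rel=1e-6
        )

    def test_k_and_vbar_enter_only_through_their_ratio(self, full_geometry):
        k = reference_k(37)
        track = _direct_track(full_geometry, ReplisomeModel(vbar=800.0), k,
                              500_000, seed=5)
        assert fit_constant(track, 2 * k).model.vbar == pytest.approx(
            2 * fit_constant(track, k).model.vbar, rel=1e-6
        )


class TestFitOscillatory:
    def test_recovers_reference_parameters(self, full_geometry):
        truth = reference_model(37)
        k = reference_k(37)
        track = _direct_track(full_geometry, truth, k, 5_000_000, seed=6)
        fit = fit_oscillatory(track, k)
        assert fit.model.vbar == pytest.approx(truth.vbar, abs=51)
        assert fit.model.delta == pytest.approx(truth.delta, abs=0.03)
        assert fit.model.omega_per_mbp == pytest.approx(4.3, abs=0.2)
        assert fit.model.phi == pytest.approx(3.0, abs=0.2)
        assert fit.n_params == 4

    def test_phase_wraps_to_principal_interval(self, full_geometry, k_37):
        m1 = ReplisomeModel(vbar=970.0, delta=0.1, omega=4e-6, phi=1.0)
        m2 = ReplisomeModel(vbar=970.0, delta=0.1, omega=4e-6, phi=1.0 + 2 * math.pi)
        assert m1.phi == pytest.approx(m2.phi)
        p1 = abundance_varspeed_D0(full_geometry, m1, k_37).bin_fractions()
        p2 = abundance_varspeed_D0(full_geometry, m2, k_37).bin_fractions()
        assert np.allclose(p1, p2, rtol=1e-12)

    def test_diffusion_profile_on_diffusion_free_truth(self, mini_geometry):
        """Profiling D on D=0 data mostly keeps the diffusion-free model."""
        k = 1e-3
        truth = ReplisomeModel(vbar=400.0, delta=0.25, omega=4e-5, phi=1.0)
        verdicts = []
        for seed in range(3):
            track = _direct_track(mini_geometry, truth, k, 300_000, seed=(9, seed))
            fit = fit_oscillatory(
                track, k, allow_diffusion=True, seed=seed,
                sim_settings={
                    "n_trajectories": 400,
                    "cell_bp": 10_000.0,
                    "horizon": 8_000.0,
                    "burn_in": 6_000.0,
                    "d_grid_kbp2": (0.0, 0.5, 2.0),
                },
            )
            assert "diffusion_profile" in fit.extra
            assert np.isfinite(fit.extra["diffusion_profile"].loglik_sim).all()
            verdicts.append(fit.extra["diffusion_significant"])
            if not fit.extra["diffusion_significant"]:
                assert fit.model.diffusion == 0.0
        assert sum(verdicts) <= 1  # diffusion deemed significant at most rarely

    def test_requires_seed_for_diffusion_path(self, mini_geometry):
        track = _direct_track(
            mini_geometry, ReplisomeModel(vbar=400.0), 1e-3, 10_000, seed=1
        )
        with pytest.raises(ValueError, match="seed"):
            fit_oscillatory(track, 1e-3, allow_diffusion=True)


class TestSelectModel:
    def test_small_gain_prefers_fewer_parameters(self, full_geometry, k_37):
        truth = ReplisomeModel(vbar=900.0)
        track = _direct_track(full_geometry, truth, k_37, 1_000_000, seed=12)
        constant = fit_constant(track, k_37)
        oscillatory = fit_oscillatory(track, k_37)
        if oscillatory.loglik - constant.loglik < 1.0:
            best, table = select_model([constant, oscillatory])
            assert best.model_kind == "constant"
            assert (table.delta_aic >= 0).all()

    def test_strong_oscillation_prefers_richer_model(self, full_geometry):
        truth = reference_model(37)
        k = reference_k(37)
        track = _direct_track(full_geometry, truth, k, 5_000_000, seed=13)
        best, table = select_model(
            [fit_constant(track, k), fit_oscillatory(track, k)]
        )
        assert best.model_kind == "oscillatory"
        assert table.loc[table.model_kind == "constant", "delta_aic"].iloc[0] > 100

    def test_mask_mismatch_rejected(self, full_geometry, k_37):
        track = _direct_track(full_geometry, ReplisomeModel(vbar=900.0), k_37,
                              100_000, seed=14)
        fit1 = fit_constant(track, k_37)
        other_mask = track.mask.copy()
        other_mask[0] = False
        other = CoverageTrack(full_geometry, track.counts, phase="corrected",
                              mask=other_mask)
        fit2 = fit_constant(other, k_37)
        with pytest.raises(ValueError, match="mask"):
            select_model([fit1, fit2])


class TestCosineProfile:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0.0, 4.0e6, 300)
        truth = (2.4, 0.18, 4.9e-6, 1.93)
        m, d, om, ph = truth
        values = m * (1 + d * np.cos(om * x + ph))
        fit = fit_cosine_profile(x, values)
        assert fit.mean == pytest.approx(m, rel=1e-6)
        assert fit.delta == pytest.approx(d, rel=1e-5)
        assert fit.omega == pytest.approx(om, rel=1e-5)
        assert fit.phi == pytest.approx(ph, rel=1e-4)
        assert fit.omega_defined

    def test_noisy_recovery_within_tolerance(self, rng):
        x = np.linspace(0.0, 4.0e6, 400)
        values = 2.4 * (1 + 0.18 * np.cos(4.9e-6 * x + 1.93))
        noisy = values * (1 + rng.normal(0, 0.05, x.size))
        fit = fit_cosine_profile(x, noisy)
        assert fit.mean == pytest.approx(2.4, rel=0.05)
        assert fit.delta == pytest.approx(0.18, abs=0.05)
        assert fit.omega == pytest.approx(4.9e-6, rel=0.05)
        assert fit.phi == pytest.approx(1.93, abs=0.3)

    def test_constant_profile_flagged(self):
        fit = fit_cosine_profile(np.arange(10.0), np.full(10, 3.5))
        assert fit.delta == 0.0
        assert not fit.omega_defined
        assert math.isnan(fit.omega)


class TestCorrelateProfiles:
    def test_identical_profiles(self, rng):
        a = rng.normal(size=50)
        assert correlate_profiles(a, a) == pytest.approx(1.0)
        assert correlate_profiles(a, -a) == pytest.approx(-1.0)

    def test_quarter_phase_cosines_uncorrelated(self):
        x = np.linspace(0, 20 * math.pi, 5000)
        assert correlate_profiles(np.cos(x), np.cos(x + math.pi / 2)) == \
            pytest.approx(0.0, abs=0.01)

    def test_nans_dropped_jointly(self):
        a = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        assert correlate_profiles(a, b) == pytest.approx(1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_profiles(np.ones(5), np.arange(5.0))
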