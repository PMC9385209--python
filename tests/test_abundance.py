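import math

import numpy as np
import pytest

from forkspeed import (
    GenomeGeometry,
    ReplisomeModel,
    abundance_constant_speed,
    abundance_varspeed_D0,
    bin_model_abundance,
    normalize_abundance,
    probability_contains,
    pst_constant_speed,
    read_profile,
    simulate_stationary,
    write_profile,
)

K, VBAR = 4.6e-4, 970.0


def test_contains_probability_is_one_at_origin(full_geometry):
    dist = pst_constant_speed(K, VBAR, full_geometry.length_bp)
    profile = probability_contains(dist, dist.beta, K, full_geometry)
    assert profile.p_origin == pytest.approx(1.0, abs=1e-12)


def test_complete_population_has_flat_profile(full_geometry):
    """k -> 0: essentially every genome is complete, so P(y) = 1 everywhere."""
    k = 1e-9
    dist = pst_constant_speed(k, VBAR, full_geometry.length_bp)
    profile = probability_contains(dist, dist.beta, k, full_geometry)
    assert np.all(profile.p_arm > 1.0 - 1e-4)


def test_constant_speed_round_trip_to_1e8(full_geometry):
    """Fork density -> P(y) -> A(y) reproduces the closed form on all bins."""
    dist = pst_constant_speed(K, VBAR, full_geometry.length_bp)
    via_pst = normalize_abundance(
        probability_contains(dist, dist.beta, K, full_geometry), full_geometry
    )
    direct = abundance_constant_speed(full_geometry, K, VBAR)
    assert np.allclose(
        via_pst.bin_fractions(), direct.bin_fractions(), rtol=1e-8, atol=0
    )
    # and P itself matches e^{-k|y|/vbar}
    assert np.allclose(
        via_pst.p_arm, np.exp(-K * via_pst.x_arm / VBAR), rtol=1e-8
    )


def test_terminus_abundance_is_complete_genome_fraction(full_geometry):
    """A(L/2)/A(0) equals beta/(k+beta) for the constant-speed model."""
    dist = pst_constant_speed(K, VBAR, full_geometry.length_bp)
    profile = probability_contains(dist, dist.beta, K, full_geometry)
    assert profile.p_terminus / profile.p_origin == pytest.approx(
        dist.beta / (K + dist.beta), rel=1e-9
    )


def test_uniform_contains_gives_uniform_bin_masses(mini_geometry):
    profile = normalize_abundance(np.ones(mini_geometry.n_bins), mini_geometry)
    assert profile.bin_fractions() == pytest.approx(
        np.full(mini_geometry.n_bins, 1.0 / mini_geometry.n_bins)
    )


def test_bin_fractions_sum_to_one(full_geometry, model_37, k_37):
    profile = abundance_varspeed_D0(full_geometry, model_37, k_37)
    assert bin_model_abundance(profile).sum() == pytest.approx(1.0, abs=1e-12)


def test_constant_model_bin_masses_match_exponential_integrals():
    """Per-bin masses agree with the analytic integral of the exponential."""
    g = GenomeGeometry(length_bp=400_000.0, origin_bp=0.0, bin_bp=50_000.0)
    k, vbar = 1e-3, 500.0
    profile = abundance_constant_speed(g, k, vbar)
    a = k / vbar
    edges = g.bin_edges()
    expected = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # integrate e^{-a |y(s)|} over the bin; origin at 0 makes |y| piecewise
        s = np.linspace(lo, hi, 20001)
        d = np.abs(np.mod(s - g.origin_bp + g.length_bp / 2, g.length_bp)
                   - g.length_bp / 2)
        expected.append(np.trapezoid(np.exp(-a * d), s))
    expected = np.asarray(expected)
    expected /= expected.sum()
    assert profile.bin_fractions() == pytest.approx(expected, rel=1e-6)


def test_refining_bins_and_reaggregating_is_exact(full_geometry, model_37, k_37):
    profile = abundance_varspeed_D0(full_geometry, model_37, k_37)
    coarse = profile.bin_fractions()
    fine_geometry = GenomeGeometry(
        full_geometry.length_bp, full_geometry.origin_bp, full_geometry.bin_bp / 10
    )
    fine = profile.bin_fractions(fine_geometry)
    idx = np.searchsorted(fine_geometry.bin_edges(), full_geometry.bin_edges())
    reaggregated = np.add.reduceat(fine, idx[:-1])
    assert np.allclose(reaggregated, coarse, rtol=1e-12, atol=1e-15)


def test_contains_monotone_for_simulated_distributions(mini_geometry):
    """P(y) decreases away from the origin for any stationary fork density."""
    model = ReplisomeModel(vbar=400.0, delta=0.3, omega=5e-5, phi=2.0, diffusion=5e3)
    k = 1e-3
    dist = simulate_stationary(
        model, k, mini_geometry, seed=5, n_trajectories=2000,
        burn_in=6.0 / k, horizon=20_000.0, cell_bp=10_000.0,
    )
    profile = probability_contains(dist, dist.beta, k, mini_geometry)
    assert np.all(np.diff(profile.p_arm) <= 1e-12)
    assert profile.p_origin == pytest.approx(1.0, abs=1e-12)


def test_simulated_abundance_matches_analytic_on_every_bin(mini_geometry):
    """Simulator route reproduces the exact D=0 profile on every bin.

    With D = 0 the trajectories are deterministic between resets, so the
    replicate-to-replicate scatter collapses far below the time-step and
    histogram-cell discretization residual; the meaningful statement is
    per-bin agreement at the scheme's accuracy (a few parts in 10^3).
    """
    model = ReplisomeModel(vbar=400.0, delta=0.25, omega=4e-5, phi=1.0)
    k = 1e-3
    runs = []
    for seed in range(4):
        dist = simulate_stationary(
            model, k, mini_geometry, seed=(77, seed), n_trajectories=3000,
            burn_in=6.0 / k, horizon=15_000.0, cell_bp=10_000.0,
        )
        prof = probability_contains(dist, dist.beta, k, mini_geometry)
        runs.append(prof.bin_fractions())
    mean = np.asarray(runs).mean(axis=0)
    truth = abundance_varspeed_D0(mini_geometry, model, k).bin_fractions()
    assert np.abs(mean / truth - 1.0).max() < 0.005


def test_profile_round_trips_through_tsv(tmp_path, mini_geometry):
    profile = abundance_constant_speed(mini_geometry, 1e-3, 400.0)
    path = tmp_path / "profile.tsv"
    write_profile(profile, path)
    loaded = read_profile(path)
    assert loaded.geometry == mini_geometry
    assert np.allclose(
        loaded.p_contains_bins(), profile.p_contains_bins(), rtol=1e-6
    )


def test_nonpositive_contains_rejected(mini_geometry):
    bad = np.ones(mini_geometry.n_bins)
    bad[3] = 0.0
    with pytest.raises(ValueError):
        normalize_abundance(bad, mini_geometry)
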