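"""Tests for the Metropolis sampler: distributions, seeds, protocol."""

import numpy as np
import pytest
from scipy import integrate, stats

from cryoevb.errors import ConfigError, SamplerFailureError
from cryoevb.evb import MappingWindow, make_windows
from cryoevb.sampling import (
    equilibrate,
    run_replicate,
    run_temperature_series,
    sample_window,
)
from cryoevb.surrogate import stationary_points
from cryoevb.thermo import R_KCAL


def test_single_well_variance_matches_equipartition(spe_bare):
    """At lam=0 the mapping potential is harmonic: var(x) = RT/k."""
    T = 295.15
    traj = sample_window(
        spe_bare, MappingWindow(0, 0.0), T, 100_000, seed=11, start=spe_bare.x1, stride=10
    )
    x = traj.x
    expected = R_KCAL * T / spe_bare.k1
    n_eff = x.size  # stride-10 thinning leaves near-independent samples
    se = expected * np.sqrt(2.0 / (n_eff - 1))
    assert abs(x.var() - expected) < 3 * se


def test_reactant_window_samples_negative_gap(spe_system):
    traj = sample_window(
        spe_system, MappingWindow(0, 0.0), 295.15, 5000, seed=4, start=spe_system.x1
    )
    assert traj.gap.mean() < 0


def test_same_seed_reproduces_trajectory_bitwise(spe_system):
    kwargs = dict(start=spe_system.x1, stride=2, record_bath=True)
    a = sample_window(spe_system, MappingWindow(3, 0.06), 290.0, 3000, seed=9, **kwargs)
    b = sample_window(spe_system, MappingWindow(3, 0.06), 290.0, 3000, seed=9, **kwargs)
    c = sample_window(spe_system, MappingWindow(3, 0.06), 290.0, 3000, seed=10, **kwargs)
    assert np.array_equal(a.x, b.x)
    assert np.array_equal(a.bath_coords, b.bath_coords)
    assert not np.array_equal(a.x, c.x)


def test_frame_energies_respect_ground_state_bound(spe_system):
    traj = sample_window(
        spe_system,
        MappingWindow(25, 0.5),
        295.15,
        4000,
        seed=21,
        start=0.0,
        record_bath=True,
    )
    frames = traj.frames
    assert (frames["ground"] <= np.minimum(frames["eps1"], frames["eps2_shifted"]) + 1e-9).all()
    assert traj.bath_coords.shape == (traj.n_frames, len(spe_system.bath))
    assert np.allclose(frames["gap"], frames["eps1"] - frames["eps2_shifted"], atol=1e-8)


def test_stationary_distribution_matches_boltzmann(spe_bare):
    """Chi-square goodness of fit on a discretized harmonic window."""
    T = 295.15
    traj = sample_window(
        spe_bare, MappingWindow(0, 0.0), T, 100_000, seed=17, start=spe_bare.x1, stride=10
    )
    x = traj.x
    rt = R_KCAL * T
    sigma = np.sqrt(rt / spe_bare.k1)
    edges = spe_bare.x1 + sigma * np.linspace(-3, 3, 13)
    counts, _ = np.histogram(x, bins=edges)

    def density(u):
        return np.exp(-0.5 * spe_bare.k1 * (u - spe_bare.x1) ** 2 / rt)

    norm = integrate.quad(density, -np.inf, np.inf)[0]
    probs = np.array(
        [integrate.quad(density, a, b)[0] / norm for a, b in zip(edges, edges[1:])]
    )
    inside = counts.sum()
    chi2, p = stats.chisquare(counts, probs / probs.sum() * inside)
    assert p > 0.01


def test_window_mean_energy_nondecreasing_in_temperature(spe_bare):
    """Harmonic window: <V> = V0 + RT/2, exactly increasing in T."""
    means = []
    for T in (285.0, 295.0, 305.0):
        traj = sample_window(
            spe_bare, MappingWindow(0, 0.0), T, 40_000, seed=23, start=spe_bare.x1
        )
        means.append(traj.mapping.mean())
    assert means[0] < means[1] < means[2]


def test_zero_acceptance_raises_sampler_failure(spe_bare):
    """A pathologically large frozen step lands every proposal on the wall."""
    with pytest.raises(SamplerFailureError):
        sample_window(
            spe_bare,
            MappingWindow(0, 0.0),
            295.15,
            50,
            seed=1,
            start=spe_bare.x1,
            burn_in=0.0,
            initial_step=1e6,
        )


def test_equilibrate_reaches_product_basin(spe_system):
    x_final = equilibrate(spe_system, 295.0, seed=6)
    x_r, x_ts, x_p = stationary_points(spe_system, 295.0)
    assert x_ts < x_final < x_p + 0.5
    assert equilibrate(spe_system, 295.0, seed=6) == x_final  # deterministic


def test_equilibrate_zero_steps_returns_start(spe_system):
    assert equilibrate(spe_system, 295.0, seed=1, steps_per_stage=0) == spe_system.x2


def test_equilibrate_rejects_bad_ladders(spe_system):
    with pytest.raises(ConfigError):
        equilibrate(spe_system, 295.0, schedule=[1.0, 200.0, 100.0, 295.0], seed=0)
    with pytest.raises(ConfigError):
        equilibrate(spe_system, 295.0, schedule=[50.0, 295.0], seed=0)


def test_replicate_has_one_trajectory_per_window(spe_bare):
    windows = make_windows(51)
    rep = run_replicate(spe_bare, 295.15, windows, 200, replicate_seed=3)
    assert len(rep.windows) == 51
    lams = [w.window.lam for w in rep.windows]
    assert lams == sorted(lams)


def test_replicates_share_shape_but_not_frames(spe_bare):
    windows = make_windows(11)
    a = run_replicate(spe_bare, 295.15, windows, 500, replicate_seed=3, replicate_id=0)
    b = run_replicate(spe_bare, 295.15, windows, 500, replicate_seed=3, replicate_id=1)
    assert len(a.windows) == len(b.windows)
    assert not np.array_equal(a.windows[5].x, b.windows[5].x)


def test_batched_series_matches_serial_replicates(spe_bare):
    """Lockstep chains consume per-replicate streams: batch == serial."""
    series = run_temperature_series(
        spe_bare,
        temperatures=[295.15],
        n_replicates=2,
        master_seed=13,
        n_windows=5,
        n_steps_per_window=400,
    )
    solo = run_replicate(
        spe_bare,
        295.15,
        make_windows(5),
        400,
        replicate_seed=13,
        replicate_id=1,
        temp_index=0,
    )
    batched = series[295.15][1]
    for wa, wb in zip(batched.windows, solo.windows):
        assert np.array_equal(wa.x, wb.x)


def test_series_seed_table_is_reproducible_and_validated(spe_bare):
    kwargs = dict(
        temperatures=[290.0, 300.0],
        n_replicates=2,
        n_windows=4,
        n_steps_per_window=200,
    )
    a = run_temperature_series(spe_bare, master_seed=5, **kwargs)
    b = run_temperature_series(spe_bare, master_seed=5, **kwargs)
    for t in a:
        for ra, rb in zip(a[t], b[t]):
            assert all(
                np.array_equal(wa.x, wb.x) for wa, wb in zip(ra.windows, rb.windows)
            )
    with pytest.raises(ConfigError):
        run_temperature_series(spe_bare, temperatures=[290.0, 290.0], n_replicates=1)


def test_single_temperature_single_replicate(spe_bare):
    series = run_temperature_series(
        spe_bare,
        temperatures=[295.0],
        n_replicates=1,
        master_seed=2,
        n_windows=3,
        n_steps_per_window=100,
    )
    assert len(series) == 1 and len(series[295.0]) == 1


def test_frame_table_round_trip(tmp_path, spe_bare):
    from cryoevb.free_energy import umbrella_profile
    from cryoevb.sampling import load_replicate_frames, write_replicate_frames

    rep = run_replicate(spe_bare, 295.15, make_windows(21), 3000, replicate_seed=31)
    write_replicate_frames(rep, tmp_path / "rep0")
    loaded = load_replicate_frames(tmp_path / "rep0")
    assert loaded.temperature == rep.temperature
    assert np.allclose(loaded.windows[7].gap, rep.windows[7].gap)
    p1 = umbrella_profile(rep, 40, support_threshold=5)
    p2 = umbrella_profile(loaded, 40, support_threshold=5)
    assert p1.dg_activation == pytest.approx(p2.dg_activation, abs=1e-6)
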