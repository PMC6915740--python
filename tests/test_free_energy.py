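"""Tests for the FEP/umbrella free-energy estimators."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate

from cryoevb.errors import AggregationError, BarrierUnresolvedError, NoBarrierError
from cryoevb.evb import MappingWindow, make_windows
from cryoevb.free_energy import (
    FreeEnergyProfile,
    aggregate_replicates,
    extract_barrier,
    fep_free_energies,
    profile_deviation,
    read_profile,
    umbrella_profile,
    write_profile,
    zwanzig_increment,
)
from cryoevb.sampling import TableReplicate, TableWindow, run_replicate
from cryoevb.surrogate import analytic_profile
from cryoevb.thermo import R_KCAL


def _window(gap, lam=0.0, index=0, T=295.15, mapping=None, ground=None):
    gap = np.asarray(gap, dtype=float)
    mapping = np.zeros_like(gap) if mapping is None else np.asarray(mapping, float)
    ground = mapping if ground is None else np.asarray(ground, float)
    return TableWindow(
        window=MappingWindow(index=index, lam=lam),
        temperature=T,
        gap=gap,
        mapping=mapping,
        ground=ground,
        eps1=np.zeros_like(gap),
        eps2_shifted=np.zeros_like(gap),
    )


def test_zwanzig_zero_perturbation_is_zero():
    w = _window(np.random.default_rng(0).normal(size=100), lam=0.3)
    assert zwanzig_increment(w, 0.3) == 0.0


def test_zwanzig_constant_perturbation_returns_constant():
    # du = -dlam * X; gap frames chosen so du = 1.7 exactly
    dlam = 0.25
    w = _window(np.full(50, -1.7 / dlam), lam=0.5)
    assert zwanzig_increment(w, 0.75) == pytest.approx(1.7, abs=1e-12)


def test_zwanzig_gaussian_closed_form_and_quadrature():
    """X ~ N(0, s): dG -> -(dlam*s)^2 / 2RT, also checked by quadrature."""
    rng = np.random.default_rng(42)
    sigma, dlam, T = 19.0, 0.02, 295.15  # one-window-sized perturbation
    rt = R_KCAL * T
    w = _window(rng.normal(0.0, sigma, 200_000), lam=0.0)
    expected = -((dlam * sigma) ** 2) / (2.0 * rt)
    got = zwanzig_increment(w, dlam)
    assert got == pytest.approx(expected, abs=0.005)
    # independent numerical quadrature of the exponential average
    f = lambda x: np.exp(-(x**2) / (2 * sigma**2) + dlam * x / rt)
    z = integrate.quad(f, -np.inf, np.inf)[0] / np.sqrt(2 * np.pi * sigma**2)
    assert -rt * np.log(z) == pytest.approx(expected, abs=1e-9)


def test_zwanzig_rejects_empty_trajectory():
    with pytest.raises(ValueError):
        zwanzig_increment(_window([]), 0.5)


def test_fep_identical_windows_accumulate_zero():
    rep = TableReplicate(
        "null", 295.15, 0, [_window(np.zeros(20), lam=0.0), _window(np.zeros(20), lam=1.0, index=1)]
    )
    assert np.allclose(fep_free_energies(rep), 0.0)


def test_fep_endpoint_matches_analytic_well_difference(converged_rep, spe_bare):
    """dG(1) - dG(0) equals the product-well offset for equal-k harmonic wells."""
    fep = fep_free_energies(converged_rep)
    e2p = spe_bare.e2_raw + spe_bare.evb.gas_shift_alpha
    assert fep[-1] - fep[0] == pytest.approx(e2p - spe_bare.e1, abs=0.15)


def test_fep_forward_and_bidirectional_agree_when_converged(converged_rep):
    f = fep_free_energies(converged_rep, bidirectional=False)
    b = fep_free_energies(converged_rep, bidirectional=True)
    assert np.max(np.abs(f - b)) < 0.1


def test_umbrella_uniform_weight_profile_is_flat():
    """Equal counts and unit reweighting factors give a flat profile."""
    edges = np.linspace(0.0, 10.0, 11)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gap = np.repeat(centers, 50)
    rep = TableReplicate("flat", 295.15, 0, [_window(gap, lam=0.0)])
    prof = umbrella_profile(rep, support_threshold=10, bin_edges=edges)
    sup = prof.delta_g[prof.supported]
    assert np.allclose(sup - sup.min(), 0.0, atol=1e-9)


def test_umbrella_profile_matches_analytic_oracle(converged_rep, spe_bare):
    prof = umbrella_profile(converged_rep)
    ana = analytic_profile(spe_bare, 295.15)
    assert profile_deviation(prof, ana) < 0.15
    assert prof.dg_activation == pytest.approx(ana.dg_activation, abs=0.1)


def test_umbrella_barrier_robust_to_bin_doubling(converged_rep):
    a = umbrella_profile(converged_rep, n_bins=100)
    b = umbrella_profile(converged_rep, n_bins=200)
    assert abs(a.dg_activation - b.dg_activation) < 0.05


def test_umbrella_undersampled_barrier_raises_with_lambda_hint(spe_bare):
    rep = run_replicate(spe_bare, 295.15, make_windows(11), 400, replicate_seed=8)
    with pytest.raises(BarrierUnresolvedError) as err:
        umbrella_profile(rep, n_bins=100, support_threshold=50)
    assert err.value.lam_range is not None


def test_gauge_invariance_of_normalized_profile(spe_bare):
    """Shifting both diabats by a constant leaves profile and barrier exact."""
    shifted_sys = dataclasses.replace(
        spe_bare, e1=spe_bare.e1 + 37.0, e2_raw=spe_bare.e2_raw + 37.0
    )
    rep_a = run_replicate(spe_bare, 295.15, make_windows(21), 3000, replicate_seed=55)
    rep_b = run_replicate(shifted_sys, 295.15, make_windows(21), 3000, replicate_seed=55)
    pa = umbrella_profile(rep_a, 40, support_threshold=5)
    pb = umbrella_profile(rep_b, 40, support_threshold=5)
    assert pa.dg_activation == pytest.approx(pb.dg_activation, abs=1e-9)
    assert np.allclose(
        pa.delta_g[pa.supported], pb.delta_g[pb.supported], atol=1e-9
    )


@pytest.mark.parametrize(
    "bins, expected",
    [
        ([0.0, 2.0, 5.0, 3.0, 1.0], (5.0, 1.0)),
        ([0.0, 3.0, 6.0, 3.0, 0.0], (6.0, 0.0)),  # symmetric double well
    ],
)
def test_extract_barrier_direct_readoff(bins, expected):
    prof = FreeEnergyProfile(
        bin_centers=np.arange(len(bins), dtype=float),
        delta_g=np.array(bins),
        counts=np.ones(len(bins), dtype=int),
        temperature=295.15,
    )
    assert extract_barrier(prof) == pytest.approx(expected)


def test_extract_barrier_rejects_monotone_profile():
    prof = FreeEnergyProfile(
        bin_centers=np.arange(5.0),
        delta_g=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        counts=None,
        temperature=295.15,
    )
    with pytest.raises(NoBarrierError):
        extract_barrier(prof)


def _fake_profile(dg, T=295.15):
    return FreeEnergyProfile(
        bin_centers=np.arange(3.0),
        delta_g=np.array([0.0, dg, 1.0]),
        counts=None,
        temperature=T,
        dg_activation=dg,
        dg_reaction=1.0,
    )


def test_aggregate_replicates_statistics():
    stats = aggregate_replicates([_fake_profile(10.0), _fake_profile(12.0)])
    assert stats.mean == pytest.approx(11.0)
    assert stats.sem == pytest.approx(1.0)
    same = aggregate_replicates([_fake_profile(7.0)] * 4)
    assert same.sem == 0.0


def test_aggregate_recovers_known_barrier_distribution():
    rng = np.random.default_rng(314)
    stats = aggregate_replicates([_fake_profile(v) for v in rng.normal(18.0, 0.5, 50)])
    assert stats.mean == pytest.approx(18.0, abs=0.2)


def test_aggregate_rejects_mixed_temperatures():
    with pytest.raises(AggregationError):
        aggregate_replicates([_fake_profile(10.0, T=285.0), _fake_profile(10.0, T=295.0)])
    with pytest.raises(AggregationError):
        aggregate_replicates([])


def test_profile_text_round_trip(tmp_path, converged_rep):
    prof = umbrella_profile(converged_rep)
    path = tmp_path / "profile.tsv"
    write_profile(prof, path)
    loaded = read_profile(path)
    assert loaded.temperature == prof.temperature
    assert loaded.dg_activation == pytest.approx(prof.dg_activation, abs=1e-5)
    sup = prof.supported
    assert np.allclose(loaded.delta_g[sup], prof.delta_g[sup], atol=1e-5)
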