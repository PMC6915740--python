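"""Tests for the Arrhenius decomposition, TST rates and comparisons."""

import math

import numpy as np
import pytest

from cryoevb.errors import ConvergenceError
from cryoevb.reference import ACTIVATION_PARAMS, printed_rate_ratio
from cryoevb.thermo import (
    ActivationParameters,
    DEFAULT_TEMPERATURES,
    KB_OVER_H,
    R_KCAL,
    T_REF,
    arrhenius_fit,
    bootstrap_ci,
    compare_variants,
    converge_activation,
    delta_g_at,
    rate_table,
    tst_rate,
)


def _line(dh, tds_ref, temps=DEFAULT_TEMPERATURES, t_ref=T_REF):
    ds = -(-tds_ref) / t_ref
    return [(t, dh - t * ds) for t in temps]


def test_arrhenius_recovers_exact_linear_input():
    params = arrhenius_fit(_line(4.6, -13.4))
    assert params.dh == pytest.approx(4.6, abs=1e-9)
    assert params.tds_ref == pytest.approx(-13.4, abs=1e-9)
    assert params.r_squared == pytest.approx(1.0, abs=1e-12)
    # identity holds to machine precision by construction
    assert params.dg_ref == params.dh - params.t_ref * params.ds


def test_arrhenius_zero_entropy_gives_pure_slope():
    params = arrhenius_fit([(t, 7.0) for t in DEFAULT_TEMPERATURES])
    assert params.dh == pytest.approx(7.0, abs=1e-9)
    assert params.ds == pytest.approx(0.0, abs=1e-12)


def test_arrhenius_noisy_recovery_is_unbiased():
    """Gaussian noise sigma=0.05 over 1000 seeds: mean dH within 0.05."""
    rng = np.random.default_rng(2024)
    clean = _line(4.6, -13.4)
    estimates = []
    for _ in range(1000):
        noisy = [(t, dg + rng.normal(0.0, 0.05)) for t, dg in clean]
        estimates.append(arrhenius_fit(noisy).dh)
    assert np.mean(estimates) == pytest.approx(4.6, abs=0.05)


def test_arrhenius_input_validation():
    with pytest.raises(ValueError):
        arrhenius_fit([(285.0, 17.5), (290.0, 17.8)])
    with pytest.raises(ValueError):
        arrhenius_fit([(285.0, 17.5), (285.0, 17.6), (295.0, 18.0)])


@pytest.mark.parametrize(
    "dh, tds, expected",
    [(4.6, -13.4, 18.0), (17.2, -2.0, 19.2), (11.3, -6.7, 18.0)],
)
def test_delta_g_identity_from_printed_components(dh, tds, expected):
    p = ActivationParameters(label="x", t_ref=T_REF, dh=dh, ds=tds / T_REF)
    assert delta_g_at(p, T_REF) == pytest.approx(expected, abs=1e-9)


def test_delta_g_constant_when_entropy_vanishes():
    p = ActivationParameters(label="x", t_ref=T_REF, dh=9.9, ds=0.0)
    for t in (250.0, 295.15, 350.0):
        assert delta_g_at(p, t) == 9.9


def test_tst_prefactor_and_inversion():
    assert tst_rate(0.0, T_REF) == pytest.approx(6.150e12, rel=1e-3)
    dg = R_KCAL * T_REF * math.log(KB_OVER_H * T_REF)
    assert tst_rate(dg, T_REF) == pytest.approx(1.0, rel=1e-12)


def test_tst_is_decreasing_in_barrier():
    assert tst_rate(18.0, T_REF) > tst_rate(18.5, T_REF)


def test_rate_table_matches_printed_wildtype_entry():
    p = ActivationParameters(label="SPE_like", t_ref=T_REF, dh=4.6, ds=-13.4 / T_REF)
    table = rate_table([p])
    k22 = table[(table.temp_c == 22.0)].k_x100.iloc[0]
    assert k22 == pytest.approx(28.9, abs=0.05)


def test_rate_table_empty_and_monotone():
    assert rate_table([]).empty
    for name, (dg, dh, tds) in ACTIVATION_PARAMS.items():
        p = ActivationParameters(label=name, t_ref=T_REF, dh=dh, ds=tds / T_REF)
        t = rate_table([p]).set_index("temp_c")
        if dh > 0:
            assert t.loc[4.0, "k_per_s"] < t.loc[39.0, "k_per_s"]


def test_compare_variants_wildtype_gap():
    spe = ActivationParameters("SPE_like", T_REF, 4.6, -13.4 / T_REF)
    ppe = ActivationParameters("PPE_like", T_REF, 17.2, -2.0 / T_REF)
    c = compare_variants(spe, ppe)
    assert c.ddg_ref == pytest.approx(1.2, abs=1e-9)
    assert c.ddh == pytest.approx(12.6, abs=1e-9)
    # compensation bookkeeping is exact: ddG(T) = ddH - T*ddS at any T
    for t in (250.0, 295.15, 320.0):
        dds = (ppe.ds - spe.ds)
        assert delta_g_at(ppe, t) - delta_g_at(spe, t) == pytest.approx(
            c.ddh - t * dds, abs=1e-9
        )


def test_compare_identical_variants_is_neutral():
    p = ActivationParameters("x", T_REF, 10.0, -0.01)
    c = compare_variants(p, p)
    assert c.ddg_ref == 0.0 and c.ddh == 0.0 and c.d_tds_ref == 0.0
    assert np.allclose(c.per_temperature.rate_ratio, 1.0)


def test_compare_rejects_mismatched_reference_temperatures():
    a = ActivationParameters("a", 295.15, 10.0, 0.0)
    b = ActivationParameters("b", 298.15, 10.0, 0.0)
    with pytest.raises(ValueError):
        compare_variants(a, b)


def test_printed_rate_ratios_reproduce_reported_activity_shifts():
    assert printed_rate_ratio("SPE_R63L_W65F_V88I", "SPE_like", 4.0) == pytest.approx(
        0.71, abs=0.005
    )
    assert printed_rate_ratio("PPE_Y93G_A99G", "PPE_like", 4.0) == pytest.approx(2.5)


# --- convergence loop ---


def test_convergence_stops_immediately_on_noiseless_runner():
    truth = dict(_line(4.6, -13.4))
    params = converge_activation(lambda t: truth[t], start=50, batch=10, cap=200)
    assert params.n_replicates == 50
    assert params.r_squared == pytest.approx(1.0)


def test_convergence_grows_in_batches_until_threshold():
    """Stops at the first batch whose fit exceeds the R² bound."""
    rng = np.random.default_rng(99)
    truth = dict(_line(4.6, -13.4))

    def runner(t):
        return truth[t] + rng.normal(0.0, 0.6)

    params = converge_activation(runner, start=50, batch=10, cap=200)
    assert params.r_squared > 0.8
    assert params.n_replicates >= 50
    assert (params.n_replicates - 50) % 10 == 0


def test_convergence_cap_raises_with_r2_trajectory():
    rng = np.random.default_rng(7)

    def hopeless(t):
        return 18.0 + rng.normal(0.0, 50.0)

    with pytest.raises(ConvergenceError) as err:
        converge_activation(hopeless, start=10, batch=10, cap=30)
    assert len(err.value.r2_history) == 3
    assert all(r <= 0.8 for r in err.value.r2_history)


# --- bootstrap ---


def test_bootstrap_zero_variance_gives_zero_width():
    truth = dict(_line(4.6, -13.4))
    per_temp = {t: [dg] * 5 for t, dg in truth.items()}
    ci = bootstrap_ci(per_temp, n_boot=200, seed=1)
    assert ci["dh_half_width"] == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_is_deterministic_given_seed():
    rng = np.random.default_rng(5)
    per_temp = {t: list(dg + rng.normal(0, 0.3, 20)) for t, dg in _line(4.6, -13.4)}
    a = bootstrap_ci(per_temp, n_boot=300, seed=42)
    b = bootstrap_ci(per_temp, n_boot=300, seed=42)
    assert a == b


def test_bootstrap_width_tracks_analytic_ols_slope_error():
    """Known sigma=0.5, n=50/temperature: half-width near the OLS slope SE."""
    rng = np.random.default_rng(11)
    sigma, n = 0.5, 50
    clean = _line(4.6, -13.4)
    per_temp = {t: list(dg + rng.normal(0, sigma, n)) for t, dg in clean}
    ci = bootstrap_ci(per_temp, n_boot=2000, seed=3)
    temps = np.array([t for t, _ in clean])
    x = 1.0 / temps
    var_y = (sigma / temps) ** 2 / n  # variance of each mean dG/T point
    c = (x - x.mean()) / ((x - x.mean()) ** 2).sum()
    se_slope = math.sqrt(float((c**2 * var_y).sum()))
    expected_half_width = 1.96 * se_slope
    assert ci["dh_half_width"] == pytest.approx(expected_half_width, rel=0.3)
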