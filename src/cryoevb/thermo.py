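"""Arrhenius decomposition of activation free energies and TST rates.

The activation free energy obeys dG‡(T) = dH‡ - T*dS‡ with dH‡ and dS‡
treated as temperature-independent.  Plotting dG‡/T against 1/T therefore
gives a straight line with slope dH‡ and intercept -dS‡; an ordinary
least-squares fit of barriers sampled at several temperatures yields the
enthalpy-entropy decomposition.  Rates follow from Eyring transition-state
theory with unit transmission coefficient,

    k(T) = (kB*T/h) * exp(-dG‡(T) / (R*T)).

Psychrophilic (cold-adapted) enzymes show low dH‡ and strongly negative
T*dS‡; mesophilic orthologs show the opposite partitioning at nearly the
same dG‡.  Rate tables are printed both in s^-1 and in units of 100 s^-1
(the printed value is k in s^-1 multiplied by 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError

__all__ = [
    "R_KCAL",
    "KB_OVER_H",
    "T_REF",
    "DEFAULT_TEMPERATURES",
    "celsius_to_kelvin",
    "ActivationParameters",
    "RateEntry",
    "arrhenius_fit",
    "converge_activation",
    "delta_g_at",
    "tst_rate",
    "rate_table",
    "compare_variants",
    "VariantComparison",
    "bootstrap_ci",
]

#: Gas constant, kcal/(mol*K).
R_KCAL = 1.987204e-3
#: Boltzmann constant over Planck constant, s^-1 K^-1 (Eyring prefactor / T).
KB_OVER_H = 2.083661e10
#: Reference temperature, K (22 degC; the temperature of the reported tables).
T_REF = 295.15
#: Temperatures at which free-energy profiles are sampled, K.
DEFAULT_TEMPERATURES = (285.0, 290.0, 295.0, 300.0, 305.0)
#: Temperatures of the rate tables, degC.
DEFAULT_RATE_TEMPS_C = (4.0, 22.0, 39.0)


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=float) + 273.15


@dataclass(frozen=True)
class ActivationParameters:
    """Thermodynamic activation parameters of one enzyme variant.

    ``dg_ref`` is always evaluated from the fit as ``dh - t_ref * ds`` so the
    identity dG‡(T_ref) = dH‡ - T_ref*dS‡ holds to machine precision.
    """

    label: str
    t_ref: float
    dh: float  # kcal/mol
    ds: float  # kcal/(mol*K)
    r_squared: float = float("nan")
    n_replicates: int | None = None
    ci_half_widths: Mapping[str, float] | None = None

    @property
    def dg_ref(self) -> float:
        return self.dh - self.t_ref * self.ds

    @property
    def tds_ref(self) -> float:
        return self.t_ref * self.ds


@dataclass(frozen=True)
class RateEntry:
    """One TST rate: variant, temperature and the rate in both unit styles."""

    label: str
    temperature: float  # K
    rate_per_s: float

    def __post_init__(self):
        if self.rate_per_s <= 0:
            raise ValueError("TST rates are strictly positive")

    @property
    def rate_x100(self) -> float:
        """Rate in the printed convention: k(s^-1) * 100."""
        return self.rate_per_s * 100.0


def arrhenius_fit(
    points: Sequence[tuple],
    *,
    t_ref: float = T_REF,
    label: str = "",
    weighted: bool = False,
    n_replicates: int | None = None,
) -> ActivationParameters:
    """Fit dG‡/T versus 1/T by least squares; slope = dH‡, intercept = -dS‡.

    Parameters
    ----------
    points : sequence of (T, dG‡) or (T, dG‡, sem)
        Temperatures in kelvin, barriers in kcal/mol.  The optional third
        element is the standard error of the barrier, used only when
        ``weighted`` is true (inverse-variance weights on dG‡/T).
    """
    pts = [tuple(p) for p in points]
    temps = np.array([p[0] for p in pts], dtype=float)
    dgs = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(temps)) < len(temps):
        raise ValueError("duplicate temperatures in Arrhenius fit")
    if len(temps) < 3:
        raise ValueError(f"Arrhenius fit needs >= 3 temperatures, got {len(temps)}")
    x = 1.0 / temps
    y = dgs / temps
    if weighted:
        sems = np.array([p[2] if len(p) > 2 else 1.0 for p in pts], dtype=float)
        sems_y = np.where(sems > 0, sems / temps, np.nan)
        w = 1.0 / np.nan_to_num(sems_y, nan=np.nanmin(sems_y) if np.any(sems_y > 0) else 1.0) ** 2
        wsum = w.sum()
        xbar = (w * x).sum() / wsum
        ybar = (w * y).sum() / wsum
        sxx = (w * (x - xbar) ** 2).sum()
        sxy = (w * (x - xbar) * (y - ybar)).sum()
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        ss_res = (w * (y - slope * x - intercept) ** 2).sum()
        ss_tot = (w * (y - ybar) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
    return ActivationParameters(
        label=label,
        t_ref=t_ref,
        dh=float(slope),
        ds=float(-intercept),
        r_squared=float(r2),
        n_replicates=n_replicates,
    )


def converge_activation(
    runner: Callable[[float], float],
    *,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    threshold: float = 0.8,
    batch: int = 10,
    start: int = 50,
    cap: int = 200,
    t_ref: float = T_REF,
    label: str = "",
) -> ActivationParameters:
    """Grow replicate batches until the Arrhenius fit exceeds the R² bound.

    ``runner(T)`` must return one new replicate barrier (kcal/mol) at
    temperature ``T`` per call.  Starting from ``start`` replicates per
    temperature, batches of ``batch`` are added and the fit of the
    per-temperature mean barriers recomputed, stopping at the first fit with
    R² > ``threshold``.  Raises :class:`ConvergenceError` (carrying the R²
    trajectory) if ``cap`` replicates per temperature are reached without
    convergence.
    """
    temps = [float(t) for t in temperatures]
    barriers: dict[float, list[float]] = {t: [] for t in temps}
    r2_history: list[float] = []
    n = 0
    target = start
    while True:
        while n < target:
            for t in temps:
                barriers[t].append(float(runner(t)))
            n += 1
        points = [(t, float(np.mean(barriers[t]))) for t in temps]
        params = arrhenius_fit(points, t_ref=t_ref, label=label, n_replicates=n)
        r2_history.append(params.r_squared)
        if params.r_squared > threshold:
            return params
        if n >= cap:
            raise ConvergenceError(
                f"Arrhenius R² stayed <= {threshold} after {n} replicates "
                f"per temperature (history: {r2_history})",
                r2_history=r2_history,
            )
        target = min(n + batch, cap)


def delta_g_at(p: ActivationParameters, temperature: float) -> float:
    """dG‡(T) = dH‡ - T*dS‡ (constant activation enthalpy and entropy)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return p.dh - temperature * p.ds


def tst_rate(dg: float, temperature: float) -> float:
    """Eyring rate k = (kB*T/h) exp(-dG‡/RT), s^-1, unit transmission."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_OVER_H * temperature * math.exp(-dg / (R_KCAL * temperature))


def rate_table(
    params: Sequence[ActivationParameters],
    temps_celsius: Sequence[float] = DEFAULT_RATE_TEMPS_C,
) -> pd.DataFrame:
    """TST rates for each variant at each temperature (Celsius input).

    Columns: variant, temp_c, temp_k, k_per_s, k_x100.
    """
    rows = []
    for p in params:
        for tc in temps_celsius:
            tk = float(celsius_to_kelvin(tc))
            entry = RateEntry(p.label, tk, tst_rate(delta_g_at(p, tk), tk))
            rows.append(
                {
                    "variant": p.label,
                    "temp_c": float(tc),
                    "temp_k": tk,
                    "k_per_s": entry.rate_per_s,
                    "k_x100": entry.rate_x100,
                }
            )
    return pd.DataFrame(rows, columns=["variant", "temp_c", "temp_k", "k_per_s", "k_x100"])


@dataclass(frozen=True)
class VariantComparison:
    """Mutant-versus-reference arithmetic at T_ref and per temperature."""

    wt_label: str
    mut_label: str
    ddg_ref: float  # kcal/mol, mut - wt at T_ref
    ddh: float
    d_tds_ref: float
    per_temperature: pd.DataFrame = field(repr=False)
    # columns: temp_c, rate_ratio (mut/wt), percent_of_wt


def compare_variants(
    wt: ActivationParameters,
    mut: ActivationParameters,
    temps_celsius: Sequence[float] = DEFAULT_RATE_TEMPS_C,
) -> VariantComparison:
    """Activation-parameter differences and mut/wt rate ratios.

    Note the exact compensation bookkeeping ddG‡(T) = ddH‡ - T*ddS‡.
    """
    if wt.t_ref != mut.t_ref:
        raise ValueError(f"mismatched reference temperatures: {wt.t_ref} vs {mut.t_ref}")
    rows = []
    for tc in temps_celsius:
        tk = float(celsius_to_kelvin(tc))
        ratio = tst_rate(delta_g_at(mut, tk), tk) / tst_rate(delta_g_at(wt, tk), tk)
        rows.append({"temp_c": float(tc), "rate_ratio": ratio, "percent_of_wt": 100.0 * ratio})
    return VariantComparison(
        wt_label=wt.label,
        mut_label=mut.label,
        ddg_ref=mut.dg_ref - wt.dg_ref,
        ddh=mut.dh - wt.dh,
        d_tds_ref=mut.tds_ref - wt.tds_ref,
        per_temperature=pd.DataFrame(rows, columns=["temp_c", "rate_ratio", "percent_of_wt"]),
    )


def bootstrap_ci(
    per_replicate_barriers: Mapping[float, Sequence[float]],
    n_boot: int = 2000,
    seed: int = 0,
    *,
    t_ref: float = T_REF,
    level: float = 0.95,
) -> dict[str, float]:
    """Percentile-bootstrap uncertainty of the Arrhenius decomposition.

    Replicate barriers are resampled with replacement within each
    temperature, the fit redone per resample, and percentile confidence
    intervals taken for dH‡ and T_ref*dS‡.  Returns the interval half-widths
    and bounds; deterministic given ``seed``.
    """
    temps = sorted(per_replicate_barriers)
    if len(temps) < 3:
        raise ValueError("bootstrap needs >= 3 temperatures")
    samples = {t: np.asarray(per_replicate_barriers[t], dtype=float) for t in temps}
    for t, arr in samples.items():
        if arr.size < 2:
            raise ValueError(f"need >= 2 replicates per temperature (T={t} has {arr.size})")
    rng = np.random.default_rng(seed)
    dh_boot = np.empty(n_boot)
    tds_boot = np.empty(n_boot)
    x = 1.0 / np.array(temps)
    for b in range(n_boot):
        means = np.array(
            [samples[t][rng.integers(0, samples[t].size, samples[t].size)].mean() for t in temps]
        )
        slope, intercept = np.polyfit(x, means / np.array(temps), 1)
        dh_boot[b] = slope
        tds_boot[b] = -intercept * t_ref
    alpha = 100.0 * (1.0 - level) / 2.0
    dh_lo, dh_hi = np.percentile(dh_boot, [alpha, 100.0 - alpha])
    tds_lo, tds_hi = np.percentile(tds_boot, [alpha, 100.0 - alpha])
    return {
        "dh_half_width": float((dh_hi - dh_lo) / 2.0),
        "tds_half_width": float((tds_hi - tds_lo) / 2.0),
        "dh_lo": float(dh_lo),
        "dh_hi": float(dh_hi),
        "tds_lo": float(tds_lo),
        "tds_hi": float(tds_hi),
        "level": float(level),
    }
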