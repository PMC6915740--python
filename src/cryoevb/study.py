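"""Canonical desk-scale study computations.

These functions bundle the package's headline computations at their
standard desk-scale problem sizes: scaled-down wildtype parameter recovery
(10 replicates, 1e4 steps per window, 5 temperatures), the sampled-profile
versus analytic-oracle comparison on a bath-free system (2e5 samples per
window), the mutant-preset shift-direction census, and the synthetic
loop-flexibility contrast.  They are what ``scripts/acceptance.py`` runs
and what the heavier end-to-end tests call.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .flexibility import iterative_average, loop_report, rmsf
from .free_energy import profile_deviation, umbrella_profile
from .pipeline import activation_from_series
from .reference import MUTANT_PRESETS, PRESET_TARGETS, WILDTYPE_PRESETS
from .sampling import run_replicate, run_temperature_series
from .surrogate import (
    DEFAULT_LOOPS,
    activation_summary,
    analytic_profile,
    build_variant,
    generate_backbone_ensemble,
    make_flex_profile,
)
from .evb import make_windows
from .thermo import DEFAULT_TEMPERATURES

__all__ = [
    "recover_wildtype_parameters",
    "oracle_deviation",
    "mutant_shift_directions",
    "loop_flexibility_contrast",
]


def recover_wildtype_parameters(
    master_seed: int,
    presets: Sequence[str] = WILDTYPE_PRESETS,
    *,
    n_replicates: int = 10,
    n_steps_per_window: int = 10_000,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
) -> dict[str, dict]:
    """Scaled-down end-to-end recovery of the declared (dH‡, T*dS‡) pairs.

    For each preset: replicated FEP sampling over the temperature ladder,
    per-replicate umbrella profiles and barriers, Arrhenius decomposition
    and bootstrap confidence intervals.  Returns, per preset, the fitted
    parameters, the CI half-widths, the declared targets, and whether the
    declared values fall inside the bootstrap intervals.
    """
    out: dict[str, dict] = {}
    for name in presets:
        system = build_variant(name)
        series = run_temperature_series(
            system,
            temperatures=temperatures,
            n_replicates=n_replicates,
            master_seed=master_seed,
            n_steps_per_window=n_steps_per_window,
        )
        params, per_temp = activation_from_series(
            series, label=name, bootstrap_seed=master_seed % (2**31)
        )
        dh_declared, tds_declared = PRESET_TARGETS[name]
        ci = params.ci_half_widths
        out[name] = {
            "params": params,
            "per_temp": per_temp,
            "declared": (dh_declared, tds_declared),
            "dh_in_ci": ci["dh_lo"] <= dh_declared <= ci["dh_hi"],
            "tds_in_ci": ci["tds_lo"] <= tds_declared <= ci["tds_hi"],
            "n_total_samples": int(
                n_replicates * len(temperatures) * 51 * n_steps_per_window
            ),
        }
    return out


def oracle_deviation(
    seed: int,
    *,
    samples_per_window: int = 200_000,
    n_windows: int = 51,
    temperature: float = 295.15,
) -> dict:
    """Max |sampled - analytic| profile deviation on a bath-free system.

    The bath-free psychrophilic-like diabats admit an exact free-energy
    curve, making the converged umbrella profile directly checkable.
    """
    system = dataclasses.replace(build_variant("SPE_like"), bath=())
    # total steps include the 10% burn-in on top of the production samples
    n_steps = int(round(samples_per_window / 0.9))
    rep = run_replicate(
        system,
        temperature,
        make_windows(n_windows),
        n_steps,
        replicate_seed=seed % (2**31),
    )
    profile = umbrella_profile(rep)
    oracle = analytic_profile(system, temperature)
    return {
        "max_abs_deviation": profile_deviation(profile, oracle),
        "dg_sampled": profile.dg_activation,
        "dg_analytic": oracle.dg_activation,
        "n_samples_per_window": int(rep.windows[0].n_frames),
    }


def mutant_shift_directions() -> dict:
    """Direction of each mutant preset's (dH‡, T*dS‡) shift vs its wildtype.

    Compares the analytic activation parameters of every calibrated mutant
    preset against its own wildtype, both to the tabulated direction
    (psychrophilic mutants shift dH‡ up and T*dS‡ toward zero, and vice
    versa — with one tabulated exception) and to the idealized expected
    direction.
    """
    wt = {side: activation_summary(build_variant(f"{side}_like")) for side in ("SPE", "PPE")}
    wt_declared = {side: PRESET_TARGETS[f"{side}_like"] for side in ("SPE", "PPE")}
    rows = []
    for name in MUTANT_PRESETS:
        side = name.split("_", 1)[0]
        s = activation_summary(build_variant(name))
        dh_shift = s["dh"] - wt[side]["dh"]
        tds_shift = s["tds_ref"] - wt[side]["tds_ref"]
        dh_declared = PRESET_TARGETS[name][0] - wt_declared[side][0]
        tds_declared = PRESET_TARGETS[name][1] - wt_declared[side][1]
        sign = 1.0 if side == "SPE" else -1.0  # expected: SPE up, PPE down
        rows.append(
            {
                "name": name,
                "matches_table": (
                    _same_direction(dh_shift, dh_declared)
                    and _same_direction(tds_shift, tds_declared)
                ),
                "expected_shift": sign * dh_shift > 0.1 and sign * tds_shift > 0.1,
            }
        )
    return {
        "per_mutant": rows,
        "n_matching_table": sum(r["matches_table"] for r in rows),
        "n_expected_shift": sum(r["expected_shift"] for r in rows),
        "n_mutants": len(rows),
    }


def _same_direction(shift: float, declared: float, tol: float = 0.15) -> bool:
    if abs(declared) < tol:
        return abs(shift) < 2 * tol
    return np.sign(shift) == np.sign(declared)


def loop_flexibility_contrast(
    seed: int,
    *,
    n_frames: int = 20_000,
    loop_multiplier: float = 1.35,
    base_amplitude: float = 0.4,
) -> dict:
    """Recover the loop RMSF contrast between a mobile and a rigid chain.

    Generates one ensemble with loop fluctuation amplitudes raised by
    ``loop_multiplier`` (psychrophilic-like) and a reference ensemble
    without, runs the full superposition + RMSF + loop-report analysis, and
    returns the mean per-loop percent change (ground truth:
    100*(multiplier - 1)).
    """
    rmsf_by_variant: dict[str, np.ndarray] = {}
    atoms = None
    for variant, mult in (("flexible", loop_multiplier), ("reference", 1.0)):
        profile = make_flex_profile(
            base_amplitude=base_amplitude, loop_multiplier=mult
        )
        traj = generate_backbone_ensemble(profile, n_frames, seed=seed % (2**31))
        atoms = traj.atoms
        avg, _ = iterative_average(traj, mask=traj.backbone_mask)
        rmsf_by_variant[variant] = rmsf(traj, avg, mask=traj.backbone_mask)
    report = loop_report(rmsf_by_variant, atoms, DEFAULT_LOOPS, "reference")
    return {
        "percent_change": report.percent_change("flexible"),
        "expected_percent": 100.0 * (loop_multiplier - 1.0),
        "n_frames": int(n_frames),
        "report": report,
    }
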