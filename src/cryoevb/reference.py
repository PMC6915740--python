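"""Published activation parameters and rate constants for the elastase pair.

These tables are the worked-example inputs of the package: computed
thermodynamic activation parameters (kcal/mol, at 22 degC / 295.15 K) and
TST rate constants (printed as k in s^-1 times 100) for the psychrophilic
salmon pancreatic elastase (SPE), the mesophilic porcine pancreatic
elastase (PPE) and fourteen designed surface-loop variants (seven per
enzyme).  Row labels name the mutation in the SPE numbering; the PPE column
of a row corresponds to the reverse substitution (e.g. the "S61R" row pairs
SPE S61R with PPE R61S).

They also define the calibration targets for the surrogate-system presets:
each preset is built so that its analytic (dH‡, T*dS‡) matches the
tabulated pair.  Not every tabulated dG‡ is self-consistent with its
components at the printed 0.1 kcal/mol precision (the published values come
from unrounded fits); ``SELF_CONSISTENT_DG`` lists the rows usable as exact
dG‡ = dH‡ - T*dS‡ identities.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ACTIVATION_PARAMS",
    "RATE_CONSTANTS_X100",
    "PRESET_TARGETS",
    "WILDTYPE_PRESETS",
    "MUTANT_PRESETS",
    "SELF_CONSISTENT_DG",
    "activation_frame",
    "rate_frame",
    "printed_rate_ratio",
]

# preset name -> (dG‡, dH‡, T*dS‡) at 295.15 K, kcal/mol
ACTIVATION_PARAMS: dict[str, tuple[float, float, float]] = {
    # --- salmon (psychrophilic) side ---
    "SPE_like": (18.0, 4.6, -13.4),
    "SPE_S61R": (18.5, 11.6, -6.9),
    "SPE_R63L_W65F_V88I": (17.7, 11.4, -6.3),
    "SPE_G93Y_G99A": (18.2, 14.2, -4.0),
    "SPE_G170S_W171Y": (18.3, 11.7, -6.5),
    "SPE_D186ins": (18.8, 4.6, -14.2),
    "SPE_D186ins_N188R": (18.8, 17.2, -1.7),
    "SPE_S218L_A221V": (18.0, 11.3, -6.7),
    # --- porcine (mesophilic) side ---
    "PPE_like": (19.2, 17.2, -2.0),
    "PPE_R61S": (18.5, 16.1, -2.5),
    "PPE_L63R_F65W_I88V": (19.4, 15.7, -3.6),
    "PPE_Y93G_A99G": (19.1, 12.0, -7.1),
    "PPE_S170G_Y171W": (19.5, 12.6, -6.9),
    "PPE_D186del": (19.8, 13.8, -6.0),
    "PPE_D186del_R188N": (19.4, 6.8, -12.6),
    "PPE_L218S_V221A": (19.4, 11.4, -8.0),
}

# preset name -> rate constants (x100 s^-1) at 4, 22 and 39 degC
RATE_CONSTANTS_X100: dict[str, tuple[float, float, float]] = {
    "SPE_like": (15.9, 28.9, 47.7),
    "SPE_S61R": (2.9, 11.4, 36.0),
    "SPE_R63L_W65F_V88I": (11.3, 43.7, 136.2),
    "SPE_G93Y_G99A": (3.7, 19.3, 77.7),
    "SPE_G170S_W171Y": (4.0, 16.2, 51.8),
    "SPE_D186ins": (3.6, 6.5, 10.7),
    "SPE_D186ins_N188R": (0.8, 6.0, 32.0),
    "SPE_S218L_A221V": (6.6, 25.3, 78.0),
    "PPE_like": (0.4, 2.8, 15.1),
    "PPE_R61S": (1.5, 10.0, 48.3),
    "PPE_L63R_F65W_I88V": (0.4, 2.5, 11.5),
    "PPE_Y93G_A99G": (1.0, 4.0, 13.2),
    "PPE_S170G_Y171W": (0.5, 2.0, 7.0),
    "PPE_D186del": (0.2, 1.1, 4.4),
    "PPE_D186del_R188N": (0.9, 2.1, 4.2),
    "PPE_L218S_V221A": (0.6, 2.3, 7.2),
}

RATE_TEMPS_C = (4.0, 22.0, 39.0)

#: Surrogate-preset calibration targets: name -> (dH‡, T*dS‡) at 295.15 K.
PRESET_TARGETS: dict[str, tuple[float, float]] = {
    name: (dh, tds) for name, (_dg, dh, tds) in ACTIVATION_PARAMS.items()
}

WILDTYPE_PRESETS = ("SPE_like", "PPE_like")
MUTANT_PRESETS = tuple(n for n in ACTIVATION_PARAMS if n not in WILDTYPE_PRESETS)

#: Rows whose printed dG‡ equals dH‡ - T*dS‡ at 0.1 kcal/mol precision.
SELF_CONSISTENT_DG = tuple(
    name
    for name, (dg, dh, tds) in ACTIVATION_PARAMS.items()
    if abs(dg - (dh - tds)) < 0.05
)


def activation_frame() -> pd.DataFrame:
    """Activation parameters as a DataFrame (variant, dg, dh, tds)."""
    return pd.DataFrame(
        [(n, *v) for n, v in ACTIVATION_PARAMS.items()],
        columns=["variant", "dg", "dh", "tds"],
    )


def rate_frame() -> pd.DataFrame:
    """Printed rate constants as a long DataFrame (variant, temp_c, k_x100)."""
    rows = [
        {"variant": n, "temp_c": t, "k_x100": k}
        for n, ks in RATE_CONSTANTS_X100.items()
        for t, k in zip(RATE_TEMPS_C, ks)
    ]
    return pd.DataFrame(rows, columns=["variant", "temp_c", "k_x100"])


def printed_rate_ratio(mutant: str, wildtype: str, temp_c: float) -> float:
    """Ratio of printed rate constants, mutant over wildtype, at ``temp_c``."""
    df = rate_frame().set_index(["variant", "temp_c"])["k_x100"]
    return float(df[(mutant, temp_c)] / df[(wildtype, temp_c)])
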