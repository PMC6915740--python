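"""Two-state empirical valence bond (EVB) energy model.

The rate-limiting step of the reaction (formation of the tetrahedral
intermediate in serine-protease acylation) is described by two diabatic
valence-bond states: a reactant state with energy ``eps1`` and a product
state whose raw energy is calibrated by a constant gas-phase shift
``gas_shift_alpha``.  The adiabatic ground-state surface is the lower
eigenvalue of the 2x2 Hamiltonian

    H = [[eps1, H12], [H12, eps2']],    eps2' = eps2_raw + gas_shift_alpha

and the generalized reaction coordinate is the energy gap X = eps1 - eps2'.
All energies are classical potential energies in kcal/mol.

Sign conventions used throughout the package:

* the gas-phase shift is applied to state 2 exactly once, at energy
  evaluation (every downstream consumer sees the shifted ``eps2'``);
* reactant-dominated configurations have X < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "EVBParameters",
    "StateEnergies",
    "MappingWindow",
    "shifted_state2",
    "adiabatic_ground",
    "ground_state_weights",
    "mapping_energy",
    "energy_gap",
    "make_windows",
]

#: Number of FEP sampling windows used per reaction free-energy calculation.
DEFAULT_N_WINDOWS = 51


@dataclass(frozen=True)
class EVBParameters:
    """Constant parameters of the two-state EVB Hamiltonian.

    Parameters
    ----------
    gas_shift_alpha : float
        Gas-phase shift added to the diabatic product state, kcal/mol.
    coupling_h12 : float
        Off-diagonal coupling element H12, kcal/mol.  Must be >= 0.
    """

    gas_shift_alpha: float = 195.0
    coupling_h12: float = 113.0

    def __post_init__(self):
        if not (math.isfinite(self.gas_shift_alpha) and math.isfinite(self.coupling_h12)):
            raise ValueError("EVB parameters must be finite")
        if self.coupling_h12 < 0:
            raise ValueError(f"coupling_h12 must be >= 0, got {self.coupling_h12}")


@dataclass(frozen=True)
class StateEnergies:
    """Diabatic energies of one configuration (product state already shifted)."""

    eps1: float
    eps2_shifted: float

    def __post_init__(self):
        if not (math.isfinite(self.eps1) and math.isfinite(self.eps2_shifted)):
            raise ValueError("diabatic energies must be finite")


@dataclass(frozen=True)
class MappingWindow:
    """One FEP mapping window: index m and mixing parameter lambda in [0, 1]."""

    index: int
    lam: float

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")


def shifted_state2(eps2_raw, params: EVBParameters):
    """Apply the gas-phase shift to the raw product diabatic energy.

    This is the single authoritative application point of the shift; all
    downstream code consumes the returned ``eps2'``.
    """
    eps2_raw = np.asarray(eps2_raw, dtype=float)
    if not np.all(np.isfinite(eps2_raw)):
        raise ValueError("eps2_raw must be finite")
    out = eps2_raw + params.gas_shift_alpha
    return float(out) if out.ndim == 0 else out


def adiabatic_ground(s, params: EVBParameters):
    """Ground-state eigenvalue of the 2x2 EVB Hamiltonian.

    Eg = (eps1 + eps2')/2 - sqrt((eps1 - eps2')^2 + 4 H12^2)/2.

    Never exceeds either diabatic energy; equals min(eps1, eps2') when the
    coupling vanishes.  Accepts a :class:`StateEnergies` or a pair of
    (broadcastable) arrays.
    """
    e1, e2 = _unpack(s)
    h12 = params.coupling_h12
    out = 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * h12 * h12)
    return float(out) if np.ndim(out) == 0 else out


def ground_state_weights(s, params: EVBParameters):
    """Squared ground-state eigenvector coefficients (c1^2, c2^2).

    The Hellmann-Feynman gradient of the ground surface along any coordinate
    is ``c1^2 * grad(eps1) + c2^2 * grad(eps2')`` (the coupling is constant).
    """
    e1, e2 = _unpack(s)
    h12 = params.coupling_h12
    if h12 == 0.0:
        c1sq = np.where(np.asarray(e1) <= np.asarray(e2), 1.0, 0.0)
        c2sq = 1.0 - c1sq
    else:
        delta = e1 - e2
        root = np.sqrt(delta * delta + 4.0 * h12 * h12)
        # dEg/de1 = c1^2 by Hellmann-Feynman; closed form below.  The
        # root can underflow to zero for subnormal couplings; the states
        # are then maximally mixed.
        with np.errstate(divide="ignore", invalid="ignore"):
            c1sq = np.where(root > 0, 0.5 * (1.0 - delta / np.where(root > 0, root, 1.0)), 0.5)
        c2sq = 1.0 - c1sq
    if np.ndim(c1sq) == 0:
        return float(c1sq), float(c2sq)
    return c1sq, c2sq


def mapping_energy(s, lam):
    """FEP mapping potential eps_m = (1 - lam) * eps1 + lam * eps2'."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0.0) or np.any(lam_arr > 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    e1, e2 = _unpack(s)
    out = (1.0 - lam_arr) * e1 + lam_arr * e2
    return float(out) if np.ndim(out) == 0 else out


def energy_gap(s):
    """Energy-gap reaction coordinate X = eps1 - eps2' (reactant at X < 0)."""
    e1, e2 = _unpack(s)
    out = e1 - e2
    return float(out) if np.ndim(out) == 0 else out


def make_windows(n_windows: int = DEFAULT_N_WINDOWS) -> list[MappingWindow]:
    """Evenly spaced mapping windows lambda_m = m / (n_windows - 1)."""
    if n_windows < 2:
        raise ConfigError(f"n_windows must be >= 2, got {n_windows}")
    denom = n_windows - 1
    return [MappingWindow(index=m, lam=m / denom) for m in range(n_windows)]


def _unpack(s):
    if isinstance(s, StateEnergies):
        return s.eps1, s.eps2_shifted
    e1, e2 = s
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))):
        raise ValueError("diabatic energies must be finite")
    return e1, e2
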