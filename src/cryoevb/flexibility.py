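"""Backbone mobility analysis: superposition, average structures and RMSF.

The flexibility observable is the per-atom root-mean-square positional
fluctuation about an iteratively superposed average structure,

    RMSF_i = sqrt( < |r_i - <r_i>|^2 > ),

where every frame is least-squares superposed (Kabsch) onto the running
average, and the average is recomputed until it stops moving ("iterpose"
style iterative superposition).  Loop-level flexibility is the mean
backbone RMSF over the residues of a surface-loop region, and variants are
compared as the percent change relative to a reference variant, averaged at
the RMSF level over independent replicate trajectories.

Backbone atoms are N, CA and C (three beads per residue); the superposition
mask for averaging defaults to all backbone atoms of the whole chain so
that loop fluctuations are measured in the frame of the stable core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError

__all__ = [
    "BACKBONE_NAMES",
    "Structure",
    "Trajectory",
    "LoopRegion",
    "FlexibilityReport",
    "kabsch_superpose",
    "apply_transform",
    "iterative_average",
    "rmsf",
    "loop_report",
    "make_bead_atoms",
]

BACKBONE_NAMES = ("N", "CA", "C")

#: Fraction of leading frames discarded under the equilibration protocol
#: (2 ns of equilibration out of 12 ns simulated = first sixth).
EQUILIBRATION_DISCARD = 1.0 / 6.0


@dataclass
class Structure:
    """Atom table (resid, resname, name, chain) plus Cartesian coordinates, A."""

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def backbone_mask(self) -> np.ndarray:
        return self.atoms["name"].isin(BACKBONE_NAMES).to_numpy()


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table; coords shaped (n_frames, n_atoms, 3)."""

    atoms: pd.DataFrame
    coords: np.ndarray
    frame_spacing_ps: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords must be (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(atoms=self.atoms, coords=self.coords[i])

    @property
    def backbone_mask(self) -> np.ndarray:
        return self.atoms["name"].isin(BACKBONE_NAMES).to_numpy()


@dataclass(frozen=True)
class LoopRegion:
    """A named surface-loop region: chain id plus inclusive residue range."""

    name: str
    chain: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"loop {self.name}: start {self.start} > end {self.end}")


def _resolve_mask(mask, n_atoms: int) -> np.ndarray:
    if mask is None:
        return np.ones(n_atoms, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    out = np.zeros(n_atoms, dtype=bool)
    out[mask] = True
    return out


def kabsch_superpose(mobile, reference, mask=None):
    """Optimal proper rotation and translation of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the masked RMSD to the
    reference.  The rotation always has determinant +1.  Raises
    :class:`DegenerateGeometryError` for < 3 masked atoms or collinear sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    m = _resolve_mask(mask, mobile.shape[0])
    if m.sum() != _resolve_mask(mask, reference.shape[0]).sum() or mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal masked atom counts")
    if m.sum() < 3:
        raise DegenerateGeometryError(f"need >= 3 masked atoms, got {int(m.sum())}")
    mob = mobile[m]
    ref = reference[m]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    sv = np.linalg.svd(b, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise DegenerateGeometryError("masked atoms are (nearly) collinear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, rssd = Rotation.align_vectors(a, b)
    rmat = rot.as_matrix()
    translation = ref_c - mob_c @ rmat.T
    fitted = mob @ rmat.T + translation
    rmsd = float(np.sqrt(((fitted - ref) ** 2).sum() / m.sum()))
    return rmat, translation, rmsd


def apply_transform(coords, rotation, translation):
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def iterative_average(
    traj: Trajectory,
    mask=None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[Structure, int]:
    """Iteratively superposed average structure of a trajectory.

    Alternates (superpose every frame onto the current average; recompute
    the coordinate mean) until the average moves less than ``tol`` A (RMS
    over masked atoms) or ``max_iter`` is reached, in which case a warning
    is issued and the best average returned.  Returns the converged average
    and the number of iterations used.
    """
    if traj.n_frames < 2:
        raise ValueError("iterative averaging needs >= 2 frames")
    m = _resolve_mask(mask, traj.coords.shape[1])
    avg = traj.coords[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        acc = np.zeros_like(avg)
        for f in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(traj.coords[f], avg, mask=m)
            acc += apply_transform(traj.coords[f], rot, trans)
        new_avg = acc / traj.n_frames
        disp = float(np.sqrt(((new_avg[m] - avg[m]) ** 2).sum() / m.sum()))
        avg = new_avg
        if disp < tol:
            return Structure(atoms=traj.atoms, coords=avg), n_iter
    warnings.warn(
        f"iterative average did not converge in {max_iter} iterations", RuntimeWarning
    )
    return Structure(atoms=traj.atoms, coords=avg), n_iter


def rmsf(
    traj: Trajectory,
    average: Structure,
    mask=None,
    *,
    discard_fraction: float = 0.0,
) -> np.ndarray:
    """Per-atom RMSF about ``average`` after masked superposition of each frame.

    ``discard_fraction`` drops that leading fraction of frames before the
    analysis (set to 1/6 to mirror a 2 ns equilibration of a 12 ns run).
    """
    m = _resolve_mask(mask, traj.coords.shape[1])
    if not m.any():
        raise ValueError("superposition mask is empty")
    start = int(round(discard_fraction * traj.n_frames))
    frames = traj.coords[start:]
    if frames.shape[0] < 1:
        raise ValueError("no frames left after discarding equilibration")
    acc = np.zeros(traj.coords.shape[1])
    for f in range(frames.shape[0]):
        rot, trans, _ = kabsch_superpose(frames[f], average.coords, mask=m)
        dev = apply_transform(frames[f], rot, trans) - average.coords
        acc += (dev**2).sum(axis=1)
    return np.sqrt(acc / frames.shape[0])


@dataclass
class FlexibilityReport:
    """Per-atom and per-loop flexibility of several variants vs a reference."""

    atoms: pd.DataFrame
    reference_variant: str
    per_atom: dict[str, np.ndarray]
    per_atom_spread: dict[str, np.ndarray]
    n_replicates: dict[str, int]
    loops: pd.DataFrame = field(repr=False)
    # columns: variant, loop, mean_rmsf, pct_change

    def percent_change(self, variant: str, loops: Sequence[str] | None = None) -> float:
        """Mean of per-loop percent changes for ``variant`` (its mutant bar)."""
        df = self.loops[self.loops["variant"] == variant]
        if loops is not None:
            df = df[df["loop"].isin(loops)]
        if df.empty:
            raise KeyError(f"no loop rows for variant {variant!r}")
        return float(df["pct_change"].mean())


def loop_report(
    rmsf_by_variant: Mapping[str, np.ndarray | Sequence[np.ndarray]],
    atoms: pd.DataFrame,
    regions: Sequence[LoopRegion],
    reference_variant: str,
) -> FlexibilityReport:
    """Per-loop mean backbone RMSF and percent change vs a reference variant.

    Values per variant may be a single per-atom RMSF array or a sequence of
    arrays from independent replicate trajectories; replicates are averaged
    at the RMSF level before the percent change is taken.
    """
    if reference_variant not in rmsf_by_variant:
        raise KeyError(f"reference variant {reference_variant!r} missing")
    per_atom: dict[str, np.ndarray] = {}
    spread: dict[str, np.ndarray] = {}
    n_reps: dict[str, int] = {}
    for variant, value in rmsf_by_variant.items():
        arrs = (
            [np.asarray(value, dtype=float)]
            if np.asarray(value[0]).ndim == 0
            else [np.asarray(a, dtype=float) for a in value]
        )
        if any(a.shape != (len(atoms),) for a in arrs):
            raise ValueError(f"variant {variant!r}: RMSF length does not match atom table")
        stack = np.stack(arrs)
        per_atom[variant] = stack.mean(axis=0)
        spread[variant] = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(len(atoms))
        n_reps[variant] = stack.shape[0]

    backbone = atoms["name"].isin(BACKBONE_NAMES).to_numpy()
    resids = atoms["resid"].to_numpy()
    chains = atoms["chain"].to_numpy()
    region_masks = {}
    for region in regions:
        sel = (
            backbone
            & (chains == region.chain)
            & (resids >= region.start)
            & (resids <= region.end)
        )
        if not sel.any():
            raise ValueError(
                f"loop {region.name!r} ({region.chain} {region.start}-{region.end}) "
                "selects no atoms"
            )
        region_masks[region.name] = sel

    rows = []
    for variant in rmsf_by_variant:
        for name, sel in region_masks.items():
            mean_rmsf = float(per_atom[variant][sel].mean())
            ref_rmsf = float(per_atom[reference_variant][sel].mean())
            rows.append(
                {
                    "variant": variant,
                    "loop": name,
                    "mean_rmsf": mean_rmsf,
                    "pct_change": 100.0 * (mean_rmsf - ref_rmsf) / ref_rmsf,
                }
            )
    return FlexibilityReport(
        atoms=atoms,
        reference_variant=reference_variant,
        per_atom=per_atom,
        per_atom_spread=spread,
        n_replicates=n_reps,
        loops=pd.DataFrame(rows, columns=["variant", "loop", "mean_rmsf", "pct_change"]),
    )


def make_bead_atoms(n_residues: int, chain: str = "A") -> pd.DataFrame:
    """Atom table for a three-bead (N, CA, C) backbone chain."""
    rows = [
        {"resid": i + 1, "resname": "ALA", "name": name, "chain": chain}
        for i in range(n_residues)
        for name in BACKBONE_NAMES
    ]
    return pd.DataFrame(rows, columns=["resid", "resname", "name", "chain"])
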