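"""Trajectory file I/O: multi-model PDB and XYZ frame files.

Parsing and writing go through MDAnalysis; this module adds strict
pre-validation (consistent atom counts across models, well-formed
MODEL/ENDMDL nesting) with errors that name the offending model, plus the
loop-region table reader.

XYZ files carry no residue metadata: on reading, atoms are assigned to
residues in consecutive triplets (the three-bead N/CA/C backbone convention
of the surrogate generator).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrajectoryFormatError
from .flexibility import BACKBONE_NAMES, LoopRegion, Trajectory

__all__ = [
    "read_trajectory",
    "write_multimodel_pdb",
    "write_xyz_frames",
    "read_loop_regions",
]


def _validate_pdb(path: Path) -> None:
    counts: list[int] = []
    in_model = False
    model_index = 0
    current = 0
    saw_model = False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                raise TrajectoryFormatError(
                    f"nested MODEL record inside model {model_index}"
                )
            in_model = True
            saw_model = True
            model_index += 1
            current = 0
        elif rec == "ENDMDL":
            if not in_model:
                raise TrajectoryFormatError(
                    f"ENDMDL without matching MODEL (after model {model_index})"
                )
            in_model = False
            counts.append(current)
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if in_model:
        raise TrajectoryFormatError(f"MODEL {model_index} not closed by ENDMDL")
    if saw_model and len(set(counts)) > 1:
        bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"model {bad} has {counts[bad - 1]} atoms, expected {counts[0]}"
        )


def _validate_xyz(path: Path) -> None:
    lines = path.read_text().splitlines()
    i = 0
    frame = 0
    n_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame += 1
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryFormatError(f"frame {frame}: bad atom-count line {i + 1}")
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise TrajectoryFormatError(f"frame {frame} has {n} atoms, expected {n_ref}")
        i += 2 + n
    if n_ref is None:
        raise TrajectoryFormatError("empty XYZ file")


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ frame file into a :class:`Trajectory`.

    Format is inferred from the suffix unless ``fmt`` ("pdb" or "xyz") is
    given.  Frames are kept in file order; PDB residue numbering is
    preserved (1-based).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "xyz"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if fmt == "pdb":
        _validate_pdb(path)
    else:
        _validate_xyz(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
        names = [str(n) for n in u.atoms.names]
        if fmt == "pdb":
            resids = [int(r) for r in u.atoms.resids]
            resnames = [str(r) for r in u.atoms.resnames]
            try:
                chains = [str(c) if str(c).strip() else "A" for c in u.atoms.chainIDs]
            except (AttributeError, mda.exceptions.NoDataError):
                chains = ["A"] * len(names)
        else:
            resids = [i // 3 + 1 for i in range(len(names))]
            resnames = ["ALA"] * len(names)
            chains = ["A"] * len(names)
    atoms = pd.DataFrame(
        {"resid": resids, "resname": resnames, "name": names, "chain": chains}
    )
    return Trajectory(atoms=atoms, coords=coords)


def _as_universe(traj: Trajectory):
    import MDAnalysis as mda

    atoms = traj.atoms
    resid_codes, resid_index = pd.factorize(
        pd.Series(list(zip(atoms["chain"], atoms["resid"])))
    )
    n_res = len(resid_index)
    u = mda.Universe.empty(
        len(atoms),
        n_residues=n_res,
        atom_resindex=resid_codes,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].tolist())
    u.add_TopologyAttr("chainIDs", atoms["chain"].tolist())
    first_atom = np.searchsorted(resid_codes, np.arange(n_res))
    u.add_TopologyAttr("resids", atoms["resid"].to_numpy()[first_atom])
    u.add_TopologyAttr("resnames", atoms["resname"].to_numpy()[first_atom])
    u.add_TopologyAttr("elements", [n[:1] for n in atoms["name"]])
    u.load_new(np.asarray(traj.coords, dtype=np.float32), order="fac")
    return u


def _write(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda

    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=len(traj.atoms), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_multimodel_pdb(traj: Trajectory, path) -> Path:
    """Write a trajectory as MODEL/ENDMDL records (one model per frame)."""
    path = Path(path).with_suffix(".pdb")
    _write(traj, path)
    return path


def write_xyz_frames(traj: Trajectory, path) -> Path:
    """Write a trajectory as concatenated XYZ frames."""
    path = Path(path).with_suffix(".xyz")
    _write(traj, path)
    return path


def read_loop_regions(path) -> list[LoopRegion]:
    """Read a delimited loop-region file with columns name, chain, start, end."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    expected = ["name", "chain", "start", "end"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"region file missing columns: {missing}")
    return [
        LoopRegion(
            name=str(r["name"]),
            chain=str(r["chain"]),
            start=int(r["start"]),
            end=int(r["end"]),
        )
        for _, r in df.iterrows()
    ]
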