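"""Boltzmann sampling of surrogate systems under FEP mapping potentials.

Metropolis Monte Carlo replaces molecular dynamics here: every observable
downstream (free-energy profiles, RMSF) is configurational, so no dynamics
are needed, and the per-replicate randomization of initial velocities maps
to seed-randomized MC streams.  The sampler works on the bath-marginal
effective potential

    V_m(x; T) = (1 - lam_m) eps1(x) + lam_m eps2'(x) + T * eta(x),

which is the exact x-marginal of the joint mapping potential after the
harmonic bath modes are integrated out; explicit bath coordinates can be
drawn from their conditional Gaussians for any retained frame, which
reproduces exact joint samples.

Protocol mirrored from the reference procedure: systems are annealed from
1 K to the target temperature in the tetrahedral-intermediate (lam = 1)
state before production; windows are then sampled in ascending lambda, each
starting from the previous window's final state, with the first fraction of
each window discarded as burn-in (during which the Gaussian step size is
tuned to a 30-50% acceptance rate, then frozen).

Randomness is organized hash-free around counter-based Philox streams: one
64-bit master key plus a counter (temperature index, replicate, window,
stage), so every draw in a study is reachable from the master seed and
replicates/windows are statistically independent by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SamplerFailureError
from .evb import MappingWindow, make_windows
from .surrogate import SurrogateSystem
from .thermo import DEFAULT_TEMPERATURES, R_KCAL

__all__ = [
    "WindowTrajectory",
    "ReplicateRun",
    "equilibrate",
    "sample_window",
    "run_replicate",
    "run_temperature_series",
    "write_replicate_frames",
    "load_replicate_frames",
]

log = logging.getLogger(__name__)

DEFAULT_STEPS_PER_WINDOW = 10_000
DEFAULT_BURN_IN = 0.1
#: Window-slot value reserved for the annealing stage in seed counters.
EQUILIBRATION_SLOT = 0xFFFF
_ADAPT_INTERVAL = 100


def _rng(seed: int, counter=(0, 0, 0, 0)) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=int(seed), counter=list(counter)))


def _potential_factory(sys: SurrogateSystem, lam: float, temperature: float):
    """Fast closure for the bath-marginal mapping potential."""
    k1, x1, e1 = sys.k1, sys.x1, sys.e1
    k2, x2 = sys.k2, sys.x2
    e2 = sys.e2_raw + sys.evb.gas_shift_alpha
    c = sys.switch_center
    x_ref = sys.reactant_ref if sys.reactant_ref is not None else sys.x1
    terms: dict[float, float] = {}
    for mode in sys.bath:
        # normalized switch (s - s0)/(1 - s0); the constant -s0/(1 - s0)
        # part is dropped (Metropolis only sees energy differences)
        s0 = math.exp(-((x_ref - c) ** 2) / (2.0 * mode.width**2))
        amp = (
            0.5
            * R_KCAL
            * math.log(mode.k_transition / mode.k_reactant)
            * temperature
            / (1.0 - s0)
        )
        terms[mode.width] = terms.get(mode.width, 0.0) + amp
    term_list = [(a, 2.0 * w * w) for w, a in terms.items() if a != 0.0]

    def potential(x):
        v = (1.0 - lam) * (0.5 * k1 * (x - x1) ** 2 + e1) + lam * (
            0.5 * k2 * (x - x2) ** 2 + e2
        )
        for amp, denom in term_list:
            v = v + amp * np.exp(-((x - c) ** 2) / denom)
        return v

    return potential


def _advance(potential, x, rt, normals, logu, step, *, adapt=False, stride=None):
    """Advance parallel Metropolis chains through one block of draws.

    Returns (final x, recorded positions (C, n_rec), accepted counts, step).
    """
    n = normals.shape[1]
    v = potential(x)
    accepted = np.zeros(x.shape[0], dtype=np.int64)
    block = np.zeros(x.shape[0], dtype=np.int64)
    rec = []
    for i in range(n):
        prop = x + step * normals[:, i]
        vp = potential(prop)
        hit = logu[:, i] < (v - vp) / rt
        x = np.where(hit, prop, x)
        v = np.where(hit, vp, v)
        accepted += hit
        if adapt:
            block += hit
            if (i + 1) % _ADAPT_INTERVAL == 0:
                frac = block / _ADAPT_INTERVAL
                step = np.where(
                    frac < 0.3, step * 0.8, np.where(frac > 0.5, step * 1.25, step)
                )
                block[:] = 0
        if stride is not None and (i + 1) % stride == 0:
            rec.append(x.copy())
    xs = np.stack(rec, axis=1) if rec else np.empty((x.shape[0], 0))
    return x, xs, accepted, step


@dataclass
class WindowTrajectory:
    """Per-window samples at one temperature, with lazily evaluated energies.

    Stores the reaction-coordinate samples; the diabatic, gap, ground-state
    and mapping energies are exact functions of x and are evaluated on
    demand (plus the explicit bath potential when bath coordinates were
    recorded).  All frames share one window and temperature by
    construction.
    """

    system: SurrogateSystem
    window: MappingWindow
    temperature: float
    seed: int
    counter: tuple[int, int, int, int]
    x: np.ndarray
    step_size: float
    accept_rate: float
    n_steps: int
    stride: int = 1
    bath_coords: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size < 1:
            raise ValueError("window trajectory must hold at least one frame")

    @property
    def n_frames(self) -> int:
        return self.x.size

    @property
    def bath_potential(self) -> np.ndarray:
        if self.bath_coords is None:
            return np.zeros_like(self.x)
        k = self.system.bath_stiffness(self.x)
        return 0.5 * (k * self.bath_coords**2).sum(axis=1)

    @property
    def eps1(self) -> np.ndarray:
        return self.system.eps1(self.x) + self.bath_potential

    @property
    def eps2_shifted(self) -> np.ndarray:
        return self.system.eps2_shifted(self.x) + self.bath_potential

    @property
    def gap(self) -> np.ndarray:
        return self.system.gap(self.x)

    @property
    def ground(self) -> np.ndarray:
        return self.system.ground(self.x) + self.bath_potential

    @property
    def mapping(self) -> np.ndarray:
        lam = self.window.lam
        return (1.0 - lam) * self.eps1 + lam * self.eps2_shifted

    @property
    def frames(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "step": (np.arange(self.n_frames) + 1) * self.stride,
                "x": self.x,
                "eps1": self.eps1,
                "eps2_shifted": self.eps2_shifted,
                "gap": self.gap,
                "ground": self.ground,
                "mapping": self.mapping,
            }
        )
        if self.bath_coords is not None:
            for i in range(self.bath_coords.shape[1]):
                df[f"bath_{i}"] = self.bath_coords[:, i]
        return df


@dataclass
class ReplicateRun:
    """One replicate: all window trajectories at a single temperature."""

    label: str
    temperature: float
    replicate_id: int
    windows: list[WindowTrajectory]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        lams = [w.window.lam for w in self.windows]
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("windows must be in ascending lambda order")
        if any(w.temperature != self.temperature for w in self.windows):
            raise ValueError("all windows must share the replicate temperature")


def _default_schedule(t_final: float) -> np.ndarray:
    return np.geomspace(1.0, t_final, 12)


def equilibrate(
    sys: SurrogateSystem,
    t_final: float,
    schedule: Sequence[float] | None = None,
    seed: int = 0,
    *,
    steps_per_stage: int = 200,
    counter: tuple[int, int, int, int] = (0, 0, EQUILIBRATION_SLOT, 0),
) -> float:
    """Anneal to ``t_final`` in the product (tetrahedral-intermediate) state.

    Starting from the product-well bottom, short Metropolis runs on the
    lam = 1 mapping potential are chained over a temperature ladder (default
    geometric, 1 K to ``t_final``).  Returns the final reaction coordinate;
    deterministic given the seed.
    """
    ladder = np.asarray(
        _default_schedule(t_final) if schedule is None else schedule, dtype=float
    )
    if ladder.size and (np.any(np.diff(ladder) < 0)):
        raise ConfigError("annealing ladder must be non-decreasing")
    if ladder.size and ladder[0] > 10.0:
        raise ConfigError(f"annealing ladder must start at <= 10 K, got {ladder[0]}")
    x = np.array([sys.x2], dtype=float)
    if steps_per_stage <= 0 or ladder.size == 0:
        return float(x[0])
    rng = _rng(seed, counter)
    for t_stage in ladder:
        potential = _potential_factory(sys, 1.0, t_stage)
        rt = R_KCAL * t_stage
        step = np.full(1, 2.4 * math.sqrt(rt / sys.k2))
        normals = rng.standard_normal((1, steps_per_stage))
        logu = np.log(rng.random((1, steps_per_stage)))
        x, _, _, _ = _advance(potential, x, rt, normals, logu, step, adapt=True)
    return float(x[0])


def _sample_window_batch(
    sys: SurrogateSystem,
    window: MappingWindow,
    temperature: float,
    n_steps: int,
    rngs: Sequence[np.random.Generator],
    starts: np.ndarray,
    *,
    stride: int = 1,
    burn_in: float = DEFAULT_BURN_IN,
    seed: int = 0,
    counters: Sequence[tuple] = (),
    bath_rngs: Sequence[np.random.Generator] | None = None,
    initial_step: float | None = None,
) -> list[WindowTrajectory]:
    """Advance one window for several replicate chains in lockstep.

    Each chain consumes draws only from its own stream, so results are
    identical whether chains run batched or one at a time.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n_burn = int(burn_in * n_steps)
    n_prod = n_steps - n_burn
    if n_prod < 1:
        raise ValueError("burn-in leaves no production steps")
    potential = _potential_factory(sys, window.lam, temperature)
    rt = R_KCAL * temperature
    k_eff = min(sys.k1, sys.k2)
    x = np.asarray(starts, dtype=float).copy()
    step0 = initial_step if initial_step is not None else 2.4 * math.sqrt(rt / k_eff)
    step = np.full(x.shape[0], step0)

    def draw(n):
        normals = np.stack([r.standard_normal(n) for r in rngs])
        logu = np.log(np.stack([r.random(n) for r in rngs]))
        return normals, logu

    if n_burn > 0:
        normals, logu = draw(n_burn)
        x, _, _, step = _advance(potential, x, rt, normals, logu, step, adapt=True)
    normals, logu = draw(n_prod)
    x, xs, accepted, _ = _advance(
        potential, x, rt, normals, logu, step, adapt=False, stride=stride
    )
    out = []
    for c in range(x.shape[0]):
        if accepted[c] == 0:
            raise SamplerFailureError(
                f"window {window.index} (lambda={window.lam:.3f}) accepted no "
                f"moves over {n_prod} production steps"
            )
        bath = None
        if bath_rngs is not None and len(sys.bath) > 0:
            k = sys.bath_stiffness(xs[c])
            bath = bath_rngs[c].standard_normal(k.shape) * np.sqrt(rt / k)
        out.append(
            WindowTrajectory(
                system=sys,
                window=window,
                temperature=temperature,
                seed=seed,
                counter=tuple(counters[c]) if counters else (0, 0, window.index, 0),
                x=xs[c],
                step_size=float(step[c]),
                accept_rate=float(accepted[c] / n_prod),
                n_steps=n_steps,
                stride=stride,
                bath_coords=bath,
            )
        )
    return out


def sample_window(
    sys: SurrogateSystem,
    window: MappingWindow,
    temperature: float,
    n_steps: int,
    seed: int,
    start: float,
    *,
    stride: int = 1,
    burn_in: float = DEFAULT_BURN_IN,
    record_bath: bool = False,
    counter: tuple[int, int, int, int] | None = None,
    initial_step: float | None = None,
) -> WindowTrajectory:
    """Sample one mapping window with Metropolis MC from ``start``.

    Targets the density proportional to exp(-V_m/RT); the Gaussian step
    size is tuned during burn-in (30-50% acceptance) and frozen for
    production; records are thinned by ``stride``.  Deterministic given the
    seed (and optional Philox counter).
    """
    ctr = counter if counter is not None else (0, 0, window.index, 0)
    bath_ctr = (*ctr[:3], ctr[3] + 1)
    traj = _sample_window_batch(
        sys,
        window,
        temperature,
        n_steps,
        [_rng(seed, ctr)],
        np.array([start], dtype=float),
        stride=stride,
        burn_in=burn_in,
        seed=seed,
        counters=[ctr],
        bath_rngs=[_rng(seed, bath_ctr)] if record_bath else None,
        initial_step=initial_step,
    )[0]
    log.debug(
        "window %d lam=%.3f T=%.1f acceptance %.2f",
        window.index,
        window.lam,
        temperature,
        traj.accept_rate,
    )
    return traj


def run_replicate(
    sys: SurrogateSystem,
    temperature: float,
    windows: Sequence[MappingWindow],
    n_steps_per_window: int,
    replicate_seed: int,
    *,
    replicate_id: int = 0,
    temp_index: int = 0,
    stride: int = 1,
    burn_in: float = DEFAULT_BURN_IN,
    record_bath: bool = False,
    equilibration_steps: int = 200,
) -> ReplicateRun:
    """One full FEP pass: anneal, then sample all windows in ascending lambda.

    Each window is seeded deterministically from the replicate seed and the
    counter (temp_index, replicate_id, window, stage), and starts from the
    previous window's final state.
    """
    runs = _run_replicates_batch(
        sys,
        temperature,
        windows,
        n_steps_per_window,
        replicate_seed,
        [replicate_id],
        temp_index=temp_index,
        stride=stride,
        burn_in=burn_in,
        record_bath=record_bath,
        equilibration_steps=equilibration_steps,
    )
    return runs[0]


def _run_replicates_batch(
    sys: SurrogateSystem,
    temperature: float,
    windows: Sequence[MappingWindow],
    n_steps_per_window: int,
    master_seed: int,
    replicate_ids: Sequence[int],
    *,
    temp_index: int = 0,
    stride: int = 1,
    burn_in: float = DEFAULT_BURN_IN,
    record_bath: bool = False,
    equilibration_steps: int = 200,
) -> list[ReplicateRun]:
    windows = list(windows)
    lams = [w.lam for w in windows]
    if any(b <= a for a, b in zip(lams, lams[1:])):
        raise ConfigError("windows must be in strictly ascending lambda order")
    starts = np.array(
        [
            equilibrate(
                sys,
                temperature,
                seed=master_seed,
                counter=(temp_index, rep, EQUILIBRATION_SLOT, 0),
                steps_per_stage=equilibration_steps,
            )
            for rep in replicate_ids
        ]
    )
    per_rep_windows: list[list[WindowTrajectory]] = [[] for _ in replicate_ids]
    for window in windows:
        counters = [(temp_index, rep, window.index, 0) for rep in replicate_ids]
        rngs = [_rng(master_seed, c) for c in counters]
        bath_rngs = (
            [_rng(master_seed, (temp_index, rep, window.index, 1)) for rep in replicate_ids]
            if record_bath
            else None
        )
        trajs = _sample_window_batch(
            sys,
            window,
            temperature,
            n_steps_per_window,
            rngs,
            starts,
            stride=stride,
            burn_in=burn_in,
            seed=master_seed,
            counters=counters,
            bath_rngs=bath_rngs,
        )
        starts = np.array([t.x[-1] for t in trajs])
        for c, t in enumerate(trajs):
            per_rep_windows[c].append(t)
    return [
        ReplicateRun(
            label=sys.label,
            temperature=temperature,
            replicate_id=rep,
            windows=per_rep_windows[c],
            provenance={
                "master_seed": int(master_seed),
                "temp_index": int(temp_index),
                "replicate": int(rep),
                "n_windows": len(windows),
                "n_steps_per_window": int(n_steps_per_window),
                "stride": int(stride),
                "burn_in": float(burn_in),
                "acceptance": [t.accept_rate for t in per_rep_windows[c]],
            },
        )
        for c, rep in enumerate(replicate_ids)
    ]


def run_temperature_series(
    sys: SurrogateSystem,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    n_replicates: int = 50,
    master_seed: int = 0,
    *,
    n_windows: int = 51,
    n_steps_per_window: int = DEFAULT_STEPS_PER_WINDOW,
    stride: int = 1,
    burn_in: float = DEFAULT_BURN_IN,
    record_bath: bool = False,
    equilibration_steps: int = 200,
) -> dict[float, list[ReplicateRun]]:
    """Replicated FEP runs over a temperature ladder.

    Seeds derive reproducibly from ``master_seed`` via the counter scheme
    (temperature index, replicate, window, stage); the same master seed
    always yields identical runs, and each replicate's stream is isolated.
    """
    temps = [float(t) for t in temperatures]
    if len(set(temps)) != len(temps):
        raise ConfigError(f"duplicate temperatures: {temps}")
    windows = make_windows(n_windows)
    out: dict[float, list[ReplicateRun]] = {}
    for t_idx, t in enumerate(temps):
        out[t] = _run_replicates_batch(
            sys,
            t,
            windows,
            n_steps_per_window,
            master_seed,
            list(range(n_replicates)),
            temp_index=t_idx,
            stride=stride,
            burn_in=burn_in,
            record_bath=record_bath,
            equilibration_steps=equilibration_steps,
        )
        log.info("sampled %s at %.1f K: %d replicates", sys.label, t, n_replicates)
    return out


# ---------------------------------------------------------------------------
# Frame-table persistence (delimited text + JSON sidecar)
# ---------------------------------------------------------------------------


@dataclass
class TableWindow:
    """A window's frames reloaded from a persisted frame table.

    Duck-typed stand-in for :class:`WindowTrajectory` in the free-energy
    estimators (exposes ``window``, ``temperature``, ``gap``, ``mapping``
    and ``ground`` arrays).
    """

    window: MappingWindow
    temperature: float
    gap: np.ndarray
    mapping: np.ndarray
    ground: np.ndarray
    eps1: np.ndarray
    eps2_shifted: np.ndarray


@dataclass
class TableReplicate:
    """Replicate reassembled from frame tables, usable by the estimators."""

    label: str
    temperature: float
    replicate_id: int
    windows: list[TableWindow]
    provenance: dict = field(default_factory=dict)


def write_replicate_frames(rep: ReplicateRun, directory) -> None:
    """Persist a replicate as one frame table per window plus a JSON sidecar.

    Each table has one row per retained frame (step, x, eps1, eps2', X, Eg,
    eps_m); the sidecar records variant, temperature, lambdas and
    provenance.
    """
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for traj in rep.windows:
        path = directory / f"window_{traj.window.index:03d}.tsv"
        traj.frames.to_csv(path, sep="\t", index=False, float_format="%.8f")
    sidecar = {
        "label": rep.label,
        "temperature": rep.temperature,
        "replicate_id": rep.replicate_id,
        "lambdas": [w.window.lam for w in rep.windows],
        "provenance": rep.provenance,
    }
    (directory / "replicate.json").write_text(json.dumps(sidecar, indent=2))


def load_replicate_frames(directory) -> TableReplicate:
    """Reload a persisted replicate for downstream free-energy analysis."""
    import json
    from pathlib import Path

    directory = Path(directory)
    sidecar = json.loads((directory / "replicate.json").read_text())
    windows = []
    for index, lam in enumerate(sidecar["lambdas"]):
        df = pd.read_csv(directory / f"window_{index:03d}.tsv", sep="\t")
        windows.append(
            TableWindow(
                window=MappingWindow(index=index, lam=float(lam)),
                temperature=float(sidecar["temperature"]),
                gap=df["gap"].to_numpy(),
                mapping=df["mapping"].to_numpy(),
                ground=df["ground"].to_numpy(),
                eps1=df["eps1"].to_numpy(),
                eps2_shifted=df["eps2_shifted"].to_numpy(),
            )
        )
    return TableReplicate(
        label=sidecar["label"],
        temperature=float(sidecar["temperature"]),
        replicate_id=int(sidecar["replicate_id"]),
        windows=windows,
        provenance=sidecar.get("provenance", {}),
    )
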