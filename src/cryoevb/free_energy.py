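"""Free-energy profiles along the energy-gap coordinate.

Window trajectories are turned into a reaction free-energy profile in two
steps.  First the Zwanzig (exponential-average) estimator accumulates the
free energy of moving between adjacent mapping potentials,

    dG(lam_m -> lam_{m+1}) = -RT ln < exp(-(eps_{m+1} - eps_m)/RT) >_m,

where eps_{m+1} - eps_m = -dlam * X for the linear mapping potential.
Second, the EVB umbrella correction reweights each window's samples from
the mapping potential to the adiabatic ground surface, binned along X:

    dG(X_b) = dG(lam_m) - RT ln < delta_b(X) exp(-(Eg - eps_m)/RT) >_m.

Bins are combined across windows by sample-count weighting, the profile is
shifted so the reactant minimum sits at zero, and the activation and
reaction free energies are read off the stationary points.  All exponential
averages are log-sum-exp stabilized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .errors import AggregationError, BarrierUnresolvedError, NoBarrierError
from .thermo import R_KCAL

__all__ = [
    "FreeEnergyProfile",
    "zwanzig_increment",
    "fep_free_energies",
    "umbrella_profile",
    "extract_barrier",
    "aggregate_replicates",
    "BarrierStats",
    "profile_deviation",
    "write_profile",
    "read_profile",
]

#: Minimum raw frames per (window, bin) for that window to contribute.
DEFAULT_SUPPORT_THRESHOLD = 10
DEFAULT_N_BINS = 100
#: Percentile trim of the pooled X range (avoids stray extreme samples).
DEFAULT_TRIM = (0.5, 99.5)
#: Minimum peak/valley prominence (kcal/mol) when locating stationary bins.
STATIONARY_PROMINENCE = 0.5


@dataclass
class FreeEnergyProfile:
    """Binned free energy dG(X) along the energy gap, with stationary points.

    ``delta_g`` is NaN for unsupported bins; supported values are normalized
    so the reactant minimum is zero.  Stationary-point fields are
    ``(X_location, value)`` pairs.
    """

    bin_centers: np.ndarray
    delta_g: np.ndarray
    counts: np.ndarray | None
    temperature: float
    label: str = ""
    reactant: tuple[float, float] | None = None
    transition_state: tuple[float, float] | None = None
    product: tuple[float, float] | None = None
    dg_activation: float | None = None
    dg_reaction: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def supported(self) -> np.ndarray:
        return np.isfinite(self.delta_g)


def zwanzig_increment(traj, lam_next: float) -> float:
    """Free energy of perturbing one window's samples to the next lambda.

    Exact exponential-average estimator, log-sum-exp stabilized.  Uses
    eps_{next} - eps_m = -(lam_next - lam_m) * X evaluated on the stored
    frames of ``traj``.
    """
    if not 0.0 <= lam_next <= 1.0:
        raise ValueError(f"lam_next must lie in [0, 1], got {lam_next}")
    gap = np.asarray(traj.gap, dtype=float)
    if gap.size == 0:
        raise ValueError("empty window trajectory")
    rt = R_KCAL * traj.temperature
    du = -(lam_next - traj.window.lam) * gap
    return float(-rt * (logsumexp(-du / rt) - np.log(gap.size)))


def fep_free_energies(rep, *, bidirectional: bool = True) -> np.ndarray:
    """Cumulative FEP free energies dG(lam_m) across a replicate's windows.

    dG(lam_0) = 0.  By default each increment averages the forward estimate
    from window m with the backward estimate from window m+1 (cancels the
    leading-order bias of the exponential average); ``bidirectional=False``
    selects plain forward accumulation.
    """
    windows = rep.windows
    lams = [w.window.lam for w in windows]
    if any(b <= a for a, b in zip(lams, lams[1:])):
        raise ValueError("windows must be in strictly ascending lambda order")
    incs = []
    for m in range(len(windows) - 1):
        fwd = zwanzig_increment(windows[m], lams[m + 1])
        if bidirectional:
            bwd = -zwanzig_increment(windows[m + 1], lams[m])
            incs.append(0.5 * (fwd + bwd))
        else:
            incs.append(fwd)
    return np.concatenate([[0.0], np.cumsum(incs)])


def umbrella_profile(
    rep,
    n_bins: int = DEFAULT_N_BINS,
    *,
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    trim: tuple[float, float] = DEFAULT_TRIM,
    bidirectional: bool = True,
    bin_edges: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """EVB umbrella free-energy profile along X from one replicate run.

    Per-bin ground-surface estimates from every window that places at least
    ``support_threshold`` raw frames in the bin are combined by
    sample-count weighting.  Unsupported bins are masked (NaN), never
    interpolated.  Raises :class:`BarrierUnresolvedError`, naming the lambda
    range to densify, when masked bins separate the two free-energy minima.
    """
    if n_bins < 10:
        raise ValueError(f"n_bins must be >= 10, got {n_bins}")
    temperature = rep.temperature
    rt = R_KCAL * temperature
    fep = fep_free_energies(rep, bidirectional=bidirectional)

    gaps = [np.asarray(w.gap, dtype=float) for w in rep.windows]
    pooled = np.concatenate(gaps)
    if bin_edges is not None:
        edges = np.asarray(bin_edges, dtype=float)
        n_bins = edges.size - 1
    else:
        lo, hi = np.percentile(pooled, trim)
        if not hi > lo:
            lo, hi = pooled.min(), pooled.max() + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    num = np.zeros(n_bins)  # sum of count-weighted estimates
    counts = np.zeros(n_bins, dtype=int)
    window_mean_x = []
    for m, w in enumerate(rep.windows):
        x = gaps[m]
        window_mean_x.append(float(x.mean()))
        logw = (np.asarray(w.mapping, dtype=float) - np.asarray(w.ground, dtype=float)) / rt
        idx = np.digitize(x, edges) - 1
        inside = (idx >= 0) & (idx < n_bins)
        idx, lw = idx[inside], logw[inside]
        if idx.size == 0:
            continue
        binned = np.bincount(idx, minlength=n_bins)
        n_total = x.size
        for b in np.nonzero(binned >= support_threshold)[0]:
            est = fep[m] - rt * (logsumexp(lw[idx == b]) - np.log(n_total))
            num[b] += binned[b] * est
            counts[b] += binned[b]

    delta_g = np.full(n_bins, np.nan)
    mask = counts > 0
    delta_g[mask] = num[mask] / counts[mask]

    profile = FreeEnergyProfile(
        bin_centers=centers,
        delta_g=delta_g,
        counts=counts,
        temperature=temperature,
        label=getattr(rep, "label", ""),
        meta={"fep_free_energies": fep, "n_bins": n_bins},
    )
    _finalize(profile, window_mean_x=window_mean_x)
    return profile


def extract_barrier(profile: FreeEnergyProfile) -> tuple[float, float]:
    """Activation and reaction free energies from a binned profile.

    The transition state is the highest interior maximum between the
    outermost minima; the reactant (product) value is the lowest supported
    bin below (above) the transition state.  Raises
    :class:`NoBarrierError` for monotone profiles.
    """
    sup = profile.supported
    if sup.sum() < 3:
        raise NoBarrierError("profile has fewer than 3 supported bins")
    g = profile.delta_g[sup]
    x = profile.bin_centers[sup]
    ts_idx = _transition_index(g)
    r_idx = int(np.argmin(g[:ts_idx]))
    p_idx = ts_idx + 1 + int(np.argmin(g[ts_idx + 1 :]))
    dg_act = float(g[ts_idx] - g[r_idx])
    dg_rxn = float(g[p_idx] - g[r_idx])
    profile.reactant = (float(x[r_idx]), float(g[r_idx]))
    profile.transition_state = (float(x[ts_idx]), float(g[ts_idx]))
    profile.product = (float(x[p_idx]), float(g[p_idx]))
    profile.dg_activation = dg_act
    profile.dg_reaction = dg_rxn
    return dg_act, dg_rxn


def _transition_index(g: np.ndarray) -> int:
    """Index of the transition-state bin within a supported-bin array."""
    peaks, _ = find_peaks(g, prominence=STATIONARY_PROMINENCE)
    if peaks.size == 0:
        raise NoBarrierError("no interior maximum in profile")
    valleys, _ = find_peaks(-g, prominence=STATIONARY_PROMINENCE)
    candidates = sorted({0, g.size - 1, *valleys.tolist()})
    left, right = candidates[0], candidates[-1]
    between = peaks[(peaks > left) & (peaks < right)]
    if between.size == 0:
        raise NoBarrierError("no interior maximum between the outermost minima")
    return int(between[np.argmax(g[between])])


def _finalize(profile: FreeEnergyProfile, window_mean_x=None) -> None:
    """Normalize to the reactant minimum and fill stationary-point fields."""
    try:
        extract_barrier(profile)
    except NoBarrierError:
        sup = profile.supported
        if sup.any():
            profile.delta_g = profile.delta_g - np.nanmin(profile.delta_g)
        return
    # Check support continuity between the minima before trusting the barrier.
    sup = profile.supported
    x_r = profile.reactant[0]
    x_p = profile.product[0]
    gap_bins = (
        (profile.bin_centers > x_r) & (profile.bin_centers < x_p) & ~sup
    )
    if gap_bins.any():
        lam_hint = None
        if window_mean_x:
            missing_x = profile.bin_centers[gap_bins]
            means = np.asarray(window_mean_x)
            lo_i = int(np.argmin(np.abs(means - missing_x.min())))
            hi_i = int(np.argmin(np.abs(means - missing_x.max())))
            n = len(window_mean_x) - 1
            lam_hint = (min(lo_i, hi_i) / max(n, 1), max(lo_i, hi_i) / max(n, 1))
        raise BarrierUnresolvedError(
            "unsupported bins between the reactant and product minima; "
            f"densify sampling around lambda {lam_hint}",
            lam_range=lam_hint,
        )
    shift = profile.reactant[1]
    profile.delta_g = profile.delta_g - shift
    profile.reactant = (profile.reactant[0], 0.0)
    profile.transition_state = (
        profile.transition_state[0],
        profile.transition_state[1] - shift,
    )
    profile.product = (profile.product[0], profile.product[1] - shift)


@dataclass(frozen=True)
class BarrierStats:
    """Replicate-level barrier statistics at one temperature."""

    temperature: float
    mean: float
    sem: float
    values: tuple[float, ...]


def aggregate_replicates(profiles: Sequence[FreeEnergyProfile]) -> BarrierStats:
    """Mean and standard error of per-replicate activation free energies.

    Barriers are extracted per replicate first and then averaged, keeping
    the replicate dispersion available for the convergence loop and the
    bootstrap.  All profiles must share one temperature.
    """
    if not profiles:
        raise AggregationError("no profiles to aggregate")
    temps = {p.temperature for p in profiles}
    if len(temps) > 1:
        raise AggregationError(f"mixed temperatures in aggregation: {sorted(temps)}")
    values = []
    for p in profiles:
        if p.dg_activation is None:
            extract_barrier(p)
        values.append(float(p.dg_activation))
    arr = np.asarray(values)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return BarrierStats(
        temperature=float(temps.pop()),
        mean=float(arr.mean()),
        sem=sem,
        values=tuple(values),
    )


def write_profile(profile: FreeEnergyProfile, path) -> None:
    """Write a profile as delimited text with a JSON comment header."""
    import json
    from pathlib import Path

    header = {
        "temperature": profile.temperature,
        "variant": profile.label,
        "normalization": "reactant minimum at zero",
        "dg_activation": profile.dg_activation,
        "dg_reaction": profile.dg_reaction,
    }
    counts = (
        profile.counts
        if profile.counts is not None
        else np.zeros(profile.bin_centers.size, dtype=int)
    )
    lines = ["# " + json.dumps(header), "bin_center\tdelta_g\tcount"]
    for x, g, c in zip(profile.bin_centers, profile.delta_g, counts):
        lines.append(f"{x:.6f}\t{g:.6f}\t{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> FreeEnergyProfile:
    """Read a profile written by :func:`write_profile`."""
    import json
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    header = json.loads(lines[0].lstrip("# "))
    rows = [line.split("\t") for line in lines[2:] if line.strip()]
    profile = FreeEnergyProfile(
        bin_centers=np.array([float(r[0]) for r in rows]),
        delta_g=np.array([float(r[1]) for r in rows]),
        counts=np.array([int(r[2]) for r in rows]),
        temperature=float(header["temperature"]),
        label=str(header.get("variant", "")),
        dg_activation=header.get("dg_activation"),
        dg_reaction=header.get("dg_reaction"),
        meta={"header": header},
    )
    return profile


def profile_deviation(profile: FreeEnergyProfile, reference: FreeEnergyProfile) -> float:
    """Max |profile - reference| after aligning additive constants.

    The reference (e.g. an analytic oracle) is interpolated at the
    profile's supported bin centers; the additive constant is fixed by the
    count-weighted mean offset over those bins.
    """
    sup = profile.supported
    x = profile.bin_centers[sup]
    g = profile.delta_g[sup]
    ref_sup = reference.supported
    ref = np.interp(x, reference.bin_centers[ref_sup], reference.delta_g[ref_sup])
    w = profile.counts[sup] if profile.counts is not None else np.ones_like(g)
    offset = np.average(g - ref, weights=w)
    return float(np.max(np.abs(g - ref - offset)))
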