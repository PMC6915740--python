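"""Run configuration: TOML schema, validation and defaults.

Defaults mirror the reference protocol: 51 FEP windows, temperatures
285/290/295/300/305 K, replicate policy of 50 starting replicates grown in
batches of 10 until the Arrhenius R² exceeds 0.8.  Validation aggregates
all problems (it does not stop at the first) and rejects unknown keys with
a spelling suggestion.
"""

from __future__ import annotations

import difflib
import tomllib
from dataclasses import dataclass, field, fields as dc_fields
from typing import Any

from .errors import ConfigError

__all__ = [
    "ReplicatePolicy",
    "SamplerSettings",
    "BinningSettings",
    "FlexibilitySettings",
    "RunConfig",
    "validate_config",
    "load_config",
]


@dataclass(frozen=True)
class ReplicatePolicy:
    start: int = 50
    batch: int = 10
    threshold: float = 0.8
    cap: int = 200
    mode: str = "converge"  # "converge" or "fixed"


@dataclass(frozen=True)
class SamplerSettings:
    n_windows: int = 51
    steps_per_window: int = 10_000
    stride: int = 1
    burn_in: float = 0.1
    master_seed: int = 0
    equilibration_steps: int = 200


@dataclass(frozen=True)
class BinningSettings:
    n_bins: int = 100
    support_threshold: int = 10
    trim_lo: float = 0.5
    trim_hi: float = 99.5
    bidirectional: bool = True


@dataclass(frozen=True)
class FlexibilitySettings:
    enabled: bool = False
    n_frames: int = 2000
    n_replicates: int = 4
    loop_multiplier: float = 1.35
    base_amplitude: float = 0.4
    discard_fraction: float = 1.0 / 6.0


@dataclass(frozen=True)
class RunConfig:
    variants: tuple[str, ...] = ("SPE_like", "PPE_like")
    temperatures: tuple[float, ...] = (285.0, 290.0, 295.0, 300.0, 305.0)
    t_ref: float = 295.15
    rate_temps_celsius: tuple[float, ...] = (4.0, 22.0, 39.0)
    output_dir: str = "results"
    replicates: ReplicatePolicy = field(default_factory=ReplicatePolicy)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    binning: BinningSettings = field(default_factory=BinningSettings)
    flexibility: FlexibilitySettings = field(default_factory=FlexibilitySettings)


_SECTIONS = {
    "replicates": ReplicatePolicy,
    "sampler": SamplerSettings,
    "binning": BinningSettings,
    "flexibility": FlexibilitySettings,
}
_TOP_SCALARS = {"variants", "temperatures", "t_ref", "rate_temps_celsius", "output_dir"}


def _suggest(key: str, known) -> str:
    match = difflib.get_close_matches(key, list(known), n=1)
    return f" (did you mean {match[0]!r}?)" if match else ""


def _coerce_section(cls, data: dict, path: str, errors: list[str]):
    known = {f.name for f in dc_fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{path}.{key}: unknown key{_suggest(key, known)}")
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def validate_config(raw_text: str) -> RunConfig:
    """Parse and validate a TOML run configuration.

    An empty document yields the full-default (reference-protocol) config.
    All violations are aggregated into one :class:`ConfigError`.
    """
    errors: list[str] = []
    try:
        data = tomllib.loads(raw_text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"not valid TOML: {exc}") from exc

    top_known = _TOP_SCALARS | set(_SECTIONS)
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a table")
                continue
            kwargs[key] = _coerce_section(_SECTIONS[key], value, key, errors)
        elif key in _TOP_SCALARS:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        else:
            errors.append(f"{key}: unknown key{_suggest(key, top_known)}")

    cfg = RunConfig(**{k: v for k, v in kwargs.items() if k in {f.name for f in dc_fields(RunConfig)}})
    _check_values(cfg, errors)
    if errors:
        raise ConfigError(
            "invalid run configuration:\n  " + "\n  ".join(errors), errors=errors
        )
    return cfg


def _check_values(cfg: RunConfig, errors: list[str]) -> None:
    if not cfg.variants:
        errors.append("variants: must name at least one variant")
    temps = list(cfg.temperatures)
    if len(set(temps)) != len(temps):
        errors.append("temperatures: duplicate values")
    for t in temps:
        if t <= 0:
            errors.append(f"temperatures: must be positive kelvin, got {t}")
    if cfg.t_ref <= 0:
        errors.append(f"t_ref: must be positive, got {cfg.t_ref}")
    r = cfg.replicates
    if r.mode not in ("converge", "fixed"):
        errors.append(f"replicates.mode: must be 'converge' or 'fixed', got {r.mode!r}")
    if r.start < 1 or r.batch < 1 or r.cap < r.start:
        errors.append("replicates: need start >= 1, batch >= 1, cap >= start")
    if not 0.0 <= r.threshold <= 1.0:
        errors.append(f"replicates.threshold: must lie in [0, 1], got {r.threshold}")
    s = cfg.sampler
    if s.n_windows < 2:
        errors.append(f"sampler.n_windows: must be >= 2, got {s.n_windows}")
    if s.steps_per_window < 10:
        errors.append(f"sampler.steps_per_window: must be >= 10, got {s.steps_per_window}")
    if not 0.0 <= s.burn_in < 1.0:
        errors.append(f"sampler.burn_in: must lie in [0, 1), got {s.burn_in}")
    b = cfg.binning
    if b.n_bins < 10:
        errors.append(f"binning.n_bins: must be >= 10, got {b.n_bins}")
    if not 0.0 <= b.trim_lo < b.trim_hi <= 100.0:
        errors.append("binning: need 0 <= trim_lo < trim_hi <= 100")
    f = cfg.flexibility
    if f.n_frames < 2:
        errors.append(f"flexibility.n_frames: must be >= 2, got {f.n_frames}")
    if f.base_amplitude <= 0 or f.loop_multiplier <= 0:
        errors.append("flexibility: amplitudes and multipliers must be positive")


def load_config(path) -> RunConfig:
    """Read and validate a TOML configuration file."""
    from pathlib import Path

    return validate_config(Path(path).read_text())
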