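"""Exception hierarchy for the cryoevb pipeline."""


class CryoEvbError(Exception):
    """Base class for all cryoevb-specific errors."""


class ConfigError(CryoEvbError, ValueError):
    """Invalid configuration value or malformed run configuration.

    May carry an aggregated list of messages in ``errors``.
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors) if errors is not None else [message]


class DegenerateSystemError(CryoEvbError, ValueError):
    """Surrogate parameter set does not produce a double-well ground surface."""


class DegenerateGeometryError(CryoEvbError, ValueError):
    """Atom selection too small or collinear for a unique superposition."""


class CalibrationError(CryoEvbError, RuntimeError):
    """Preset calibration failed to reach its target activation parameters."""


class SamplerFailureError(CryoEvbError, RuntimeError):
    """Monte Carlo sampler accepted no moves over a full production run."""


class BarrierUnresolvedError(CryoEvbError, RuntimeError):
    """No bin near the barrier top reached the support threshold.

    ``lam_range`` names the mapping-parameter range whose sampling should be
    densified.
    """

    def __init__(self, message, lam_range=None):
        super().__init__(message)
        self.lam_range = lam_range


class NoBarrierError(CryoEvbError, ValueError):
    """Free-energy profile has no interior maximum between two minima."""


class AggregationError(CryoEvbError, ValueError):
    """Replicate profiles cannot be aggregated (mixed temperature/variant)."""


class ConvergenceError(CryoEvbError, RuntimeError):
    """Replicate-batch convergence loop exhausted its cap.

    ``r2_history`` carries the trajectory of regression coefficients seen.
    """

    def __init__(self, message, r2_history=None):
        super().__init__(message)
        self.r2_history = list(r2_history) if r2_history is not None else []


class TrajectoryFormatError(CryoEvbError, ValueError):
    """Trajectory file is malformed (inconsistent models, bad nesting...)."""
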