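"""Exception hierarchy for the cpgdrnn package."""


class CpgDrnnError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CpgDrnnError, ValueError):
    """A configuration value is outside its admissible range."""


class InsufficientDataError(CpgDrnnError, ValueError):
    """Too little signal to perform the requested analysis (e.g. < 3 gait cycles)."""


class ExtractionError(CpgDrnnError, ValueError):
    """Harmonic extraction failed (no spectral peak in the physiologic band)."""


class DegenerateNormalizationError(CpgDrnnError, ValueError):
    """A channel is constant and cannot be mapped onto [-1, 1]."""


class StabilityError(CpgDrnnError, ValueError):
    """The Euler step dt is too large relative to the smallest time constant."""


class DivergenceError(CpgDrnnError, ArithmeticError):
    """Network state or training loss became non-finite."""


class TrainingFailedError(CpgDrnnError, RuntimeError):
    """All restarts diverged despite rate-reduction recovery."""


class UndefinedSIError(CpgDrnnError, ValueError):
    """Similarity index is undefined because one pattern has zero energy."""


class DegenerateInputError(CpgDrnnError, ValueError):
    """Input has no variance (rank-0) and admits no plane fit."""


class CheckpointFormatError(CpgDrnnError, ValueError):
    """A parameter checkpoint file is corrupted or has an unknown schema."""


class EmptyReportError(CpgDrnnError, ValueError):
    """No experiment results were supplied to the report generator."""
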