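"""Exception hierarchy shared across the pipeline."""


class EegBetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegBetaError, ValueError):
    """An invalid configuration value; the message names the violated constraint."""


class TooShortRecordingError(EegBetaError, ValueError):
    """A recording is too short for the requested operation."""


class UnsupportedUpsamplingError(EegBetaError, ValueError):
    """Resampling above the original rate is not supported."""


class CalibrationError(EegBetaError, ValueError):
    """Not enough usable data to calibrate the artifact model."""


class InterpolationError(EegBetaError, ValueError):
    """Too few good electrodes to fit the spherical spline."""


class EmptyRecordingError(EegBetaError, ValueError):
    """Window rejection removed the entire recording."""


class EstimationError(EegBetaError, ValueError):
    """Spectral estimation impossible on the given input."""


class UndefinedFeatureError(EegBetaError, ValueError):
    """A feature is undefined (e.g. zero total band power on a silent channel)."""


class DegenerateLabelsError(EegBetaError, ValueError):
    """Classification labels contain fewer than two classes."""


class DegenerateInputError(EegBetaError, ValueError):
    """A statistical test received degenerate input (empty group, zero variance...)."""


class AlignmentError(EegBetaError, ValueError):
    """Paired inputs are misaligned."""


class PipelineStageError(EegBetaError, RuntimeError):
    """Wraps an error raised inside a named preprocessing stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
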