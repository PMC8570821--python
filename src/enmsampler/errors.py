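"""Exception hierarchy.

Every error raised by this package derives from :class:`EnmSamplerError`,
so callers can catch one base class at pipeline boundaries.
"""


class EnmSamplerError(Exception):
    """Base class for all package errors."""


class InputError(EnmSamplerError):
    """A user-supplied input (file path, accession) is missing or unusable."""


class FormatError(EnmSamplerError):
    """A file exists but cannot be parsed under the supported dialect."""


class ContractError(EnmSamplerError):
    """An API precondition was violated (shape/count mismatch, bad argument)."""


class SelectionError(EnmSamplerError):
    """An atom-selection expression is unsupported or selects nothing usable."""


class ModelError(EnmSamplerError):
    """The elastic network cannot be built on the given coordinates."""


class DegeneracyError(ModelError):
    """The network has a degenerate spectrum (wrong rigid-body mode count)."""


class SamplingError(EnmSamplerError):
    """Conformer generation failed (e.g. repeated zero-norm displacement)."""


class GeometryError(EnmSamplerError):
    """A geometric operation is ill-posed (collinear selection, etc.)."""


class AnalysisError(EnmSamplerError):
    """An ensemble-analysis operation received degenerate data."""


class RelaxationError(EnmSamplerError):
    """Structural relaxation failed (adapter fault, broken contract)."""


class NumericError(RelaxationError):
    """Non-finite energy or force encountered during minimization."""


class ConfigurationError(EnmSamplerError):
    """Pipeline/backend configuration is invalid or incomplete."""


class PipelineError(EnmSamplerError):
    """A pipeline stage failed; message carries generation/stage context."""


class ResumeError(PipelineError):
    """A resume request is inconsistent with the stored run record."""
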