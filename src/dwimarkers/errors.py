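"""Typed exceptions raised by the pipeline.

All readers and validators raise subclasses of :class:`ValidationError`;
nothing is silently coerced.
"""


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class ShapeMismatchError(ValidationError):
    """Array dimensions do not match what the acquisition scheme implies."""


class SchemeError(ValidationError):
    """b-value/direction table is malformed or a key shell is absent."""


class LabelError(ValidationError):
    """Label volume inconsistent with its dictionary."""


class ManifestError(ValidationError):
    """Study manifest violates the session layout contract."""


class SignatureError(ValidationError):
    """Signature library or kurtosis parameters out of their valid domain."""


class EmptyRoiError(ValidationError):
    """ROI contains no valid voxel."""


class TimecourseError(ValidationError):
    """Scan sequence cannot be partitioned into time points."""


class CalibrationError(ValidationError):
    """Requested effect size is not reachable within the valid model domain."""


class PhantomError(ValidationError):
    """Phantom geometry infeasible on the requested grid."""
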