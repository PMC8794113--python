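"""Exception hierarchy for :mod:`calimb`."""


class CalimbError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CalimbError, ValueError):
    """A dataset specification violates its invariants."""


class InvalidDistortionError(CalimbError, ValueError):
    """A distortion family was given non-invertible or out-of-domain parameters."""


class DegenerateLabelsError(CalimbError, ValueError):
    """An operation requiring both classes received single-class labels."""


class DegenerateInputError(CalimbError, ValueError):
    """Input scores carry no usable signal (e.g. all identical)."""


class FitError(CalimbError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics in ``args``."""


class ScoreFileError(CalimbError, ValueError):
    """A delimited score file failed validation."""
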