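"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`TracerKinError`, so callers (and the CLI) can distinguish bad input
from genuine bugs.
"""


class TracerKinError(Exception):
    """Base class for all tracerkin errors."""


class FormatError(TracerKinError):
    """A file does not have the expected structure (missing columns, ...)."""


class ValidationError(TracerKinError):
    """Data violate a type invariant (non-positive activity, empty study, ...)."""


class DomainError(TracerKinError):
    """A scalar argument is outside the mathematical domain of an operation."""


class InsufficientDataError(TracerKinError):
    """Too few points for the requested fit."""


class NoDecayError(TracerKinError):
    """Terminal-phase slope is non-negative; no half-life is defined."""


class SelectionError(TracerKinError):
    """No window satisfies the automated selection rule; pick one manually."""


class PairingError(TracerKinError):
    """Ligand measurements without a vascular-marker counterpart."""


class ExtrapolationError(TracerKinError):
    """Requested time lies outside the sampled serum curve."""


class DegenerateDesignError(TracerKinError):
    """Regression design with zero variance in the predictor."""


class ReferenceSampleError(TracerKinError):
    """No samples at the normalization reference time."""
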