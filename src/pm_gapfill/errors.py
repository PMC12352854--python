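"""Exception hierarchy shared across the package."""


class PMGapfillError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PMGapfillError, ValueError):
    """A configuration object violates its invariants."""


class PlacementError(PMGapfillError, RuntimeError):
    """Synthetic gaps cannot be placed under the separation constraints."""


class DegenerateInputError(PMGapfillError, ValueError):
    """Too few usable values for the requested statistic."""


class InsufficientDataError(PMGapfillError, ValueError):
    """Not enough observed data to fit or apply a method at all."""


class MethodInapplicableError(PMGapfillError, RuntimeError):
    """A method cannot be applied to this particular gap (e.g. missing
    anchors); benchmarks record this as a failure, not as a zero."""


class ContractViolationError(PMGapfillError, ValueError):
    """Caller broke an interface contract (shape/length mismatch)."""
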