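"""Exception types shared across the pipeline stages."""


class SoxyprofError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SoxyprofError):
    """A parameter violates an operation's precondition."""


class InvalidInputError(SoxyprofError):
    """Malformed or inconsistent input data."""


class InfeasibleTargetError(SoxyprofError):
    """A requested sequence-identity target cannot be realised."""


class LayoutConflictError(SoxyprofError):
    """Two planted loci would overlap on the synthetic contig."""


class InvalidModelError(SoxyprofError):
    """An ecology model references an unknown label or is not a distribution."""


class DegenerateCalibrationError(SoxyprofError):
    """Decoy scores have zero variance; Gumbel fit undefined."""


class IncomparablePairError(SoxyprofError):
    """Two alignment rows share no non-gap columns (distance undefined)."""


class IncompleteInputError(SoxyprofError):
    """A hit lacks its corresponding signature call."""


class UndefinedAssociationError(SoxyprofError):
    """Association test requested with fewer than two environment labels."""


class InvalidAnnotationError(SoxyprofError):
    """Gene models contain duplicate identifiers."""
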