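"""Exception hierarchy shared across fogkit modules."""


class FogkitError(Exception):
    """Base class for all fogkit errors."""


class ContractError(FogkitError):
    """A documented precondition of an operation was violated."""


class FormatError(FogkitError):
    """An input file does not conform to the expected dialect."""


class ValidationError(FogkitError):
    """Parsed data violates a domain invariant (e.g. non-binary labels)."""


class StateError(FogkitError):
    """An object was used before reaching the required state (e.g. scoring
    with an untrained detector)."""


class UndefinedMetricError(FogkitError):
    """A metric is undefined for the given inputs (e.g. ROC with one class)."""
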