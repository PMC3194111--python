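"""Exception hierarchy for radonrisk."""


class RadonRiskError(Exception):
    """Base class for all radonrisk errors."""


class SchemaError(RadonRiskError):
    """A tabular input does not match its documented schema."""


class ValidationError(RadonRiskError):
    """A value violates a domain invariant (range, vocabulary, nesting)."""


class ConvergenceError(RadonRiskError):
    """An estimation routine failed to converge or the data are degenerate."""
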