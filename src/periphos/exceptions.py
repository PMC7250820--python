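"""Package-specific exception types."""


class DegenerateDataError(ValueError):
    """Observed data carry no usable signal (all zero / all identical)."""


class DegenerateDesignError(ValueError):
    """The experimental design cannot identify the requested quantity."""


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


class NonConvergenceError(RuntimeError):
    """An optimizer failed to converge from every starting point."""
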