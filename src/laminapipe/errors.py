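"""Exception types shared across the pipeline."""


class LaminapipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LaminapipeError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ValidationError(LaminapipeError, ValueError):
    """Input data violate a contract (bad depth, missing column, empty group...)."""
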