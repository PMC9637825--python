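"""Exception hierarchy shared across the pipeline stages."""


class CohnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CohnetError, ValueError):
    """A parameter combination that cannot define a valid analysis."""


class InputError(CohnetError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(CohnetError, ValueError):
    """Structurally valid input on which the operation is undefined
    (zero-variance segment, constant connectivity matrix, zero baseline)."""
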