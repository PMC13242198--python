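"""Exception hierarchy shared across the pipeline stages."""


class TacsAttnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TacsAttnError, ValueError):
    """Invalid generator/analysis configuration (inconsistent counts, bad rates, ...)."""


class DataError(TacsAttnError, ValueError):
    """Input data violate a structural contract (unknown labels, missing channels, ...)."""


class DomainError(TacsAttnError, ValueError):
    """A requested window/band falls outside what the data resolve."""


class InferenceError(TacsAttnError, ValueError):
    """A statistical routine was asked for an answer the design cannot give (n too small, zero area, ...)."""
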