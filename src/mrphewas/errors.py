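"""Exception hierarchy shared across the package."""


class MRPheWASError(Exception):
    """Base class for all package errors."""


class ParameterError(MRPheWASError, ValueError):
    """A function argument is outside its admissible range."""


class InputError(MRPheWASError, ValueError):
    """Malformed or inconsistent input data (tables, rsids, alleles)."""


class ConfigError(MRPheWASError, ValueError):
    """Invalid run configuration (duplicate trait names, unknown keys)."""


class EstimationError(MRPheWASError, RuntimeError):
    """A model fit failed in a way that cannot be represented in output."""


class MethodError(MRPheWASError, ValueError):
    """An estimator was called with too few variants or degenerate weights."""
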