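"""Exception hierarchy shared across the package."""


class VescaError(Exception):
    """Base class for all package errors."""


class ParameterError(VescaError, ValueError):
    """A simulation or model parameter is out of range or inconsistent."""


class ConfigurationError(VescaError, ValueError):
    """A run configuration (file, flag or field combination) is invalid."""


class DataError(VescaError, ValueError):
    """A dataset violates a structural invariant."""


class ModelError(VescaError, ValueError):
    """A model cannot be formed or fitted on the given data."""
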