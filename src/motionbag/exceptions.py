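"""Exception hierarchy shared across the package."""


class MotionBagError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MotionBagError):
    """A simulation or run configuration field is invalid."""


class InputError(MotionBagError):
    """An array/scalar argument violates the operation's domain."""


class SchemaError(MotionBagError):
    """A tabular input is malformed: missing keys, bad columns, out-of-range values."""


class FitError(MotionBagError):
    """A model fit failed (singular design, non-convergence, ...)."""
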