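"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`VsdikitError`
so callers can catch the package's failures without also swallowing plain
programming mistakes.
"""


class VsdikitError(Exception):
    """Base class for all errors raised by vsdikit."""


class ValidationError(VsdikitError, ValueError):
    """An input object violates one of its documented invariants."""


class FormatError(VsdikitError, ValueError):
    """A file on disk does not match the declared format or metadata."""


class DataQualityError(VsdikitError):
    """Input data are formally valid but unusable (e.g. too many dead pixels)."""


class StateError(VsdikitError, RuntimeError):
    """An operation was applied in the wrong order (e.g. double bleach correction)."""


class NormalizationError(VsdikitError):
    """The 20 Hz reference response needed for normalization is missing or zero."""


class FitError(VsdikitError):
    """A curve fit did not converge or its result was requested before fitting."""


class ConfigError(VsdikitError, ValueError):
    """A run configuration failed schema validation."""
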