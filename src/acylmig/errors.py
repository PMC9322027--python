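"""Exception hierarchy.

All validation problems raise :class:`ValidationError` (a ``ValueError``),
all scheme/rate-set mismatches raise :class:`ConfigurationError`, so callers
(and the CLI) can map failures to exit codes uniformly.
"""


class AcylmigError(Exception):
    """Base class for all package errors."""


class ValidationError(AcylmigError, ValueError):
    """Invalid user input: bad fractions, negative rates, malformed files."""


class ConfigurationError(AcylmigError, ValueError):
    """Scheme and rate set (or options) are mutually inconsistent."""


class UnitError(ValidationError):
    """Unrecognized rate-constant unit label."""


class NonEquilibratingError(AcylmigError):
    """The migration sub-network has no finite equilibrium composition."""
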