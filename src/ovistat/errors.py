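"""Exception hierarchy shared across the package.

Two error families matter to callers: input/validation problems
(:class:`ValidationError`, CLI exit code 2) and statistically degenerate
situations such as a monomorphic locus or a saturated distance
(:class:`DegenerateStatisticError`, CLI exit code 3).
"""


class OvistatError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OvistatError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateStatisticError(OvistatError, RuntimeError):
    """A statistic or test is undefined for the given data."""
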