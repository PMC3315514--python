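"""Exception hierarchy for coreferentiality analysis.

All validation failures are hard errors: the permutation scheme assumes
complete, finite, non-degenerate data, so silent coercion or pairwise
deletion would invalidate the null distribution.
"""


class CoreferentialityError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(CoreferentialityError, ValueError):
    """Input dimensions violate the minimum requirements (N >= 4, k >= 3)
    or do not match across inputs."""


class DegenerateDataError(CoreferentialityError, ValueError):
    """Data are numerically degenerate: zero-variance column, constant
    correlation profile, missing/non-finite values, or |r| >= 1 where a
    strict inequality is required."""


class ParameterError(CoreferentialityError, ValueError):
    """A tuning parameter is outside its valid domain."""
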