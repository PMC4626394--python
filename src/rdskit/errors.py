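"""Exception taxonomy shared across the package.

Every failure mode that callers may want to handle programmatically gets its
own class; all inherit from :class:`RDSKitError` so pipeline stages can wrap
and re-raise with stage context without losing the original type.
"""

from __future__ import annotations


class RDSKitError(Exception):
    """Base class for all rdskit errors."""


class CodeFormatError(RDSKitError, ValueError):
    """Referral code does not match the ``Lnnn-dddddddddd`` shape.

    Carries ``position``, the 0-based index of the first offending character,
    when it can be located.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class CodeStructureError(RDSKitError, ValueError):
    """Path digits violate the prefix property (a nonzero digit after a zero)."""


class DuplicateCodeError(RDSKitError, ValueError):
    """Two participant records carry the same referral code."""


class MissingParentError(RDSKitError, ValueError):
    """A non-seed code whose recruiter's code is absent from the data."""

    def __init__(self, message: str, missing_codes: list[str] | None = None):
        super().__init__(message)
        self.missing_codes = missing_codes or []


class CouponLimitError(RDSKitError, ValueError):
    """A recruiter has more recruits than the coupon allowance (five)."""


class SchemaError(RDSKitError, ValueError):
    """A delimited participant file is missing a mandatory column."""


class TraitValueError(RDSKitError, ValueError):
    """A trait column holds a value other than 0 or 1."""


class InsufficientDataError(RDSKitError, ValueError):
    """An estimator was asked to run on data that cannot support it."""


class DegenerateChainError(RDSKitError, ValueError):
    """The recruitment chain has no unique stationary distribution.

    ``absorbing_classes`` names the closed communicating classes (by group
    label) that make the chain reducible.
    """

    def __init__(self, message: str, absorbing_classes: list[list[str]] | None = None):
        super().__init__(message)
        self.absorbing_classes = absorbing_classes or []


class UndefinedRatioError(RDSKitError, ZeroDivisionError):
    """Prevalence ratio with a zero denominator."""


class UndefinedTestError(RDSKitError, ValueError):
    """Wald test requested with a zero standard error."""


class NonConvergenceError(RDSKitError, RuntimeError):
    """An iterative procedure exceeded its iteration budget."""


class ConfigError(RDSKitError, ValueError):
    """A simulation configuration is internally inconsistent or infeasible."""
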