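"""Exception hierarchy for summr.

All package-specific failures derive from :class:`SummrError` so callers can
distinguish data/configuration problems from programming errors.
"""

from __future__ import annotations


class SummrError(Exception):
    """Base class for all summr errors."""


class SchemaError(SummrError):
    """A required column is missing or the file dialect cannot be understood."""


class ValidationError(SummrError):
    """One or more input rows violate the summary-statistics invariants.

    Attributes
    ----------
    problems:
        List of ``(row, snp_id, reason)`` tuples, ``row`` being the 1-based
        data-row index (header excluded).
    """

    def __init__(self, problems, message: str | None = None):
        self.problems = list(problems)
        if message is None:
            head = "; ".join(
                f"row {r}: {snp or '<?>'}: {reason}" for r, snp, reason in self.problems[:5]
            )
            more = "" if len(self.problems) <= 5 else f" (+{len(self.problems) - 5} more)"
            message = f"{len(self.problems)} invalid row(s): {head}{more}"
        super().__init__(message)


class DomainError(SummrError, ValueError):
    """An argument is outside the mathematical domain of a formula."""


class InsufficientInstrumentsError(SummrError):
    """Fewer instruments than the estimator's minimum."""


class LDMismatchError(SummrError):
    """Variants required for clumping are missing from the LD matrix."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"{len(self.missing)} variant(s) missing from LD matrix: "
                         + ", ".join(self.missing[:10]))


class EmptyAnalysisError(SummrError):
    """An analysis stage removed every remaining instrument."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no instruments left after stage '{stage}'")


class ConfigError(SummrError):
    """Invalid analysis or simulation configuration."""
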