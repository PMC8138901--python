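"""Shared validation helpers and exception types."""

from __future__ import annotations


class ValidationError(ValueError):
    """An input object violates one of its documented invariants.

    The message always names the offending field, column, or record so the
    failure can be traced back to a concrete file or parameter.
    """


class RankDeficiencyError(ValidationError):
    """A design matrix (or one of its columns) is not of full column rank."""


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)
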