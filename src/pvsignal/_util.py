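"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as report tables conventionally do.

    Python's built-in ``round`` is banker's rounding; published
    pharmacovigilance tables round 0.05 up, so we do the same for display
    values. Internal statistics are never rounded.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class UserInputError(ValueError):
    """Invalid user-supplied data or configuration (CLI exit code 1)."""


class SchemaError(UserInputError):
    """A required table column is missing or a vocabulary is violated."""
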