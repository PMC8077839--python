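"""Small shared helpers: exact half-up rounding and error types."""

from __future__ import annotations

from fractions import Fraction


class NeutralQolError(Exception):
    """Base class for all package errors."""


class ValidationError(NeutralQolError):
    """An input violates a structural invariant."""


class ConfigError(NeutralQolError):
    """A configuration value is unknown or inconsistent."""


class EmptyInputError(NeutralQolError):
    """An aggregation was requested over an empty collection."""


def round_half_up_ratio(numerator: int, denominator: int, scale: int = 100) -> int:
    """Round ``scale * numerator / denominator`` half-up to an integer, exactly.

    Used for the integer percentages printed in report tables; computed in
    exact rational arithmetic so 54.5 -> 55 regardless of float representation.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty cell")
    frac = Fraction(scale * numerator, denominator) + Fraction(1, 2)
    return int(frac.numerator // frac.denominator)


def round_half_up(x: float) -> int:
    """Half-up rounding of a float to the nearest integer."""
    frac = Fraction(x).limit_denominator(10**9) + Fraction(1, 2)
    return int(frac.numerator // frac.denominator)
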