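"""Half-up rounded summary figures for reports.

Percentages and ratios printed in reports are rounded half-up at a stated
number of decimals, matching conventional manuscript rounding (129/155 ->
83.2%), rather than Python's banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at ``decimals`` decimal places."""
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def ratio(numerator: float, denominator: float, decimals: int = 2) -> float:
    """numerator / denominator rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    return round_half_up(numerator / denominator, decimals)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percent denominator is zero")
    return round_half_up(100.0 * numerator / denominator, decimals)


def coverage_percent(covered_bp: int, total_bp: int, decimals: int = 1) -> float:
    """Fraction of a sequence compendium covered by a feature set, as %."""
    return percent(covered_bp, total_bp, decimals)


def expected_overlap_percent(
    covered_a_bp: int,
    covered_b_bp: int,
    total_bp: int,
    decimals: int = 0,
) -> float:
    """Expected % overlap of two coverage sets under independence.

    The product of the two coverage fractions, as a percentage of the
    compendium.
    """
    if total_bp == 0:
        raise ZeroDivisionError("total_bp is zero")
    frac = (covered_a_bp / total_bp) * (covered_b_bp / total_bp)
    return round_half_up(100.0 * frac, decimals)
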