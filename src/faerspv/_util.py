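"""Small shared helpers: date parsing and percent rendering."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal


def parse_faers_date(raw: object) -> tuple[_dt.date | None, int | None]:
    """Parse a FAERS date field.

    Returns ``(date, sort_key)`` where *date* is a full-precision
    ``datetime.date`` (None for partial or missing values) and *sort_key* is
    the YYYYMMDD integer with missing month/day padded with 01 (None when the
    field is empty or unparseable).  Deduplication needs a total order, onset
    arithmetic needs day precision; the two uses get different views.
    """
    if raw is None:
        return None, None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "none"}:
        return None, None
    if not s.isdigit():
        return None, None
    if len(s) == 8:
        try:
            d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return None, None
        return d, int(s)
    if len(s) == 6:  # YYYYMM
        return None, int(s) * 100 + 1
    if len(s) == 4:  # YYYY
        return None, int(s) * 10000 + 101
    return None, None


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage with half-up rounding at *decimals* places.

    Matches the rounding convention of published FAERS summary tables
    (e.g. 631/774 -> 81.52).  Returns ``nan`` for a zero denominator.
    """
    if denominator == 0:
        return float("nan")
    raw = 100.0 * numerator / denominator
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(raw)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold(term: object) -> str:
    """Case-fold and trim a free-text term (drug name or MedDRA PT)."""
    return str(term).strip().casefold()
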