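"""Small shared helpers: fiscal years, age bands, report rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

#: Default 5-year age bands for people aged 65+, open-ended at 85.
DEFAULT_AGE_BANDS: tuple[str, ...] = ("65-69", "70-74", "75-79", "80-84", "85+")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in report tables.

    Python's built-in ``round`` is banker's rounding; report tables in this
    field round 0.05 up, so 9.85 -> 9.9 rather than 9.8.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fiscal_year(dates: pd.Series | pd.Timestamp) -> pd.Series | str:
    """Australian fiscal year label ("2005/06") for a date or date Series.

    Fiscal years run 1 July - 30 June; 2005-07-01..2006-06-30 -> "2005/06".
    """
    if isinstance(dates, pd.Timestamp):
        start = dates.year if dates.month >= 7 else dates.year - 1
        return f"{start}/{(start + 1) % 100:02d}"
    d = pd.to_datetime(dates)
    start = d.dt.year.where(d.dt.month >= 7, d.dt.year - 1)
    return start.astype(str) + "/" + ((start + 1) % 100).map("{:02d}".format)


def _band_edges(bands: tuple[str, ...]) -> list[tuple[int, float, str]]:
    out = []
    for b in bands:
        if b.endswith("+"):
            out.append((int(b[:-1]), float("inf"), b))
        else:
            lo, hi = b.split("-")
            out.append((int(lo), int(hi), b))
    return out


def age_band(ages: pd.Series, bands: tuple[str, ...] = DEFAULT_AGE_BANDS) -> pd.Series:
    """Map integer ages to band labels; ages outside all bands become NA."""
    out = pd.Series(pd.NA, index=ages.index, dtype="object")
    for lo, hi, label in _band_edges(bands):
        out = out.mask((ages >= lo) & (ages <= hi), label)
    return out
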