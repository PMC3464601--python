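"""ICD-10-AM code-range predicates used for episode extraction.

The diagnosis ranges of interest are structural string ranges of ICD-10-AM:

* falls as external cause of injury: W00-W19 (mechanism-of-injury codes);
* injury principal diagnoses: S00 through T75, plus T79 — the upper cut at
  T75/T79 excludes complications of medical and surgical care (T80-T88);
* hip fracture: S72.0-S72.2 (fractures of the femoral neck, pertrochanteric
  and subtrochanteric region); S72.3 and above are shaft and distal femur
  fractures and do not count.

Codes are compared as strings on the letter + two-digit category (and for
hip fracture the first digit after the decimal point), so "S72.01" matches
the S72.0 group. Malformed codes simply fail every predicate.
"""

from __future__ import annotations

import re

import pandas as pd

_CATEGORY_RE = re.compile(r"^([A-Z])(\d{2})")

#: Procedure codes treated as hip revision procedures (replaceable set).
REVISION_PROCEDURES: frozenset[str] = frozenset({"49324-00", "49327-00", "49330-00"})

#: Primary hip fracture repair procedures used by the synthetic generator.
PRIMARY_HIP_PROCEDURES: tuple[str, ...] = ("47519-00", "49315-00", "49318-00")


def _category(code: str) -> tuple[str, int] | None:
    if not isinstance(code, str):
        return None
    m = _CATEGORY_RE.match(code.strip().upper())
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def is_fall_mechanism(code: str) -> bool:
    """True for external-cause mechanism codes W00-W19 (falls)."""
    cat = _category(code)
    return cat is not None and cat[0] == "W" and cat[1] <= 19


def is_injury_principal(code: str) -> bool:
    """True for principal diagnoses in S00-T75 or T79."""
    cat = _category(code)
    if cat is None:
        return False
    letter, num = cat
    if letter == "S":
        return True
    if letter == "T":
        return num <= 75 or num == 79
    return False


def is_hip_fracture(code: str) -> bool:
    """True for hip fracture principal diagnoses S72.0-S72.2."""
    cat = _category(code)
    if cat is None or (cat[0], cat[1]) != ("S", 72):
        return False
    rest = code.strip().upper()[3:]
    if not rest.startswith("."):
        return False
    return len(rest) > 1 and rest[1] in "012"


def series_predicate(codes: pd.Series, predicate) -> pd.Series:
    """Vectorised wrapper; non-string / malformed entries map to False."""
    return codes.map(lambda c: predicate(c) if isinstance(c, str) else False)
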