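"""Time/length unit helpers.

All internal quantities are SI (seconds, meters, m**2).  Calendar words are
given a fixed convention so that user-facing durations are unambiguous:
1 month = 30.4375 days and 1 year = 365.25 days.
"""

from __future__ import annotations

import re

SECOND = 1.0
MINUTE = 60.0
HOUR = 3600.0
DAY = 86400.0
MONTH = 30.4375 * DAY
YEAR = 365.25 * DAY

_TIME_UNITS = {
    "s": SECOND, "sec": SECOND, "second": SECOND, "seconds": SECOND,
    "min": MINUTE, "minute": MINUTE, "minutes": MINUTE,
    "h": HOUR, "hr": HOUR, "hour": HOUR, "hours": HOUR,
    "d": DAY, "day": DAY, "days": DAY,
    "month": MONTH, "months": MONTH,
    "y": YEAR, "yr": YEAR, "year": YEAR, "years": YEAR,
}

_DURATION_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*([a-zA-Z]+)\s*$")


def parse_duration(value: "float | str") -> float:
    """Convert a duration to seconds.

    Accepts a plain number (already seconds) or a string like ``"2 months"``,
    ``"30 min"``, ``"1h"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _DURATION_RE.match(value)
    if not m:
        raise ValueError(f"cannot parse duration {value!r}")
    qty, unit = float(m.group(1)), m.group(2).lower()
    if unit not in _TIME_UNITS:
        raise ValueError(f"unknown time unit {unit!r} in {value!r}")
    return qty * _TIME_UNITS[unit]
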