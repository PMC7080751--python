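"""Unit conventions: rates are stored in /week, durations in days."""

DAYS_PER_WEEK = 7.0


def per_week_to_per_day(rate_per_week: float) -> float:
    return rate_per_week / DAYS_PER_WEEK


def per_day_to_per_week(rate_per_day: float) -> float:
    return rate_per_day * DAYS_PER_WEEK
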