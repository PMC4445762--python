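"""Unit conventions.

Public interfaces speak the clinical literature's units — net invasion rate D
in mm²/year, net proliferation rate rho in 1/year — while the solver works in
mm and days, matching the cadence of clinical imaging.  Conversion happens at
the API boundary and nowhere else.
"""

DAYS_PER_YEAR = 365.25


def per_year_to_per_day(x: float) -> float:
    return x / DAYS_PER_YEAR


def per_day_to_per_year(x: float) -> float:
    return x * DAYS_PER_YEAR
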