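"""Cumulative and time-weighted-average exposure for one job history.

A career is converted to a calendar-year intensity series (overlapping
jobs average their intensities), then summed over lags and time windows
before the reference date.  The lag-1 total always splits exactly into the
1-4 window, the 5-9 window and the lag-10 remainder.
"""

from types import SimpleNamespace

from rfjem import Jem, JemEntry, yearly_series, compute_profile

jem = Jem([
    JemEntry("8253", "E", intensity=2.2, prevalence=0.21),
    JemEntry("4115", "E", intensity=0.0, prevalence=0.0),
])


def spell(start, end, code, nonstandard=False):
    return SimpleNamespace(pid="w1", start_year=start, end_year=end,
                           isco88=code, nonstandard=nonstandard,
                           source_reported=False, source_uncertain=False)


history = [
    spell(1978, 1989, "4115"),          # unexposed office work
    spell(1988, 2001, "8253"),          # exposed; overlaps 1988-89
    spell(2002, 2003, None, True),      # nonstandard period, kept as unexposed
]

series = yearly_series("w1", history, jem, method="M1", field_kind="E")
print("1988 (overlap of unexposed+exposed jobs):", series.values[1988],
      "= mean of {0.0, 2.2}")

ref_year = 2004
profile = compute_profile(series, ref_year)
for label in ("lag1", "lag5", "lag10", "win1_4", "win5_9"):
    print(f"{label:>7}: cumulative={profile.cumulative[label]:6.2f}  "
          f"years worked={profile.years_worked[label]:2d}  "
          f"TWA={profile.twa[label]:.3f}")

lhs = profile.cumulative["lag1"]
rhs = (profile.cumulative["win1_4"] + profile.cumulative["win5_9"]
       + profile.cumulative["lag10"])
print(f"\nconservation: lag1 {lhs:.2f} == win1_4 + win5_9 + lag10 {rhs:.2f}")
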