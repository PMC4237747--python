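"""Day length and its annual range as a function of latitude.

Δphotoperiod (annual max minus min day length) is the environmental
covariate of the selection scan: zero at the equator, 24 h past the polar
circle, and monotone in |latitude| in between.
"""

from photoclines import annual_photoperiod_extremes, day_length, delta_photoperiod

print("latitude  Dec-solstice  Jun-solstice  annual-min  annual-max  delta")
for lat in (0, 15, 30, 45, 60, 70):
    lo, hi = annual_photoperiod_extremes(lat)
    print(
        f"{lat:7.0f}  {day_length(lat, 355):11.2f}h {day_length(lat, 172):12.2f}h"
        f" {lo:10.2f}h {hi:10.2f}h {delta_photoperiod(lat):5.2f}h"
    )
print()
print("A population at 45N sees ~8.6h winter days and ~15.4h summer days:")
print("its delta of ~6.9h is the 'selective pressure' axis of the scan.")
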