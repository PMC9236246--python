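"""Compute the composite Air Quality Health Index from pollutant means.

The AQHI combines 24-h mean O3, NO2 and PM2.5 through exponential risk
transforms; AQHI-x is the same formula fed the daily maximum 8-h ozone
average. Here both are evaluated at the published all-months mean
concentrations of the Toronto 2004-2015 study period.
"""

from casecross import compute_aqhi
from casecross.datasets import POLLUTANT_MEANS
from casecross.exposure import aqhi_presentation_scale

o3, no2, pm25 = (POLLUTANT_MEANS[k] for k in ("O3", "NO2", "PM2.5"))
aqhi = compute_aqhi(o3, no2, pm25)
aqhi_x = compute_aqhi(POLLUTANT_MEANS["O3H8"], no2, pm25)

print(f"inputs: O3 {o3} ppb (24-h mean), NO2 {no2} ppb, PM2.5 {pm25} ug/m3")
print(f"AQHI   (continuous) = {aqhi:.4f}  -> public scale {aqhi_presentation_scale(aqhi):.0f}")
print(f"AQHI-x (O3 as 8-h max, {POLLUTANT_MEANS['O3H8']} ppb) = {aqhi_x:.4f}")
print("The continuous values enter the regression models; the public scale")
print("(1-10+) is presentation only. At these mean conditions air quality")
print("sits in the low-risk band.")
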