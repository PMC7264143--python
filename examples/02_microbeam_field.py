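"""Build an ideal microbeam comb, measure its PVDR, calibrate the scan.

The array is 50 um beamlets at 400 um pitch. The peak-to-valley dose
ratio (PVDR) is measured across the 5 central beamlets the way a
strip dosimeter traverse would be analysed, and the vertical scan speed
needed to deliver a valley prescription is computed from the intrinsic
dose rate of the 0.5 mm high dynamic field.
"""

from mrtplan import ArraySpec, calibrate_scan_speed, comb_profile, measure_pvdr
from mrtplan.microbeam import DeliverySpec

spec = ArraySpec(width_um=50, pitch_um=400, field_width_mm=8, field_height_mm=8)
profile = comb_profile(spec, peak_gy=40.0, valley_gy=5.0)
pvdr, sd = measure_pvdr(profile, spec)
print(f"beamlet area fraction f_peak = {spec.f_peak:.3f}")
print(f"PVDR of the ideal 40/5 comb  = {pvdr:.1f} +/- {sd:.1f}")

smoothed = ArraySpec(penumbra_um=5.0)
pvdr_pen, _ = measure_pvdr(comb_profile(smoothed, 40.0, 5.0), smoothed)
print(f"with a 5 um Gaussian penumbra = {pvdr_pen:.2f}")

delivery = DeliverySpec(peak_rate_gy_s=40.0, valley_rate_gy_s=5.0,
                        field_height_mm=0.5)
speed = calibrate_scan_speed(delivery, prescription_gy=5.0, component="valley")
print(f"scan speed for a 5 Gy valley  = {speed:.2f} mm/s")
# The ideal comb reproduces the geometric peak/valley ratio exactly;
# penumbra smoothing lowers the measured PVDR only marginally because
# the valley is sampled near-midway between beamlets.
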