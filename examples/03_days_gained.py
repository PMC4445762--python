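"""Score treatment response with Days Gained.

The untreated virtual control (UVC) extrapolates a patient's pre-treatment
growth.  Days Gained is the time-axis distance from the UVC back to the
post-treatment scan: how many days of untreated growth the therapy erased."""

from gliomapi import (Kinetics, RadiusObservation, build_uvc,
                      classify_response, days_gained)

kin = Kinetics(D=40.0, rho=10.0, K=1e5)      # v = 40 mm/yr
anchor = RadiusObservation(0.0, "T1Gd", 20.0)  # last pre-treatment scan
uvc = build_uvc(kin, anchor, horizon=365.0, mode="linear")

for radius in (20.0, 25.0, uvc.radius_at(91.0), 32.0):
    post = RadiusObservation(91.0, "T1Gd", radius)
    score = days_gained(uvc, post)
    call = classify_response(score, cutoff=60.0)
    print(f"  post-treatment radius {radius:5.2f} mm at day 91 -> "
          f"Days Gained {score.dg:7.1f} d  ({call})")

print("\n20 mm (no growth in 91 d) gains all 91 days; a scan on the UVC "
      "curve gains 0; a radius beyond it is hyper-progression (negative).")
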