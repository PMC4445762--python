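"""Radiosensitive vs radioresistant patients under the standard 60 Gy course.

Couples the growth model to linear-quadratic cell kill (PIRT).  The two
radiosensitivities contrast a responder (alpha = 0.340 /Gy) with a
non-responder (alpha = 0.016 /Gy) on the same virtual patient."""

from gliomapi import (Kinetics, RadiusObservation, SolverSettings, build_uvc,
                      days_gained, extract_radius, front_profile,
                      simulate_pirt, standard_plan, surviving_fraction)

kin = Kinetics(D=15.0, rho=8.0, K=1e5)
settings = SolverSettings.auto(kin, r_max=60.0)
lesion = front_profile(kin, settings, radius=15.0)
uvc = build_uvc(kin, RadiusObservation(0.0, "T1Gd", 15.0), 365.0,
                settings=settings)

scan_day = 120.0  # ~11 weeks after the 6-week course ends
for alpha in (0.340, 0.016):
    s = surviving_fraction(alpha, 10.0, 2.0)
    plan = standard_plan(alpha)  # 30 x 2 Gy weekday fractions over 6 weeks
    snap = simulate_pirt(kin, lesion, plan, scan_day, settings)[-1]
    radius = extract_radius(snap, 0.80)
    dg = days_gained(uvc, RadiusObservation(scan_day, "T1Gd", radius))
    print(f"alpha = {alpha:5.3f} /Gy: survives {s:.1%} of cells per 2 Gy "
          f"fraction; radius 15.0 -> {radius:5.2f} mm at day {scan_day:.0f}; "
          f"Days Gained {dg.dg:5.1f} d")

print("\nThe radiosensitive tumor is still below its pre-treatment size "
      "months later (the score saturates at the full elapsed time); the "
      "radioresistant one has nearly rejoined its untreated growth curve.")
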