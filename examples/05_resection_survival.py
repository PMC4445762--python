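"""The surgical iceberg: what a gross total resection actually removes.

At the same 15 mm visible (T1Gd) lesion radius, a nodular tumor
(high rho/D) hides few cells beyond its imaging margin while a diffuse one
(low rho/D) hides most of them — so the margin needed to remove 99% of
cells, and the value of surgery, differ sharply."""

from gliomapi import (Kinetics, SolverSettings, apply_resection, extract_radius,
                      front_profile, margin_for_fraction_removed,
                      resolve_margin, time_to_fatal_radius, total_cells)

for name, (D, rho) in {"nodular": (4.0, 16.0), "diffuse": (25.0, 4.0)}.items():
    kin = Kinetics(D=D, rho=rho, K=1e5)
    st = SolverSettings.auto(kin, r_max=70.0)
    lesion = front_profile(kin, st, radius=15.0)
    gtr = resolve_margin(lesion, "GTR")
    _, removed = apply_resection(lesion, gtr)
    frac = removed / total_cells(lesion)
    margin99 = margin_for_fraction_removed(lesion, 0.99)
    surr = time_to_fatal_radius(kin, lesion, settings=st, resection=gtr)
    print(f"{name:8s} (rho/D = {kin.rho_over_D:5.2f} /mm²): GTR removes "
          f"{frac:5.1%} of cells; 99% margin = {margin99:5.1f} mm vs GTR "
          f"margin {gtr.margin_radius:.1f} mm; time to 35 mm fatal size "
          f"{surr.time_to_fatal:6.0f} d")

print("\nFor the nodular tumor the 99% margin nearly coincides with the "
      "visible lesion; for the diffuse one it lies far outside — surgery "
      "leaves the invading tail either way, which is why the model predicts "
      "recurrence regardless of extent.")
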