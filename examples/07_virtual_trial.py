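"""A two-arm virtual trial: radiosensitive vs radioresistant radiotherapy.

Samples a seeded cohort of virtual patients, treats every patient under
both arms (matched design), scores Days Gained against each patient's own
untreated virtual control, follows everyone to a 35 mm fatal radius, and
reports Kaplan-Meier curves per arm."""

from gliomapi import CohortSpec, TherapyArm, run_virtual_trial, standard_plan
from gliomapi.cohort import logrank_p_value

spec = CohortSpec(seed=11, n=8)
arms = [TherapyArm("radiosensitive", radiation=standard_plan(0.340)),
        TherapyArm("radioresistant", radiation=standard_plan(0.016))]
result = run_virtual_trial(spec, arms, horizon=2500.0)

table = result["patients"]
print(table[["patient_id", "arm", "rho_over_D_per_mm2", "days_gained",
             "time_to_fatal_days"]].round(2).to_string(index=False))

print("\nmedian Days Gained by arm:")
print(table.groupby("arm")["days_gained"].median().round(1).to_string())

a = table[table.arm == "radiosensitive"]
b = table[table.arm == "radioresistant"]
p = logrank_p_value(a.time_to_fatal_days, ~a.censored,
                    b.time_to_fatal_days, ~b.censored)
print(f"\nlog-rank p (sensitive vs resistant survival surrogate): {p:.3f}")
print("higher radiosensitivity -> larger Days Gained and longer time to "
      "fatal size on the same patients.")
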