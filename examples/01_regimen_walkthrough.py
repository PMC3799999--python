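"""Trace one episode's pharmacy fills through the regimen engine.

A patient starts drug A, augments with drug B six weeks later, drops B
(step-down), and eventually stops therapy. The engine turns the fills
into validity intervals, segments regimens under the 30-day lock / 60-day
grace rules, numbers the lines of therapy, and assesses failures.
"""

from trd_episodes.regimens import (
    DrugExposure,
    derive_lots,
    segment_regimens,
    validity_intervals,
)
from trd_episodes.trd import assess_failures

# (day, days_supply) fills within an episode spanning days 0..300
fills_a = [(0, 30), (30, 30), (60, 30)]
fills_b = [(45, 30)]

exposures = [
    DrugExposure("drug_A", validity_intervals(fills_a)),
    DrugExposure("drug_B", validity_intervals(fills_b)),
]
print("validity intervals:")
for exp in exposures:
    print(f"  {exp.drug_id}: {exp.intervals}")

regimens = segment_regimens(exposures, ep_start=0, ep_end=300)
print("\nregimens (a blank regimen means no ADAP drug is valid):")
for r in regimens:
    kind = "blank" if r.is_blank else ("step-down" if r.is_step_down_of_prev
                                       else "therapy")
    print(f"  [{r.start:3d}, {r.end:3d})  {sorted(r.drug_set) or '-'}  {kind}")

lots = derive_lots(regimens)
print(f"\nlines of therapy: {[(l.lot_number, sorted(l.drug_set)) for l in lots]}")

a = assess_failures(regimens)
print(f"failed regimens: {[r.failed for r in regimens]}")
print(f"distinct failed compositions: {len(a.distinct_failed_compositions)}"
      f" -> TRD: {a.trd}")
print("\nThe augmentation {A,B} is exempt (its step-down shows intent to"
      "\nsimplify, not failure) and the final regimen is exempt as last,"
      "\nso only {A} fails once: three lines of therapy but not TRD.")
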