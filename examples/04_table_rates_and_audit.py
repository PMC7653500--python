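"""Recompute the reference table's pregnancy rates and the cohort audit.

The bundled fixture stores the published per-interval sample counts;
every printed rate cell is reproduced from raw counts (half-up, two
decimals), and the record-exclusion arithmetic recovers the included
cohort size.
"""

import fertigrade as fg

system = fg.reference_system()
rows = fg.compute_interval_rates(fg.REFERENCE_TABLE_COUNTS, system)
print(fg.rates_frame(rows).to_string(index=False))

audit = fg.exclusion_audit(fg.REFERENCE_INITIAL_RECORDS, fg.REFERENCE_EXCLUSIONS)
print(f"\ninitial records: {audit.initial}")
for label, count in audit.exclusions:
    print(f"  excluded {count:>6}  {label}")
print(f"included records: {audit.remaining}")

ratio = fg.REFERENCE_NONPREGNANT / fg.REFERENCE_PREGNANT
print(f"\nnon-pregnant : pregnant = {ratio:.2f} : 1")
print("\nNote: the BMI '<13.0' interval has zero records, so its rate is")
print("undefined (None), never reported as 0.")
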