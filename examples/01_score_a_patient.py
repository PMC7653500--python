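"""Score individual patient records with the bundled reference system.

Each of the seven indicators is mapped to a category (A normal ... D
extremely abnormal) and its 4..1 points; the total is the weighted mean
of the points, so it always lies on the 1-4 scale.  A total at or below
2.38 is grade E (poor likelihood of pregnancy); a total above 3.84 is
grade A.  The two intermediate grade boundaries were never published,
so mid-range totals come back without a grade unless you refit the
thresholds on a cohort (see example 02).
"""

import fertigrade as fg

system = fg.reference_system()

patients = {
    "young, good reserve": dict(
        age=29, bmi=21.5, fsh=6.2, afc=16, amh=3.4, oocytes=12, emt=11.8
    ),
    "age 36, mid-range AMH": dict(
        age=36, bmi=23.0, fsh=7.9, afc=12, amh=2.1, oocytes=9, emt=10.2
    ),
    "diminished reserve": dict(
        age=42, bmi=19.0, fsh=18.0, afc=2, amh=0.3, oocytes=2, emt=6.0
    ),
}

for name, record in patients.items():
    scored = fg.score_record(record, system)
    cats = " ".join(f"{k}:{v}{scored.points[k]}" for k, v in scored.categories.items())
    grade = scored.grade or "(mid-band: thresholds unpublished)"
    print(f"{name:28s} total={scored.total:.4f} grade={grade}")
    print(f"  {cats}")

print()
print("A higher total means fewer/milder abnormal indicators; the worst")
print("patient above sits in grade E, i.e. total <= 2.38.")
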