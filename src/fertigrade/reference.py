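"""Bundled reference fixture: the published fitted grading system.

This module encodes, as data, the fitted system reported for a
60 648-record single-hospital IVF fresh-embryo-transfer cohort: the
seven indicators with their interval divisions, category letters,
points, per-interval sample counts and pregnancy counts, the
random-forest weights (percent), and the published grade endpoints
(worst grade at total <= 2.38, best grade at total > 3.84; the two
intermediate thresholds were not published and are stored as
placeholders).

Two printed rows pair letters and points inconsistently with the
stated letter/point convention (the AMH rows and the endometrial-
thickness rows); this fixture assigns categories by observed
pregnancy-rate rank, which reproduces every self-consistent row and is
the documented deviation for those two indicators.  Printed interval
labels such as "11-15" are the display form of half-open intervals with
.5 midpoint cuts for count-valued indicators.

Note the per-indicator totals below sum to 60 647, one less than the
stated cohort size — an inconsistency of the published table itself,
kept verbatim here.
"""

from __future__ import annotations

from .discretize import DiscretizationScheme, who_bmi_scheme
from .system import GradeScheme, ScoringSystem
from .weights import WeightVector

#: Initial record count and labelled exclusions of the source cohort.
REFERENCE_INITIAL_RECORDS = 95_868
REFERENCE_EXCLUSIONS: dict[str, int] = {
    "frozen embryo transfer": 29_185,
    "resuscitation": 5_843,
    "egg donation": 120,
    "double uterus (fresh transfer)": 72,
}
#: Stated included-record count.
REFERENCE_INCLUDED_RECORDS = 60_648
#: Pregnant / non-pregnant group sizes of the included records.
REFERENCE_PREGNANT = 15_021
REFERENCE_NONPREGNANT = 45_627

#: Published weights in percent, in table order.
REFERENCE_WEIGHTS_PCT: dict[str, float] = {
    "age": 17.48,
    "fsh": 5.81,
    "afc": 12.14,
    "amh": 16.16,
    "bmi": 7.85,
    "oocytes": 23.07,
    "emt": 17.49,
}

#: Per-indicator interval rows: (label, total, pregnant), interval order.
REFERENCE_TABLE_COUNTS: dict[str, list[tuple[str, int, int]]] = {
    "age": [
        ("<35", 44_523, 12_698),
        ("35-37", 7_246, 1_588),
        ("38-40", 4_635, 615),
        (">40", 4_243, 119),
    ],
    "fsh": [
        ("<=10", 53_973, 14_015),
        ("11-15", 5_157, 903),
        ("16-25", 1_250, 94),
        (">25", 267, 8),
    ],
    "afc": [
        ("<3", 1_610, 66),
        ("3-6", 8_014, 873),
        ("7-10", 9_598, 2_199),
        (">=11", 41_425, 11_882),
    ],
    "amh": [
        ("<=0.50", 1_272, 46),
        ("0.51-1.27", 2_439, 344),
        ("1.28-5.18", 49_398, 11_660),
        (">5.18", 7_538, 2_970),
    ],
    "bmi": [
        ("<13.0", 0, 0),
        ("13.0-14.9", 21, 5),
        ("15.0-18.4", 2_962, 951),
        ("18.5-24.9", 53_348, 12_664),
        ("25.0-34.9", 4_296, 1_395),
        ("35.0-39.9", 16, 2),
        (">=40.0", 4, 3),
    ],
    "oocytes": [
        ("<=2", 5_176, 233),
        ("3-5", 8_269, 1_468),
        ("6-10", 16_355, 4_794),
        ("11-15", 14_796, 5_009),
        ("16-30", 15_063, 3_488),
        ("31-45", 946, 27),
        (">45", 42, 1),
    ],
    "emt": [
        ("<=6", 1_766, 50),
        ("7-8", 5_074, 491),
        ("9-11", 18_947, 4_063),
        (">=11", 34_860, 10_416),
    ],
}

#: Published grade endpoints on the 1-4 total-score scale.
REFERENCE_GRADE_LOW = 2.38  # total <= 2.38 -> grade E
REFERENCE_GRADE_HIGH = 3.84  # total > 3.84 -> grade A


def _scheme(indicator, cuts, points, categories, orientation, labels):
    return DiscretizationScheme(
        indicator=indicator,
        cuts=cuts,
        points=points,
        categories=categories,
        orientation=orientation,
        labels=labels,
    )


def reference_schemes() -> tuple[DiscretizationScheme, ...]:
    """The seven fitted interval schemes, in table order."""
    return (
        _scheme("age", (35.0, 38.0, 41.0), (4, 3, 2, 1), ("A", "B", "C", "D"),
                "monotone_decreasing",
                ("<35", "35-37", "38-40", ">40")),
        _scheme("fsh", (10.5, 15.5, 25.5), (4, 3, 2, 1), ("A", "B", "C", "D"),
                "monotone_decreasing",
                ("<=10", "11-15", "16-25", ">25")),
        _scheme("afc", (2.5, 6.5, 10.5), (1, 2, 3, 4), ("D", "C", "B", "A"),
                "monotone_increasing",
                ("<3", "3-6", "7-10", ">=11")),
        # AMH categories follow the rate ranking (rate rises with AMH),
        # not the printed letters.
        _scheme("amh", (0.505, 1.275, 5.185), (1, 2, 3, 4), ("D", "C", "B", "A"),
                "monotone_increasing",
                ("<=0.50", "0.51-1.27", "1.28-5.18", ">5.18")),
        who_bmi_scheme(),
        _scheme("oocytes", (2.5, 5.5, 10.5, 15.5, 30.5, 45.5),
                (1, 2, 3, 4, 3, 2, 1), ("D", "C", "B", "A", "B", "C", "D"),
                "medium",
                ("<=2", "3-5", "6-10", "11-15", "16-30", "31-45", ">45")),
        # Endometrial thickness: printed letters run A..D against points
        # 1..4; categories here follow the points/rate convention.
        _scheme("emt", (6.5, 8.5, 11.0), (1, 2, 3, 4), ("D", "C", "B", "A"),
                "monotone_increasing",
                ("<=6", "7-8", "9-11", ">=11")),
    )


def reference_weights() -> WeightVector:
    """Published weights normalized from percent (they sum to 100.00)."""
    names = tuple(s.indicator for s in reference_schemes())
    pct = [REFERENCE_WEIGHTS_PCT[n] for n in names]
    total = sum(pct)
    return WeightVector(
        names,
        tuple(p / total for p in pct),
        {"source": "published reference table", "unit": "percent/100"},
    )


def reference_grades() -> GradeScheme:
    """Five grades with the two published endpoint thresholds.

    The intermediate thresholds were not published; they are ``None``
    placeholders, so only grade E (total <= 2.38) and grade A
    (total > 3.84) can be resolved from this fixture.
    """
    return GradeScheme(
        (REFERENCE_GRADE_LOW, None, None, REFERENCE_GRADE_HIGH),
        ("A", "B", "C", "D", "E"),
    )


def reference_system() -> ScoringSystem:
    """The bundled reference scoring system."""
    return ScoringSystem(
        schemes=reference_schemes(),
        weights=reference_weights(),
        grades=reference_grades(),
        metadata={
            "source": "published reference system",
            "cohort_size": REFERENCE_INCLUDED_RECORDS,
            "note": (
                "intermediate grade thresholds unpublished; AMH and "
                "endometrial-thickness categories follow rate ranking"
            ),
        },
    )
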