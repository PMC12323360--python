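"""Age binning and the reported cohort demographics used for calibration.

The simulator draws age and gender frequencies from the published
demographic composition of the two source cohorts (a commercial
customer database of 5,372 profiles and a public cross-sectional
collection of 2,067 participants). The printed counts and percentages
are carried here verbatim so that the percentage arithmetic can be
recomputed and audited; note that a few published rows are internally
inconsistent with their own totals (see ``is_consistent``).
"""

from __future__ import annotations

from dataclasses import dataclass

#: (label, low, high) with high=None for the open-ended top bin.
AGE_BINS = (
    ("0-10", 0, 10),
    ("11-20", 11, 20),
    ("21-30", 21, 30),
    ("31-40", 31, 40),
    ("41-50", 41, 50),
    ("51-60", 51, 60),
    ("61-70", 61, 70),
    ("71-80", 71, 80),
    ("81+", 81, None),
)

AGE_BIN_LABELS = tuple(label for label, _, _ in AGE_BINS)


def age_to_bin(age: float | None) -> str | None:
    """Map an age in years to its decade bin label, or None."""
    if age is None or age < 0:
        return None
    for label, low, high in AGE_BINS:
        if high is None or age <= high:
            return label
    return None  # pragma: no cover


@dataclass(frozen=True)
class DemographicRow:
    dataset: str
    variable: str
    count: int
    printed_percent: float

    def recomputed_percent(self, total: int) -> float:
        return 100.0 * self.count / total

    def is_consistent(self, total: int) -> bool:
        """Whether the printed percentage equals count/total at the
        printed one-decimal precision (half-unit tolerance)."""
        return abs(self.recomputed_percent(total) - self.printed_percent) <= 0.05


COMMERCIAL_TOTAL = 5372
PUBLIC_TOTAL = 2067

#: Reported demographics, as printed. The commercial gender rows
#: "female" and "not stated" and the public "gender not stated" row do
#: not reproduce from their counts and totals.
DEMOGRAPHICS: tuple[DemographicRow, ...] = (
    DemographicRow("commercial", "gender male", 1979, 36.8),
    DemographicRow("commercial", "gender female", 2673, 49.7),
    DemographicRow("commercial", "gender not stated", 1112, 20.6),
    DemographicRow("commercial", "age 0-10", 602, 11.2),
    DemographicRow("commercial", "age 11-20", 331, 6.2),
    DemographicRow("commercial", "age 21-30", 640, 11.9),
    DemographicRow("commercial", "age 31-40", 1213, 22.6),
    DemographicRow("commercial", "age 41-50", 1045, 19.5),
    DemographicRow("commercial", "age 51-60", 846, 15.7),
    DemographicRow("commercial", "age 61-70", 476, 8.9),
    DemographicRow("commercial", "age 71-80", 189, 3.5),
    DemographicRow("commercial", "age 81+", 30, 0.6),
    DemographicRow("commercial", "country US", 4909, 91.4),
    DemographicRow("commercial", "country UK", 162, 3.0),
    DemographicRow("commercial", "country other", 301, 5.6),
    DemographicRow("public", "gender male", 1075, 52.0),
    DemographicRow("public", "gender female", 441, 21.3),
    DemographicRow("public", "gender not stated", 551, 13.5),
    DemographicRow("public", "age 0-10", 203, 9.8),
    DemographicRow("public", "age 11-20", 425, 20.6),
    DemographicRow("public", "age 21-30", 287, 13.9),
    DemographicRow("public", "age 31-40", 558, 27.0),
    DemographicRow("public", "age 41-50", 10, 0.5),
    DemographicRow("public", "age 51-60", 51, 2.5),
    DemographicRow("public", "age 61-70", 63, 3.0),
    DemographicRow("public", "age 71-80", 16, 0.8),
)

TOTALS = {"commercial": COMMERCIAL_TOTAL, "public": PUBLIC_TOTAL}


def commercial_age_counts() -> dict[str, int]:
    return {
        row.variable.removeprefix("age "): row.count
        for row in DEMOGRAPHICS
        if row.dataset == "commercial" and row.variable.startswith("age ")
    }


def commercial_gender_counts() -> dict[str, int]:
    return {
        row.variable.removeprefix("gender ").replace("not stated", "unknown"): row.count
        for row in DEMOGRAPHICS
        if row.dataset == "commercial" and row.variable.startswith("gender ")
    }
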