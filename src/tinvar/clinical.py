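"""Phenotype subgroup selection and clinical feature comparisons.

Subgroups: chronic/bothersome tinnitus is TFI >= 48 ("tinnitus is a big
problem"); the severe subgroup is THI >= 58. Comorbidity frequencies are
compared with a 2x2 Pearson chi-squared (no continuity correction), with
a Fisher exact fallback, recorded in the output, whenever any expected
cell falls below 5. Continuous features use the Welch two-sample t test
with a Shapiro-Wilk normality check recorded per group.

Note: a comparison of a severe subset against its full superset cohort
(as clinical tables of this design are often printed) is not a comparison
of independent groups; :func:`compare_categorical` flags this when asked.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .burden import chi2_2x2
from .errors import ValidationError
from .io import ClinicalRecord


def select_chronic(records: Sequence[ClinicalRecord], tfi_min: float = 48
                   ) -> list[ClinicalRecord]:
    """Subjects with chronic bothersome tinnitus: TFI >= tfi_min.

    Every non-missing duration category in the fixed vocabulary already
    encodes a duration beyond 6 months; records with missing duration are
    retained (duration was a recruitment criterion, not a data filter).
    """
    return [r for r in records if r.tfi >= tfi_min]


def select_severe(records: Sequence[ClinicalRecord], thi_min: float = 58
                  ) -> list[ClinicalRecord]:
    """The severe subgroup: THI >= thi_min (inclusive)."""
    return [r for r in records if r.thi >= thi_min]


def display_percent(count: int, total: int) -> int:
    """Whole-percent display convention: round(100 * count / total)."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return int(round(100 * count / total))


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    test: str           # "chi2" | "fisher" | "welch-t"
    statistic: float
    p_value: float
    note: str = ""

    @property
    def percent_a(self) -> int:
        return display_percent(self.count_a, self.total_a)

    @property
    def percent_b(self) -> int:
        return display_percent(self.count_b, self.total_b)


def compare_categorical(feature: str, group_a: Sequence[ClinicalRecord],
                        group_b: Sequence[ClinicalRecord],
                        non_independent: bool = False) -> GroupComparison:
    """Compare a boolean comorbidity flag between two groups.

    Falls back from chi-squared to Fisher's exact test when any expected
    cell is below 5, recording which test produced the p-value.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    ca = sum(bool(getattr(r, feature)) for r in group_a)
    cb = sum(bool(getattr(r, feature)) for r in group_b)
    na, nb = len(group_a), len(group_b)
    table = np.array([[ca, na - ca], [cb, nb - cb]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        test, statistic = "fisher", float("nan")
    else:
        statistic, p = chi2_2x2(*table.ravel())
        test = "chi2"
    note = "groups are not independent (subset vs superset)" if non_independent else ""
    return GroupComparison(feature=feature, count_a=ca, total_a=na,
                           count_b=cb, total_b=nb, test=test,
                           statistic=statistic, p_value=float(p), note=note)


def compare_continuous(feature: str, group_a: Sequence[ClinicalRecord],
                       group_b: Sequence[ClinicalRecord]) -> GroupComparison:
    """Welch two-sample t test on a numeric feature, with normality checks.

    Shapiro-Wilk p-values per group are recorded in the note; a
    zero-variance group is a validation error rather than a silent NaN.
    """
    xa = np.array([float(getattr(r, feature)) for r in group_a])
    xb = np.array([float(getattr(r, feature)) for r in group_b])
    for name, x in (("a", xa), ("b", xb)):
        if len(x) < 3:
            raise ValidationError(f"group {name} needs >= 3 observations, has {len(x)}")
        if np.ptp(x) == 0:
            raise ValidationError(f"group {name} has zero variance in {feature!r}")
    sw_a = stats.shapiro(xa).pvalue
    sw_b = stats.shapiro(xb).pvalue
    if np.array_equal(np.sort(xa), np.sort(xb)):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return GroupComparison(
        feature=feature, count_a=len(xa), total_a=len(xa),
        count_b=len(xb), total_b=len(xb), test="welch-t",
        statistic=float(t), p_value=float(p),
        note=f"shapiro_p_a={sw_a:.3g}, shapiro_p_b={sw_b:.3g}",
    )
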