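"""Classification accuracy of sex estimates against recorded sex.

An estimate is correct iff its label equals the recorded sex. Missing
and indeterminate estimates are never correct but stay in the
denominator — an observer who could not score a cranium has not
classified it correctly, and the published per-observer percentages
follow this convention. Per-sex percentages use the per-sex
denominators (10 male, 10 female crania in the study).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

from .dataset import RecordedSexTable, ScoreTable, Sex
from .discriminant import DiscriminantSpec, EstimateLabel, SexEstimate, WALKER_EQ2, estimate_table

__all__ = ["ClassificationSummary", "AccuracyReport", "percent_correct", "accuracy_report"]


@dataclass(frozen=True)
class ClassificationSummary:
    """Correct/incorrect/missing counts for one observer (or pooled)."""

    observer: str
    n_crania: int
    n_correct: int
    n_incorrect: int
    n_missing: int
    n_male: int
    n_male_correct: int
    n_female: int
    n_female_correct: int
    # (recorded sex, estimated label) -> count; includes missing/indeterminate columns
    confusion: Mapping[tuple[str, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        assert self.n_correct + self.n_incorrect + self.n_missing == self.n_crania

    @property
    def fraction_correct(self) -> float:
        return self.n_correct / self.n_crania if self.n_crania else float("nan")

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.fraction_correct

    @property
    def male_percent_correct(self) -> float:
        return 100.0 * self.n_male_correct / self.n_male if self.n_male else float("nan")

    @property
    def female_percent_correct(self) -> float:
        return (
            100.0 * self.n_female_correct / self.n_female if self.n_female else float("nan")
        )


def percent_correct(
    estimates: Mapping[object, SexEstimate],
    recorded: RecordedSexTable,
    observer: str = "",
) -> ClassificationSummary:
    """Summarise one observer's estimates (cranium -> estimate) against truth.

    Every estimated cranium must have a recorded sex; an unknown cranium
    raises a lookup error.
    """
    confusion: Counter = Counter()
    n_correct = n_missing = 0
    per_sex_total = Counter()
    per_sex_correct = Counter()
    for cranium, estimate in estimates.items():
        truth = recorded[cranium]
        confusion[(truth.value, estimate.label.value)] += 1
        per_sex_total[truth] += 1
        if estimate.label in (EstimateLabel.MISSING, EstimateLabel.INDETERMINATE):
            n_missing += 1
        elif estimate.label.value == truth.value:
            n_correct += 1
            per_sex_correct[truth] += 1
    n_crania = len(estimates)
    return ClassificationSummary(
        observer=observer,
        n_crania=n_crania,
        n_correct=n_correct,
        n_incorrect=n_crania - n_correct - n_missing,
        n_missing=n_missing,
        n_male=per_sex_total[Sex.MALE],
        n_male_correct=per_sex_correct[Sex.MALE],
        n_female=per_sex_total[Sex.FEMALE],
        n_female_correct=per_sex_correct[Sex.FEMALE],
        confusion=dict(confusion),
    )


@dataclass(frozen=True)
class AccuracyReport:
    """Per-observer classification summaries plus a pooled summary."""

    per_observer: Mapping[str, ClassificationSummary]
    pooled: ClassificationSummary

    def to_frame(self) -> pd.DataFrame:
        rows = [*self.per_observer.values(), self.pooled]
        return pd.DataFrame(
            {
                "observer": [s.observer for s in rows],
                "n_crania": [s.n_crania for s in rows],
                "n_correct": [s.n_correct for s in rows],
                "n_incorrect": [s.n_incorrect for s in rows],
                "n_missing": [s.n_missing for s in rows],
                "percent_correct": [round(s.percent_correct, 1) for s in rows],
                "male_percent_correct": [round(s.male_percent_correct, 1) for s in rows],
                "female_percent_correct": [
                    round(s.female_percent_correct, 1) for s in rows
                ],
            }
        )


def accuracy_report(
    table: ScoreTable,
    recorded: RecordedSexTable,
    spec: DiscriminantSpec = WALKER_EQ2,
) -> AccuracyReport:
    """Estimate every cell of the table and score each observer against truth.

    The pooled summary aggregates counts over observers (its denominator
    is observers x crania).
    """
    estimates = estimate_table(table, spec)
    per_observer = {}
    for observer in table.observers:
        own = {c: estimates[(observer, c)] for c in table.crania}
        per_observer[observer] = percent_correct(own, recorded, observer=observer)
    pooled = _pool(per_observer.values())
    return AccuracyReport(per_observer=per_observer, pooled=pooled)


def _pool(summaries) -> ClassificationSummary:
    summaries = list(summaries)
    confusion: Counter = Counter()
    for s in summaries:
        confusion.update(s.confusion)
    return ClassificationSummary(
        observer="pooled",
        n_crania=sum(s.n_crania for s in summaries),
        n_correct=sum(s.n_correct for s in summaries),
        n_incorrect=sum(s.n_incorrect for s in summaries),
        n_missing=sum(s.n_missing for s in summaries),
        n_male=sum(s.n_male for s in summaries),
        n_male_correct=sum(s.n_male_correct for s in summaries),
        n_female=sum(s.n_female for s in summaries),
        n_female_correct=sum(s.n_female_correct for s in summaries),
        confusion=dict(confusion),
    )
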