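"""Logistic discriminant sex estimation from cranial trait scores.

The shipped discriminant is Walker's equation 2, the two-trait function
for fragmentary crania::

    Y = glabella * (-1.568) + mastoid * (-1.459) + 7.434

Negative Y estimates male, positive female, with the cut-off at zero.
Both coefficients are negative because robusticity scores run 1
(gracile, typically female) to 5 (robust, typically male).

The probability attached to an estimate is the logistic transform of
the discriminant score, p_female = 1 / (1 + exp(-Y)); this is the
convention that reproduces the published probability columns. Displayed
percentages are rounded half-up to whole percent.

The spec of a discriminant (coefficients per trait, intercept, cut-off)
is user-configurable so other published equations can be supplied; only
equation 2 ships, the only one usable with the three traits scored here.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd
from scipy.special import expit

from .dataset import ScoreTable, Trait, VALID_SCORES
from .errors import MissingScoreError

__all__ = [
    "DiscriminantSpec",
    "WALKER_EQ2",
    "EstimateLabel",
    "SexEstimate",
    "discriminant_score",
    "sex_probabilities",
    "classify",
    "estimate_table",
    "estimates_to_frame",
    "round_half_up_percent",
]


@dataclass(frozen=True)
class DiscriminantSpec:
    """A linear discriminant on trait scores with a classification cut-off.

    ``coefficients`` maps each trait the equation uses to its weight per
    score point; traits absent from the mapping are ignored (equation 2
    has no supra-orbital term).
    """

    coefficients: Mapping[Trait, float]
    intercept: float
    cut_off: float = 0.0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    @property
    def traits(self) -> tuple[Trait, ...]:
        return tuple(self.coefficients)


WALKER_EQ2 = DiscriminantSpec(
    coefficients={Trait.GLABELLA: -1.568, Trait.MASTOID_PROCESS: -1.459},
    intercept=7.434,
    cut_off=0.0,
    name="walker_eq2",
)


class EstimateLabel(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    INDETERMINATE = "indeterminate"
    MISSING = "missing"


@dataclass(frozen=True)
class SexEstimate:
    """A sex call with its discriminant score and class probabilities.

    ``label`` is ``missing`` when a required trait score was absent; the
    numeric fields are then ``None``. ``indeterminate`` marks a score
    exactly on the cut-off.
    """

    label: EstimateLabel
    y: float | None = None
    p_male: float | None = None
    p_female: float | None = None

    @property
    def is_missing(self) -> bool:
        return self.label is EstimateLabel.MISSING


def discriminant_score(
    scores: Mapping[Trait, int | None], spec: DiscriminantSpec = WALKER_EQ2
) -> float:
    """Evaluate Y = sum(coefficient * score) + intercept.

    Raises :class:`MissingScoreError` naming the absent traits if any
    trait the spec requires is missing from ``scores`` or ``None``.
    """
    absent = [t.value for t in spec.traits if scores.get(t) is None]
    if absent:
        raise MissingScoreError(f"missing required trait score(s): {', '.join(absent)}")
    for trait in spec.traits:
        if scores[trait] not in VALID_SCORES:
            raise ValueError(f"{trait.value} score {scores[trait]!r} outside 1-5")
    return spec.intercept + sum(spec.coefficients[t] * scores[t] for t in spec.traits)


def sex_probabilities(y: float) -> tuple[float, float]:
    """(p_male, p_female) for a discriminant score: p_female = logistic(y)."""
    if not math.isfinite(y):
        raise ValueError(f"discriminant score must be finite, got {y!r}")
    p_female = float(expit(y))
    return 1.0 - p_female, p_female


def classify(
    scores: Mapping[Trait, int | None], spec: DiscriminantSpec = WALKER_EQ2
) -> SexEstimate:
    """Sex estimate for one cranium's trait scores.

    A missing required score yields ``label = missing`` (missing is a
    value here, not an error: unscored crania stay in accuracy
    denominators downstream). Otherwise male iff Y < cut-off, female iff
    Y > cut-off, indeterminate at exact equality.
    """
    try:
        y = discriminant_score(scores, spec)
    except MissingScoreError:
        return SexEstimate(EstimateLabel.MISSING)
    p_male, p_female = sex_probabilities(y)
    if y < spec.cut_off:
        label = EstimateLabel.MALE
    elif y > spec.cut_off:
        label = EstimateLabel.FEMALE
    else:
        label = EstimateLabel.INDETERMINATE
    return SexEstimate(label, y=y, p_male=p_male, p_female=p_female)


def estimate_table(
    table: ScoreTable, spec: DiscriminantSpec = WALKER_EQ2
) -> dict[tuple[str, object], SexEstimate]:
    """One :class:`SexEstimate` per (observer, cranium) pair of the table."""
    return {
        (observer, cranium): classify(table.scores_for(observer, cranium), spec)
        for observer in table.observers
        for cranium in table.crania
    }


def round_half_up_percent(probability: float) -> int:
    """Whole-percent display rounding, halves away from zero (0.955 -> 96)."""
    return int(math.floor(probability * 100.0 + 0.5))


def estimates_to_frame(estimates: Mapping[tuple[str, object], SexEstimate]) -> pd.DataFrame:
    """Export view: observer,cranium,sex,prob_male_pct,prob_female_pct,y.

    Missing estimates emit ``sex=missing`` with empty numeric fields.
    """
    rows = []
    for (observer, cranium), est in estimates.items():
        if est.is_missing:
            rows.append((observer, cranium, est.label.value, None, None, None))
        else:
            rows.append(
                (
                    observer,
                    cranium,
                    est.label.value,
                    round_half_up_percent(est.p_male),
                    round_half_up_percent(est.p_female),
                    round(est.y, 6),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["observer", "cranium", "sex", "prob_male_pct", "prob_female_pct", "y"],
    )
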