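"""Multi-rater agreement statistics.

Two chance-or-rank-based statistics cover the two kinds of data the
study produces:

* tie-corrected **Kendall's coefficient of concordance** (W) for the
  ordinal 1-5 trait scores, where a 1-vs-4 disagreement should weigh
  more than a 1-vs-2 disagreement;
* **Fleiss' kappa** for the nominal male/female sex estimates, the
  multi-rater generalisation appropriate when more than two observers
  rate the same items.

Both feed the conventional Landis-Koch verbal bands (poor / slight /
fair / moderate / substantial / almost perfect).

Formulas (m raters, n items):

W: rank each rater's n values with mid-ranks; item rank sums
``R_i``; ``S = sum_i (R_i - m(n+1)/2)^2``; per-rater tie correction
``T_j = sum over tie groups (t^3 - t)``; then
``W = 12 S / (m^2 (n^3 - n) - m sum_j T_j)``.

kappa: with ``n_ij`` raters putting item i in category j,
``P_i = (sum_j n_ij^2 - m) / (m(m-1))``; ``P_bar = mean_i P_i``;
``p_j = sum_i n_ij / (n m)``; ``P_e = sum_j p_j^2``;
``kappa = (P_bar - P_e) / (1 - P_e)``.

Rank-based W is undefined on ragged matrices, so the only missing-data
policy offered here is listwise deletion (:func:`complete_cases`).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .dataset import ScoreTable, Trait
from .discriminant import EstimateLabel, SexEstimate
from .errors import DegenerateInputError, UndefinedStatisticError

__all__ = [
    "RatingsMatrix",
    "AgreementResult",
    "midrank",
    "kendalls_w",
    "fleiss_kappa",
    "landis_koch_label",
    "complete_cases",
    "sex_label_matrix",
    "LANDIS_KOCH_BANDS",
]


@dataclass(frozen=True)
class RatingsMatrix:
    """A complete m raters x n items matrix of ratings.

    ``values`` is a list of per-rater rows (ordinal numbers for W,
    hashable category labels for kappa); completeness is enforced at
    construction, so any missing-data policy has already been applied.
    ``dropped`` records items removed by that policy, for reporting.
    """

    values: tuple[tuple[object, ...], ...]
    raters: tuple[str, ...]
    items: tuple[object, ...]
    dropped: tuple[object, ...] = ()

    def __post_init__(self):
        m, n = len(self.raters), len(self.items)
        if m < 2 or n < 2:
            raise DegenerateInputError(
                f"need at least 2 raters and 2 items, got m={m}, n={n}"
            )
        if len(self.values) != m or any(len(row) != n for row in self.values):
            raise ValueError("values must be an m x n grid")
        if any(v is None for row in self.values for v in row):
            raise ValueError("ratings matrix must be complete (no missing cells)")

    @property
    def m(self) -> int:
        return len(self.raters)

    @property
    def n(self) -> int:
        return len(self.items)

    def numeric(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class AgreementResult:
    """An agreement statistic with its intermediate components and verbal band."""

    statistic: str
    value: float
    m: int
    n: int
    label: str
    components: dict = field(default_factory=dict, repr=False)
    dropped: tuple = ()


def midrank(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks of a sequence: tied values share the mean of their span.

    Ranks always sum to n(n+1)/2.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return rankdata(values, method="average")


def _tie_correction(ranks: np.ndarray) -> float:
    """T = sum over tie groups of (t^3 - t) for one rater's ranks."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendalls_w(matrix: RatingsMatrix) -> AgreementResult:
    """Tie-corrected Kendall's coefficient of concordance.

    0 means no concordance among raters, 1 perfect concordance. Raises
    :class:`UndefinedStatisticError` when the tie correction consumes
    the whole denominator (every rater assigned a single constant
    value).
    """
    data = matrix.numeric()
    m, n = matrix.m, matrix.n
    ranks = np.vstack([midrank(row) for row in data])
    rank_sums = ranks.sum(axis=0)  # R_i per item
    deviations = rank_sums - m * (n + 1) / 2.0
    s = float(np.sum(deviations**2))
    tie_terms = np.array([_tie_correction(row) for row in ranks])
    denominator = m**2 * (n**3 - n) - m * float(tie_terms.sum())
    if denominator <= 0:
        raise UndefinedStatisticError(
            "Kendall's W is undefined: every rater gave a single constant value, "
            "so the tie correction exhausts the denominator"
        )
    w = 12.0 * s / denominator
    return AgreementResult(
        statistic="kendalls_w",
        value=w,
        m=m,
        n=n,
        label=landis_koch_label(w),
        components={
            "rank_sums": rank_sums,
            "S": s,
            "tie_terms": tie_terms,
            "denominator": denominator,
        },
        dropped=matrix.dropped,
    )


def fleiss_kappa(
    matrix: RatingsMatrix, categories: Sequence | None = None
) -> AgreementResult:
    """Fleiss' kappa for nominal ratings by m raters of n items.

    1 is perfect agreement, 0 agreement at chance level, negative worse
    than chance. Raises :class:`UndefinedStatisticError` when every
    rating falls in one category (expected agreement P_e = 1, so the
    chance correction divides by zero).
    """
    if categories is None:
        categories = sorted({v for row in matrix.values for v in row}, key=str)
    categories = list(categories)
    index = {c: j for j, c in enumerate(categories)}
    m, n = matrix.m, matrix.n
    counts = np.zeros((n, len(categories)), dtype=float)  # n_ij
    for row in matrix.values:
        for i, value in enumerate(row):
            try:
                counts[i, index[value]] += 1
            except KeyError:
                raise ValueError(f"rating {value!r} not in category set {categories}")
    per_item = (np.sum(counts**2, axis=1) - m) / (m * (m - 1))  # P_i
    p_bar = float(per_item.mean())
    proportions = counts.sum(axis=0) / (n * m)  # p_j
    p_e = float(np.sum(proportions**2))
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "Fleiss' kappa is undefined: all ratings fall in a single category, "
            "so expected agreement is 1 and the chance correction divides by zero"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return AgreementResult(
        statistic="fleiss_kappa",
        value=kappa,
        m=m,
        n=n,
        label=landis_koch_label(kappa),
        components={
            "counts": counts,
            "P_i": per_item,
            "P_bar": p_bar,
            "P_e": p_e,
            "p_j": proportions,
            "categories": categories,
        },
        dropped=matrix.dropped,
    )


# Landis-Koch strength-of-agreement bands: (upper bound, name); a value
# belongs to the first band whose upper bound it does not exceed, so the
# printed boundaries 0.20/0.40/0.60/0.80 fall in the lower-named band.
LANDIS_KOCH_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


def landis_koch_label(value: float) -> str:
    """Verbal agreement band for a kappa-type statistic in (-inf, 1]."""
    if value > 1.0:
        raise ValueError(f"agreement statistics cannot exceed 1, got {value}")
    if value < 0.0:
        return "poor"
    for upper, name in LANDIS_KOCH_BANDS[1:]:
        if value <= upper:
            return name
    raise AssertionError("unreachable")


def complete_cases(table: ScoreTable, trait: Trait | str) -> RatingsMatrix:
    """Listwise deletion: the raters x crania score matrix for one trait.

    Crania with any missing score for this trait are dropped entirely
    (and recorded in ``.dropped``), because rank-based concordance needs
    a complete matrix. Raises :class:`DegenerateInputError` when fewer
    than two complete crania remain.
    """
    trait = Trait.parse(trait) if not isinstance(trait, Trait) else trait
    kept, dropped = [], []
    for cranium in table.crania:
        if any(table.cells[(o, cranium, trait)] is None for o in table.observers):
            dropped.append(cranium)
        else:
            kept.append(cranium)
    if len(kept) < 2:
        raise DegenerateInputError(
            f"fewer than 2 crania have complete {trait.value} scores"
        )
    values = tuple(
        tuple(table.cells[(o, c, trait)] for c in kept) for o in table.observers
    )
    return RatingsMatrix(values, table.observers, tuple(kept), tuple(dropped))


def sex_label_matrix(
    estimates: dict[tuple[str, object], SexEstimate],
    extra_rater: tuple[str, dict] | None = None,
) -> RatingsMatrix:
    """Nominal ratings matrix of sex labels, for Fleiss' kappa.

    Items (crania) where any observer's estimate is missing or
    indeterminate are dropped listwise. ``extra_rater`` optionally
    appends a pseudo-rater — e.g. the recorded sexes — as
    ``(name, {cranium: label})``.
    """
    raters = sorted({obs for obs, _ in estimates})
    items = []
    seen = set()
    for _, cranium in estimates:
        if cranium not in seen:
            seen.add(cranium)
            items.append(cranium)
    kept, dropped = [], []
    for cranium in items:
        labels = [estimates[(r, cranium)].label for r in raters]
        if any(
            lab in (EstimateLabel.MISSING, EstimateLabel.INDETERMINATE) for lab in labels
        ):
            dropped.append(cranium)
        else:
            kept.append(cranium)
    values = [
        tuple(estimates[(r, c)].label.value for c in kept) for r in raters
    ]
    if extra_rater is not None:
        name, mapping = extra_rater
        values.append(tuple(_label_text(mapping[c]) for c in kept))
        raters = raters + [name]
    return RatingsMatrix(tuple(values), tuple(raters), tuple(kept), tuple(dropped))


def _label_text(value) -> str:
    return value.value if hasattr(value, "value") else str(value)
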