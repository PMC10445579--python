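# Methods

## Problem and data

Twenty crania from living adults (10 recorded male, 10 recorded female)
were scored by eight observers on three morphoscopic traits — the
mastoid process, the supra-orbital margin, and the glabella — using the
standard ordinal robusticity scale of 1 (gracile, typically female) to
5 (robust, typically male). Four direct observers (`O1`–`O4`) scored 3D
cranial models they had reconstructed themselves; four video observers
(`V1`–`V4`) scored screen recordings of `O1`'s models. One observer
(`O3`) left two cells unscored (cranium 4, mastoid and supra-orbital).
Both score grids and the recorded sexes ship as built-in fixtures
(`builtin_study_tables()`), transcribed cell-for-cell from the source
tables — including cells whose published downstream values are
internally inconsistent. Those are flagged by the reproduction report,
never silently corrected.

Missing scores are represented explicitly (`None`) rather than dropped
at parse time, so each downstream statistic applies its own documented
missing-data policy.

## Sex estimation

Walker's equation 2, the two-trait logistic discriminant suitable for
fragmentary crania:

    Y = glabella × (−1.568) + mastoid × (−1.459) + 7.434

with the cut-off at zero: `Y < 0` → male, `Y > 0` → female. A score
exactly on the cut-off is labelled *indeterminate* — no such case
occurs in the study data, and we refuse to guess a side. A missing
required trait yields the label *missing*, a value rather than an
error, because unscored crania must remain in accuracy denominators.

The source never states how its probability columns were computed; this
package adopts

    p_female = 1 / (1 + exp(−Y)),   p_male = 1 − p_female

because it reproduces the published probability pairs (e.g. Y = −1.429
→ 81/19, Y = 0.03 → 49/51) in 156 of the 159 printed cells. The three
exceptions contradict their own printed trait scores and are flagged
(see "Known discrepancies"). Displayed percentages are rounded half-up
to whole percent (0.955 → 96), matching the tables. Discriminant
coefficients, intercept and cut-off are configurable
(`DiscriminantSpec`) so other published equations can be supplied; only
equation 2 ships because only its coefficients appear in the source.

## Agreement statistics

**Tie-corrected Kendall's W** for the ordinal scores (m raters, n
items): each rater's n scores are mid-ranked (ties share the mean of
the ranks they span, via `scipy.stats.rankdata`); with item rank sums
`R_i`, `S = Σ_i (R_i − m(n+1)/2)²` and per-rater tie terms
`T_j = Σ (t³ − t)` over tie groups,

    W = 12 S / (m² (n³ − n) − m Σ_j T_j).

W is undefined (raised as `UndefinedStatisticError`) when every rater
assigns one constant value, which exhausts the denominator. The only
missing-data policy offered is listwise deletion (`complete_cases`):
rank-based concordance is not defined on ragged matrices. With m = 2
and no ties, W = (ρ + 1)/2 for Spearman's ρ — used as a closed-form
check in the tests, alongside an independently coded brute-force
evaluation of the same textbook formula.

**Fleiss' kappa** for the nominal sex labels: with `n_ij` raters
assigning item i to category j,

    P_i = (Σ_j n_ij² − m) / (m(m−1)),  P̄ = mean_i P_i,
    p_j = Σ_i n_ij / (nm),             P_e = Σ_j p_j²,
    κ = (P̄ − P_e) / (1 − P_e).

κ is undefined when all ratings fall in one category (P_e = 1). Items
with a missing or indeterminate estimate by any rater are dropped
listwise, so the direct-observer kappa uses 19 crania. The
implementation is cross-checked against
`statsmodels.stats.inter_rater.fleiss_kappa` in the tests.

**Landis–Koch bands** interpret either statistic: poor (< 0), slight
[0, 0.20], fair (0.20, 0.40], moderate (0.40, 0.60], substantial
(0.60, 0.80], almost perfect (0.80, 1]. The comparison is made on the
raw (unrounded) value; the printed two-decimal boundaries are treated
as closed at the top of each band, so the bands partition (−∞, 1]
with no gaps or overlaps.

## Classification accuracy

An estimate is correct iff its label equals the recorded sex. Missing
and indeterminate estimates are never correct but stay in the
denominator — this convention is forced by the published numbers (an
observer with one unscored cranium and six errors is printed at 65%,
i.e. 13/20, not 13/19). Per-sex percentages use per-sex denominators.
Percentages are reported to the nearest whole percent to match the
source precision; raw fractions are retained on the summary objects.

## Reproduction report, and known discrepancies

`build_reproduction_report()` (CLI: `morphosex reproduce`) recomputes
every published downstream quantity from the embedded raw grids.
Quantities the raw data support are asserted; quantities the
publication itself cannot support are *flagged* — computed and printed
side by side with a note:

* direct-observer mastoid and supra-orbital W (printed 0.68 and 0.78;
  tie-corrected W with listwise deletion of the incomplete cranium
  gives 0.74 and 0.81, and the original missing-data handling is
  undocumented). The glabella value (0.81) and all three video-table
  values (0.79/0.76/0.84) reproduce exactly;
* `V2`'s percent correct (printed 65; the published table's own eight
  error markers imply 12/20 = 60, which is what recomputation gives);
* three probability cells that contradict their own printed scores:
  (O4, cranium 10) printed 96/4 vs computed 52/48, (V3, cranium 15)
  printed "6 9" which does not sum to 100, and (V4, cranium 9) printed
  100/0 vs computed 97/3;
* the headline kappas (0.50 between observers, 0.56 against recorded
  sex), which specify neither rater set nor missing-data handling.
  Kappa is computed for each defensible choice — O1–O4 (0.45, n = 19),
  V1–V4 (0.29), all eight observers (0.37), and all eight plus the
  recorded sex as a pseudo-rater (0.39) — and none reproduces the
  printed values, so all are flagged.

## Synthetic data generator

`generate(SyntheticConfig)` emulates the structure of the rating
experiment with a latent-Gaussian cumulative-threshold model: a
cranium's latent robusticity on each trait is its sex-specific trait
mean plus a shared cranium effect `N(0, cranium_sd)`; each observation
adds an observer bias and scoring noise `N(0, observer_sd)`; the latent
value is cut by four strictly increasing thresholds into scores 1–5;
cells go missing independently with `missing_rate`. This model was
chosen because it reproduces the qualitative phenomena seen in the real
grids — score-avoidance via bias shifts, mid-score pile-up under heavy
noise — with few parameters.

Defaults (one latent unit ≈ one threshold step): 20 crania, sex ratio
0.5, four unbiased observers, thresholds (−1.5, −0.5, 0.5, 1.5), trait
means ±1 per sex, `cranium_sd` 0.7, `observer_sd` 0.5, no missing
cells. These mirror the study's size and land equation-2 accuracy
inside the observed 65–95% band. All randomness flows from the single
config seed through one `numpy.random.Generator`; identical configs
give byte-identical datasets.

`recovery_experiment` sweeps a config grid, re-seeding each replicate
from a spawned seed sequence, and reports Monte-Carlo means and
standard errors of mean trait W, sex-label kappa, and pooled equation-2
accuracy. Replicates on which a statistic is undefined (e.g. kappa when
every estimate is one sex) are excluded from that statistic's mean.

What the generator does *not* emulate: trait-to-trait correlation
beyond the shared cranium effect, observer learning over the scoring
sequence, non-Gaussian latent spread, and any imaging/reconstruction
error — passing synthetic tests therefore says nothing about model
fidelity of 3D reconstructions, only about the statistical pipeline.

## Problem sizes and numerical choices

All study recomputations are desk scale (8 observers × 20 crania) and
deterministic. Simulation-based tests use 10–30 replicates of 20-crania
datasets, or single datasets of 400–500 crania for the
majority-rate checks, with fixed seeds and a ±0.05 tolerance on
chance-level and majority-rate assertions. Two-decimal rounding of W
and whole-percent rounding of accuracies mirror the source's printed
precision and are applied only at the comparison/reporting boundary;
all internal computation is in double precision.
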