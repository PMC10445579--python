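"""Cell-for-cell transcriptions of the study's published data tables.

Two rating grids (four direct observers "O1".."O4" scoring their own 3D
cranial models, and four video observers "V1".."V4" scoring screen
recordings of Observer 1's models), the recorded sex of each of the 20
crania, and the published downstream results (sex/probability grids,
percent-correct rows, concordance coefficients) used by the reproduction
report.

Scores are on the standard 1-5 robusticity scale (1 gracile/"female",
5 robust/"male"). ``None`` marks the two cells Observer 3 did not score
(cranium 4, mastoid process and supra-orbital margin). The published
grids are transcribed exactly as printed, including the cells whose
printed values are internally inconsistent; those are listed in
``KNOWN_PROBABILITY_DISCREPANCIES`` and flagged, never "fixed".
"""

from __future__ import annotations

# Per trait, per cranium: scores from observers (O1, O2, O3, O4).
OBSERVER_SCORES: dict[str, dict[int, tuple[int | None, ...]]] = {
    "mastoid_process": {
        1: (1, 3, 4, 2),
        2: (1, 5, 4, 4),
        3: (1, 5, 5, 2),
        4: (1, 5, None, 5),
        5: (3, 5, 5, 5),
        6: (2, 5, 5, 5),
        7: (1, 2, 3, 1),
        8: (1, 1, 2, 3),
        9: (2, 5, 3, 3),
        10: (1, 3, 2, 3),
        11: (3, 5, 4, 5),
        12: (4, 5, 5, 5),
        13: (3, 5, 4, 4),
        14: (2, 3, 3, 3),
        15: (1, 1, 1, 1),
        16: (2, 4, 4, 4),
        17: (1, 3, 2, 2),
        18: (2, 3, 3, 4),
        19: (2, 2, 3, 3),
        20: (2, 4, 4, 5),
    },
    "supraorbital_margin": {
        1: (1, 4, 3, 2),
        2: (3, 5, 5, 4),
        3: (2, 5, 4, 3),
        4: (1, 5, None, 2),
        5: (3, 5, 5, 5),
        6: (2, 4, 3, 4),
        7: (2, 3, 3, 3),
        8: (1, 1, 4, 3),
        9: (4, 5, 4, 5),
        10: (2, 1, 2, 2),
        11: (4, 5, 4, 4),
        12: (5, 5, 5, 5),
        13: (4, 5, 4, 5),
        14: (3, 4, 3, 3),
        15: (2, 3, 1, 2),
        16: (4, 5, 5, 4),
        17: (2, 2, 1, 2),
        18: (3, 1, 2, 3),
        19: (1, 1, 2, 1),
        20: (3, 5, 4, 4),
    },
    "glabella": {
        1: (1, 3, 3, 2),
        2: (1, 5, 4, 3),
        3: (2, 5, 3, 3),
        4: (1, 1, 1, 2),
        5: (5, 5, 5, 4),
        6: (3, 5, 4, 4),
        7: (2, 2, 4, 3),
        8: (1, 1, 1, 2),
        9: (5, 5, 5, 4),
        10: (3, 2, 1, 2),
        11: (4, 4, 4, 4),
        12: (5, 5, 5, 5),
        13: (5, 5, 5, 5),
        14: (4, 5, 4, 3),
        15: (3, 1, 1, 3),
        16: (5, 5, 5, 5),
        17: (3, 1, 1, 2),
        18: (3, 2, 1, 3),
        19: (3, 1, 2, 2),
        20: (5, 5, 4, 4),
    },
}

# Per trait, per cranium: scores from video observers (V1, V2, V3, V4).
VIDEO_SCORES: dict[str, dict[int, tuple[int, ...]]] = {
    "mastoid_process": {
        1: (2, 4, 2, 2),
        2: (4, 5, 3, 2),
        3: (3, 5, 2, 3),
        4: (5, 5, 2, 2),
        5: (5, 5, 5, 4),
        6: (5, 5, 4, 4),
        7: (1, 2, 1, 1),
        8: (3, 2, 1, 1),
        9: (3, 4, 4, 2),
        10: (4, 4, 3, 3),
        11: (5, 5, 5, 4),
        12: (5, 5, 5, 4),
        13: (4, 5, 4, 4),
        14: (3, 4, 2, 3),
        15: (1, 3, 1, 2),
        16: (4, 5, 4, 3),
        17: (2, 3, 3, 2),
        18: (3, 4, 2, 3),
        19: (1, 4, 3, 3),
        20: (5, 5, 4, 4),
    },
    "supraorbital_margin": {
        1: (2, 4, 2, 3),
        2: (4, 4, 2, 2),
        3: (4, 3, 3, 4),
        4: (3, 2, 1, 3),
        5: (5, 5, 5, 5),
        6: (4, 4, 2, 3),
        7: (3, 2, 1, 4),
        8: (2, 2, 3, 2),
        9: (5, 5, 5, 5),
        10: (3, 2, 1, 3),
        11: (4, 4, 3, 2),
        12: (5, 5, 3, 4),
        13: (4, 5, 5, 5),
        14: (4, 4, 3, 3),
        15: (3, 2, 1, 4),
        16: (5, 5, 4, 5),
        17: (3, 2, 2, 3),
        18: (3, 3, 3, 4),
        19: (1, 1, 1, 2),
        20: (4, 4, 4, 4),
    },
    "glabella": {
        1: (3, 3, 3, 2),
        2: (4, 4, 2, 2),
        3: (5, 3, 1, 2),
        4: (2, 1, 1, 1),
        5: (5, 5, 5, 5),
        6: (5, 4, 3, 3),
        7: (3, 3, 2, 3),
        8: (1, 1, 1, 1),
        9: (5, 5, 5, 5),
        10: (3, 3, 2, 2),
        11: (4, 4, 2, 2),
        12: (5, 5, 5, 5),
        13: (5, 5, 5, 5),
        14: (4, 4, 2, 1),
        15: (3, 3, 2, 2),
        16: (5, 4, 5, 4),
        17: (3, 2, 1, 3),
        18: (2, 2, 1, 1),
        19: (1, 1, 2, 2),
        20: (5, 5, 4, 3),
    },
}

OBSERVER_IDS = ("O1", "O2", "O3", "O4")
VIDEO_OBSERVER_IDS = ("V1", "V2", "V3", "V4")
CRANIUM_IDS = tuple(range(1, 21))

MALE_CRANIA = frozenset({5, 6, 9, 11, 12, 13, 14, 16, 18, 20})

# Published sex estimates: (observer, cranium) -> (sex, prob male %, prob female %),
# or None where the table prints a dash (Observer 3, cranium 4).
PRINTED_ESTIMATES: dict[tuple[str, int], tuple[str, int, int] | None] = {
    ("O1", 1): ("female", 1, 99),
    ("O2", 1): ("male", 84, 16),
    ("O3", 1): ("male", 96, 4),
    ("O4", 1): ("female", 20, 80),
    ("O1", 2): ("female", 1, 99),
    ("O2", 2): ("male", 100, 0),
    ("O3", 2): ("male", 99, 1),
    ("O4", 2): ("male", 96, 4),
    ("O1", 3): ("female", 6, 94),
    ("O2", 3): ("male", 100, 0),
    ("O3", 3): ("male", 99, 1),
    ("O4", 3): ("male", 55, 45),
    ("O1", 4): ("female", 1, 99),
    ("O2", 4): ("male", 81, 19),
    ("O3", 4): None,
    ("O4", 4): ("male", 95, 5),
    ("O1", 5): ("male", 99, 1),
    ("O2", 5): ("male", 100, 0),
    ("O3", 5): ("male", 100, 0),
    ("O4", 5): ("male", 100, 0),
    ("O1", 6): ("male", 55, 45),
    ("O2", 6): ("male", 100, 0),
    ("O3", 6): ("male", 100, 0),
    ("O4", 6): ("male", 100, 0),
    ("O1", 7): ("female", 6, 94),
    ("O2", 7): ("female", 20, 80),
    ("O3", 7): ("male", 96, 4),
    ("O4", 7): ("female", 22, 78),
    ("O1", 8): ("female", 1, 99),
    ("O2", 8): ("female", 1, 99),
    ("O3", 8): ("female", 5, 95),
    ("O4", 8): ("male", 52, 48),
    ("O1", 9): ("male", 97, 3),
    ("O2", 9): ("male", 100, 0),
    ("O3", 9): ("male", 99, 1),
    ("O4", 9): ("male", 96, 4),
    ("O1", 10): ("female", 22, 78),
    ("O2", 10): ("male", 52, 48),
    ("O3", 10): ("female", 5, 95),
    ("O4", 10): ("male", 96, 4),
    ("O1", 11): ("male", 96, 4),
    ("O2", 11): ("male", 100, 0),
    ("O3", 11): ("male", 99, 1),
    ("O4", 11): ("male", 100, 0),
    ("O1", 12): ("male", 100, 0),
    ("O2", 12): ("male", 100, 0),
    ("O3", 12): ("male", 100, 0),
    ("O4", 12): ("male", 100, 0),
    ("O1", 13): ("male", 99, 1),
    ("O2", 13): ("male", 100, 0),
    ("O3", 13): ("male", 100, 0),
    ("O4", 13): ("male", 100, 0),
    ("O1", 14): ("male", 85, 15),
    ("O2", 14): ("male", 99, 1),
    ("O3", 14): ("male", 96, 4),
    ("O4", 14): ("male", 84, 16),
    ("O1", 15): ("female", 22, 78),
    ("O2", 15): ("female", 1, 99),
    ("O3", 15): ("female", 1, 99),
    ("O4", 15): ("female", 22, 78),
    ("O1", 16): ("male", 97, 3),
    ("O2", 16): ("male", 100, 0),
    ("O3", 16): ("male", 100, 0),
    ("O4", 16): ("male", 100, 0),
    ("O1", 17): ("female", 22, 78),
    ("O2", 17): ("female", 18, 82),
    ("O3", 17): ("female", 5, 95),
    ("O4", 17): ("female", 20, 80),
    ("O1", 18): ("male", 55, 45),
    ("O2", 18): ("male", 52, 48),
    ("O3", 18): ("female", 18, 82),
    ("O4", 18): ("male", 96, 4),
    ("O1", 19): ("male", 55, 45),
    ("O2", 19): ("female", 5, 95),
    ("O3", 19): ("male", 52, 48),
    ("O4", 19): ("male", 52, 48),
    ("O1", 20): ("male", 97, 3),
    ("O2", 20): ("male", 100, 0),
    ("O3", 20): ("male", 99, 1),
    ("O4", 20): ("male", 100, 0),
    ("V1", 1): ("male", 55, 45),
    ("V2", 1): ("male", 96, 4),
    ("V3", 1): ("male", 55, 45),
    ("V4", 1): ("female", 20, 80),
    ("V1", 2): ("male", 99, 1),
    ("V2", 2): ("male", 100, 0),
    ("V3", 2): ("male", 52, 48),
    ("V4", 2): ("female", 20, 80),
    ("V1", 3): ("male", 99, 1),
    ("V2", 3): ("male", 99, 1),
    ("V3", 3): ("female", 5, 95),
    ("V4", 3): ("male", 52, 48),
    ("V1", 4): ("male", 95, 5),
    ("V2", 4): ("male", 81, 19),
    ("V3", 4): ("female", 5, 95),
    ("V4", 4): ("female", 5, 95),
    ("V1", 5): ("male", 100, 0),
    ("V2", 5): ("male", 100, 0),
    ("V3", 5): ("male", 100, 0),
    ("V4", 5): ("male", 100, 0),
    ("V1", 6): ("male", 100, 0),
    ("V2", 6): ("male", 100, 0),
    ("V3", 6): ("male", 96, 4),
    ("V4", 6): ("male", 96, 4),
    ("V1", 7): ("female", 22, 78),
    ("V2", 7): ("male", 55, 45),
    ("V3", 7): ("female", 6, 94),
    ("V4", 7): ("female", 22, 78),
    ("V1", 8): ("female", 18, 82),
    ("V2", 8): ("female", 5, 95),
    ("V3", 8): ("female", 1, 99),
    ("V4", 8): ("female", 1, 99),
    ("V1", 9): ("male", 99, 1),
    ("V2", 9): ("male", 100, 0),
    ("V3", 9): ("male", 100, 0),
    ("V4", 9): ("male", 100, 0),
    ("V1", 10): ("male", 96, 4),
    ("V2", 10): ("male", 96, 4),
    ("V3", 10): ("male", 52, 48),
    ("V4", 10): ("male", 52, 48),
    ("V1", 11): ("male", 100, 0),
    ("V2", 11): ("male", 100, 0),
    ("V3", 11): ("male", 95, 5),
    ("V4", 11): ("male", 82, 18),
    ("V1", 12): ("male", 100, 0),
    ("V2", 12): ("male", 100, 0),
    ("V3", 12): ("male", 100, 0),
    ("V4", 12): ("male", 100, 0),
    ("V1", 13): ("male", 100, 0),
    ("V2", 13): ("male", 100, 0),
    ("V3", 13): ("male", 100, 0),
    ("V4", 13): ("male", 100, 0),
    ("V1", 14): ("male", 96, 4),
    ("V2", 14): ("male", 99, 1),
    ("V3", 14): ("female", 20, 80),
    ("V4", 14): ("female", 18, 82),
    ("V1", 15): ("female", 22, 78),
    ("V2", 15): ("male", 84, 16),
    ("V3", 15): ("female", 6, 9),
    ("V4", 15): ("female", 20, 80),
    ("V1", 16): ("male", 100, 0),
    ("V2", 16): ("male", 100, 0),
    ("V3", 16): ("male", 100, 0),
    ("V4", 16): ("male", 96, 4),
    ("V1", 17): ("male", 55, 45),
    ("V2", 17): ("male", 52, 48),
    ("V3", 17): ("female", 18, 82),
    ("V4", 17): ("male", 55, 45),
    ("V1", 18): ("male", 52, 48),
    ("V2", 18): ("male", 82, 18),
    ("V3", 18): ("female", 5, 95),
    ("V4", 18): ("female", 18, 82),
    ("V1", 19): ("female", 1, 99),
    ("V2", 19): ("female", 49, 51),
    ("V3", 19): ("male", 52, 48),
    ("V4", 19): ("male", 52, 48),
    ("V1", 20): ("male", 100, 0),
    ("V2", 20): ("male", 100, 0),
    ("V3", 20): ("male", 99, 1),
    ("V4", 20): ("male", 96, 4),
}

# Published "% correct" rows.
PRINTED_PERCENT_CORRECT: dict[str, int] = {
    "O1": 95, "O2": 75, "O3": 65, "O4": 70,
    "V1": 70, "V2": 65, "V3": 70, "V4": 70,
}

# Published Kendall's coefficients of concordance, per observer set and trait.
PRINTED_KCC: dict[tuple[str, str], float] = {
    ("observers", "mastoid_process"): 0.68,
    ("observers", "supraorbital_margin"): 0.78,
    ("observers", "glabella"): 0.81,
    ("video", "mastoid_process"): 0.79,
    ("video", "supraorbital_margin"): 0.76,
    ("video", "glabella"): 0.84,
}

# Published Fleiss' kappa headline values; the rater set and missing-data
# handling behind them are not documented, so they are flagged, not asserted.
PRINTED_FLEISS_KAPPA: dict[str, float] = {
    "between_observer_sex_estimates": 0.50,
    "observer_sex_estimates_vs_recorded": 0.56,
}

# Cells whose printed probabilities cannot be reproduced from their own
# printed trait scores: (observer, cranium) -> reason.
KNOWN_PROBABILITY_DISCREPANCIES: dict[tuple[str, int], str] = {
    ("O4", 10): "printed 96/4, but the printed scores (mastoid 3, glabella 2) give 52/48",
    ("V3", 15): "printed probabilities 6/9 do not sum to 100; presumed typographical",
    ("V4", 9): "printed 100/0, but the printed scores (mastoid 2, glabella 5) give 97/3",
}
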