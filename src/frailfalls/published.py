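"""Published summary counts from the OPRA cohort, as fixed reference inputs.

The OPRA (Osteoporosis Risk Assessment) study followed 1044
community-dwelling Swedish women from age 75 for ten years; its
person-level data are not publicly deposited, but the published
contingency counts are.  This module records those printed counts so
the pipeline's cross-tabulation and odds-ratio machinery can be run
against them: percentages and 2x2 odds ratios recomputed here from the
counts should agree with the published values.

All structures are plain counts; nothing here is estimated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BASELINE_N",
    "BASELINE_FALLS_BY_FRAILTY",
    "QUINTILE_FALLS",
    "GROUP_OUTCOMES",
    "expand_counts",
    "reconstruct_denominators",
]

#: Baseline cohort size and frailty split (frail = index >= 0.25 at age 75).
BASELINE_N = {"total": 1044, "non_frail": 799, "frail": 245}

#: Falls in the 12 months before baseline, by baseline frailty status
#: (914 women had valid falls data: 693 non-frail, 221 frail).
BASELINE_FALLS_BY_FRAILTY = pd.DataFrame(
    {
        "no_falls": {"non_frail": 547, "frail": 107},
        "one_fall": {"non_frail": 84, "frail": 42},
        "recurrent": {"non_frail": 62, "frail": 72},
    }
)

#: Quintiles of the frailty index (rows, lowest first) crossed with the
#: number of falls reported in the 12 months before the outcome visit
#: (columns: none / 1 / 2 / 3+).  Keyed by (frailty age, falls age).
QUINTILE_FALLS: dict[tuple[int, int], np.ndarray] = {
    (75, 75): np.array(
        [
            [167, 14, 5, 0],
            [145, 19, 12, 6],
            [134, 27, 12, 8],
            [117, 30, 13, 17],
            [91, 36, 23, 38],
        ]
    ),
    (75, 80): np.array(
        [
            [111, 11, 10, 8],
            [105, 17, 11, 9],
            [95, 28, 12, 5],
            [96, 18, 14, 13],
            [78, 20, 20, 22],
        ]
    ),
    (75, 85): np.array(
        [
            [50, 13, 9, 3],
            [45, 15, 8, 6],
            [41, 17, 10, 5],
            [31, 17, 11, 15],
            [38, 6, 11, 20],
        ]
    ),
    (80, 85): np.array(
        [
            [47, 9, 8, 5],
            [38, 16, 10, 6],
            [40, 13, 11, 5],
            [32, 18, 9, 11],
            [30, 10, 10, 19],
        ]
    ),
}

#: Fall-frailty groups at one visit and falls outcomes at the next.
#: Per outcome: the published event counts and percentages per group, in
#: the order faller/frail, faller/non-frail, non-faller/frail,
#: non-faller/non-frail, plus the published total n with complete data.
GROUP_ORDER = ["faller_frail", "faller_nonfrail", "nonfaller_frail", "nonfaller_nonfrail"]
GROUP_OUTCOMES = {
    ("any_fall", 75, 80): {
        "events": [27, 53, 22, 100],
        "pct": [54.0, 47.3, 37.3, 24.4],
        "n_total": 631,
    },
    ("recurrent", 75, 80): {
        "events": [18, 39, 16, 45],
        "pct": [36.0, 35.5, 27.6, 11.1],
        "n_total": 625,
    },
    ("any_fall", 80, 85): {
        "events": [30, 43, 31, 67],
        "pct": [76.9, 57.3, 48.4, 37.2],
        "n_total": 358,
    },
    ("recurrent", 80, 85): {
        "events": [20, 23, 18, 33],
        "pct": [57.1, 32.4, 28.1, 18.6],
        "n_total": 347,
    },
}


def reconstruct_denominators(events, pct) -> list[int]:
    """Group sizes recovered from published event counts and percentages.

    n_g = round(100 * events_g / pct_g); exact up to the rounding of the
    published percentage.
    """
    out = []
    for e, p in zip(events, pct):
        if p <= 0:
            raise ValueError("cannot reconstruct a denominator from a zero percentage")
        out.append(int(round(100.0 * e / p)))
    return out


def expand_counts(counts: pd.DataFrame | np.ndarray, row_labels=None, col_labels=None) -> pd.DataFrame:
    """Expand a count matrix into one record per individual.

    Returns a two-column frame (row, col) whose cross-tabulation
    reproduces the input counts, so the analysis code paths can be run
    directly on published tables.
    """
    if isinstance(counts, pd.DataFrame):
        row_labels = list(counts.index)
        col_labels = list(counts.columns)
        mat = counts.to_numpy()
    else:
        mat = np.asarray(counts)
        if row_labels is None:
            row_labels = list(range(1, mat.shape[0] + 1))
        if col_labels is None:
            col_labels = list(range(mat.shape[1]))
    rows, cols = [], []
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_labels):
            k = int(mat[i, j])
            rows.extend([r] * k)
            cols.extend([c] * k)
    return pd.DataFrame({"row": rows, "col": cols})
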