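"""Deficit-accumulation frailty index.

The index is the mean of 13 per-item deficit scores, each in [0, 1] with
0 the healthiest state.  Continuous items are min-max rescaled over a
range fixed after outlier exclusion; binary items are scored 0/1 at a
cutpoint.  Frailty is classified at an empirical cutoff (default 0.25)
and, for gradient analyses, the index is binned into equal-sized
quintiles of the analysis subsample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import Cohort, DeficitSpec, FrailtyResult, ParticipantVisit

__all__ = [
    "IndexConfig",
    "rescale_continuous",
    "score_binary",
    "determine_range",
    "score_items",
    "compute_frailty_index",
    "build_index_table",
    "classify_frailty",
    "assign_quintiles",
    "compare_indices",
    "IndexComparison",
]

N_ITEMS = 13


class DegenerateRangeError(ValueError):
    """All values identical, or v_min == v_max: no range to rescale over."""


@dataclass(frozen=True)
class IndexConfig:
    """Index-building options.

    cutoff
        Frailty threshold on the index scale (default 0.25).
    min_completeness
        Fraction of items that must be non-missing for the index to be
        defined (default 0.8, i.e. at least 11 of 13 items).
    frail_boundary
        ``"ge"`` classifies index == cutoff as frail (default),
        ``"gt"`` as non-frail.
    """

    cutoff: float = 0.25
    min_completeness: float = 0.8
    frail_boundary: Literal["ge", "gt"] = "ge"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie strictly inside (0, 1)")
        if not 0.0 < self.min_completeness <= 1.0:
            raise ValueError("min_completeness must lie in (0, 1]")


def rescale_continuous(value: float, spec: DeficitSpec) -> float:
    """Min-max rescale a continuous deficit value to a unit score.

    Computes (value - v_min) / (v_max - v_min), clamped to [0, 1], and
    reflected when the *lower* end of the scale is the unhealthy one so
    that a score near 0 always means the healthier state.
    """
    if spec.kind != "continuous":
        raise ValueError(f"deficit {spec.name!r} is not continuous")
    if spec.v_min == spec.v_max:
        raise DegenerateRangeError(f"deficit {spec.name!r}: v_min == v_max")
    s = (value - spec.v_min) / (spec.v_max - spec.v_min)
    s = min(1.0, max(0.0, s))
    return 1.0 - s if spec.direction == "lower_is_worse" else s


def score_binary(value: float, spec: DeficitSpec) -> int:
    """Score a binary deficit: 1 iff the value is on the unhealthy side of the cutpoint."""
    if spec.kind != "binary":
        raise ValueError(f"deficit {spec.name!r} is not binary")
    if spec.direction == "higher_is_worse":
        return int(value >= spec.cutpoint)
    return int(value < spec.cutpoint)


def determine_range(
    values: Sequence[float], outlier_rule: tuple[float, float] = (0.005, 0.995)
) -> tuple[float, float]:
    """Fix (v_min, v_max) for rescaling after excluding extreme outliers.

    The band endpoints are the order statistics at positions
    ``floor((n-1) * q)`` for the two quantiles of ``outlier_rule`` (the
    nearest rank not exceeding the requested quantile position); values
    strictly outside the closed band are excluded, and the min and max
    of what remains become v_min and v_max.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 20:
        raise ValueError(f"need at least 20 non-missing values, got {arr.size}")
    srt = np.sort(arr)
    lo_q, hi_q = outlier_rule
    lo = srt[int(np.floor((srt.size - 1) * lo_q))]
    hi = srt[int(np.floor((srt.size - 1) * hi_q))]
    kept = srt[(srt >= lo) & (srt <= hi)]
    v_min, v_max = float(kept.min()), float(kept.max())
    if v_min == v_max:
        raise DegenerateRangeError("all retained values identical; no usable range")
    return v_min, v_max


def _score_one(value: float, spec: DeficitSpec) -> float:
    if spec.kind == "binary":
        return float(score_binary(value, spec))
    return rescale_continuous(value, spec)


def score_items(df: pd.DataFrame, specs: Sequence[DeficitSpec]) -> pd.DataFrame:
    """Vectorised per-item deficit scores for a cohort table.

    Returns a frame with one column per deficit, values in [0, 1] and
    NaN where the raw value is missing.
    """
    out = {}
    for spec in specs:
        v = pd.to_numeric(df[spec.name], errors="coerce").to_numpy(dtype=float)
        if spec.kind == "binary":
            if spec.direction == "higher_is_worse":
                s = (v >= spec.cutpoint).astype(float)
            else:
                s = (v < spec.cutpoint).astype(float)
        else:
            if spec.v_min == spec.v_max:
                raise DegenerateRangeError(f"deficit {spec.name!r}: v_min == v_max")
            s = np.clip((v - spec.v_min) / (spec.v_max - spec.v_min), 0.0, 1.0)
            if spec.direction == "lower_is_worse":
                s = 1.0 - s
        s = np.where(np.isnan(v), np.nan, s)
        out[spec.name] = s
    return pd.DataFrame(out, index=df.index)


def classify_frailty(index: float, config: IndexConfig = IndexConfig()) -> str:
    """Classify an index value as ``"frail"`` or ``"non_frail"`` at the configured cutoff."""
    if not 0.0 <= index <= 1.0:
        raise ValueError("index must lie in [0, 1]")
    if config.frail_boundary == "ge":
        return "frail" if index >= config.cutoff else "non_frail"
    return "frail" if index > config.cutoff else "non_frail"


def compute_frailty_index(
    visit: ParticipantVisit,
    specs: Sequence[DeficitSpec],
    config: IndexConfig = IndexConfig(),
) -> FrailtyResult | None:
    """Frailty index for one participant-visit.

    The index is the mean of the per-item scores over non-missing items.
    Returns None when fewer than ``min_completeness`` of the items are
    non-missing (the record is then excluded downstream).
    """
    scores = [
        _score_one(visit.deficit_values[s.name], s)
        for s in specs
        if s.name in visit.deficit_values
    ]
    n = len(scores)
    if n < config.min_completeness * len(specs):
        return None
    idx = float(np.mean(scores))
    return FrailtyResult(
        participant_id=visit.participant_id,
        visit_age=visit.visit_age,
        index=idx,
        n_items_scored=n,
        frail=classify_frailty(idx, config) == "frail",
    )


def build_index_table(cohort: Cohort, config: IndexConfig = IndexConfig()) -> pd.DataFrame:
    """Frailty results for every attended visit in a cohort.

    Returns a frame with participant_id, visit_age, index,
    n_items_scored, complete (completeness threshold met) and frail.
    Rows for non-attended visits carry NaN indices.
    """
    df = cohort.data
    scores = score_items(df, cohort.deficit_specs)
    n_items = scores.notna().sum(axis=1)
    idx = scores.mean(axis=1, skipna=True)
    complete = n_items >= config.min_completeness * len(cohort.deficit_specs)
    idx = idx.where(complete)
    if config.frail_boundary == "ge":
        frail = idx >= config.cutoff
    else:
        frail = idx > config.cutoff
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "visit_age": df["visit_age"].to_numpy(),
            "index": idx.to_numpy(),
            "n_items_scored": n_items.to_numpy(),
            "complete": complete.to_numpy(),
            "frail": np.where(idx.isna(), np.nan, frail.astype(float)).astype(object),
        }
    )


def assign_quintiles(values: Sequence[float]) -> np.ndarray:
    """Equal-sized quintile labels (1 = lowest frailty) for an analysis subsample.

    Group sizes differ by at most one, the larger groups at the low end;
    ties are broken by stable input order.  The subsample passed in must
    already be the analysis set (attendees with falls data) — quintiles
    are never computed on a superset and mapped down.
    """
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quintiles require defined index values (no NaN)")
    n = arr.size
    if n < 5:
        raise ValueError(f"need at least 5 values to form quintiles, got {n}")
    order = np.argsort(arr, kind="stable")
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q < rem else 0) for q in range(5)]
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    return labels


@dataclass(frozen=True)
class IndexComparison:
    """Agreement summary between two frailty indices on paired participants."""

    r: float
    n_pairs: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float


def compare_indices(fi_a: Sequence[float], fi_b: Sequence[float]) -> IndexComparison:
    """Pearson correlation and distribution summary of two paired indices.

    Pairs with a missing value on either side are dropped; at least 3
    complete pairs are required and both vectors must vary.
    """
    a = np.asarray(fi_a, dtype=float)
    b = np.asarray(fi_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("index vectors must be paired (equal length)")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {a.size}")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("correlation undefined: an index has zero variance")
    r = float(np.corrcoef(a, b)[0, 1])
    return IndexComparison(
        r=r,
        n_pairs=int(a.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
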