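"""Empirical frailty-cutoff selection from 10-year mortality.

Scans candidate cutoffs on a fixed grid (default step 0.02), records the
10-year mortality among participants at or above each candidate, and
locates the beginning of a steeper slope in the resulting curve with a
grid-constrained continuous two-segment least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = ["CutoffScan", "ChangePoint", "scan_mortality", "detect_slope_change"]


@dataclass
class CutoffScan:
    """Mortality profile over a grid of candidate frailty cutoffs.

    ``mortality[i]`` is the 10-year death proportion in the comparison
    group at ``cutoffs[i]`` (NaN when the group is empty).  Candidates
    whose at-or-above group has fewer than the configured minimum of
    members are marked unstable and excluded from changepoint fitting.
    """

    cutoffs: np.ndarray
    mortality: np.ndarray
    n_at_or_above: np.ndarray
    stable: np.ndarray
    mode: Literal["at_or_above", "difference"] = "at_or_above"
    step: float = 0.02
    any_deaths: bool = True


@dataclass(frozen=True)
class ChangePoint:
    """A fitted two-segment slope change."""

    cutoff: float
    rss: float
    slope_below: float
    slope_above: float
    distinct: bool  # False when the slope increase is below tolerance


def scan_mortality(
    index_values: Sequence[float],
    died_within_10y: Sequence[bool],
    step: float = 0.02,
    lo: float = 0.0,
    hi: float | None = None,
    min_group: int = 10,
    mode: Literal["at_or_above", "difference"] = "at_or_above",
) -> CutoffScan:
    """Scan candidate cutoffs and record mortality per candidate.

    mode="at_or_above" (default) records the death proportion among
    participants with index >= c.  mode="difference" records that
    proportion minus the proportion among index < c, for readers of the
    curve as a frail-vs-non-frail mortality gap.
    """
    fi = np.asarray(index_values, dtype=float)
    died = np.asarray(died_within_10y, dtype=bool)
    ok = ~np.isnan(fi)
    fi, died = fi[ok], died[ok]
    if fi.size == 0:
        raise ValueError("no index values to scan")
    if step <= 0:
        raise ValueError("step must be positive")
    if hi is None:
        hi = np.floor(fi.max() / step) * step
    n_steps = int(round((hi - lo) / step))
    cutoffs = lo + step * np.arange(n_steps + 1)

    mort = np.full(cutoffs.size, np.nan)
    n_above = np.zeros(cutoffs.size, dtype=int)
    for i, c in enumerate(cutoffs):
        above = fi >= c - 1e-12
        n_above[i] = int(above.sum())
        if n_above[i] == 0:
            continue
        m = died[above].mean()
        if mode == "difference":
            below = ~above
            m = m - (died[below].mean() if below.any() else 0.0)
        mort[i] = m
    stable = (n_above >= min_group) & ~np.isnan(mort)
    return CutoffScan(
        cutoffs=cutoffs,
        mortality=mort,
        n_at_or_above=n_above,
        stable=stable,
        mode=mode,
        step=step,
        any_deaths=bool(died.any()),
    )


def _hinge_fit(x: np.ndarray, y: np.ndarray, knot: float) -> tuple[float, np.ndarray]:
    """Least-squares continuous two-segment fit with a fixed knot; returns (rss, coefs)."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - knot, 0.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def detect_slope_change(
    scan: CutoffScan, min_slope_ratio: float = 2.0
) -> ChangePoint:
    """Locate the knee of the mortality curve on the candidate grid.

    Fits a continuous two-segment piecewise-linear model to the stable
    (candidate, mortality) points for every interior grid breakpoint and
    returns the breakpoint minimising the residual sum of squares, ties
    broken toward the smaller cutoff.  The changepoint is flagged as not
    distinct when the upper slope is below ``min_slope_ratio`` times the
    lower slope (both slopes taken at the best breakpoint).
    """
    if not scan.any_deaths:
        raise ValueError("changepoint undefined: no deaths in the scan")
    x = scan.cutoffs[scan.stable]
    y = scan.mortality[scan.stable]
    if x.size < 6:
        raise ValueError(f"need at least 6 stable candidates, got {x.size}")
    # interior breakpoints: at least two stable points on each side
    candidates = [c for c in x[2:-2]]
    if not candidates:
        raise ValueError("no interior breakpoints available")
    best: tuple[float, float, np.ndarray] | None = None
    for c in candidates:
        rss, coef = _hinge_fit(x, y, c)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, c, coef)
    rss, knot, coef = best
    slope_below = float(coef[1])
    slope_above = float(coef[1] + coef[2])
    # a knee must add a material positive slope, not numerical noise
    distinct = coef[2] > 1e-8 and (
        slope_below <= 1e-8 or slope_above >= min_slope_ratio * slope_below
    )
    return ChangePoint(
        cutoff=float(knot),
        rss=rss,
        slope_below=slope_below,
        slope_above=slope_above,
        distinct=bool(distinct),
    )
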