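"""Falls classification, cross-tabulation, and odds-ratio estimation.

Falls in the previous 12 months define three categories (none, one,
recurrent = two or more).  Combined with frailty status they give the
four fall-frailty groups.  Effect estimates are odds ratios from 2x2
cross-products (Woolf confidence intervals) or binary logistic
regression, optionally adjusted for 25(OH)D, BMI, smoking and prior
fracture.  ``run_full_analysis`` orchestrates every summary table the
pipeline produces.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core import Cohort, SMOKING_LEVELS
from .index import IndexConfig, assign_quintiles, build_index_table

__all__ = [
    "FallCategory",
    "FallFrailtyGroup",
    "classify_falls",
    "fall_frailty_group",
    "ContingencyTable",
    "cross_tabulate",
    "chi_square",
    "EffectEstimate",
    "odds_ratio_2x2",
    "logistic_or",
    "frailty_increment_or",
    "SeparationError",
    "AnalysisReport",
    "run_full_analysis",
]

Z95 = 1.959963984540054  # standard normal 97.5th percentile


class FallCategory(str, enum.Enum):
    NO_FALLS = "no_falls"
    ONE_FALL = "one_fall"
    RECURRENT = "recurrent"


class FallFrailtyGroup(str, enum.Enum):
    FALLER_FRAIL = "faller_frail"
    FALLER_NONFRAIL = "faller_nonfrail"
    NONFALLER_FRAIL = "nonfaller_frail"
    NONFALLER_NONFRAIL = "nonfaller_nonfrail"


class SeparationError(RuntimeError):
    """Logistic fit failed to converge; a covariate separates the outcome."""


def classify_falls(n_falls: int) -> FallCategory:
    """Map a 12-month falls count to its category (0 / 1 / two-or-more)."""
    n = int(n_falls)
    if n < 0:
        raise ValueError("falls count must be non-negative")
    if n == 0:
        return FallCategory.NO_FALLS
    if n == 1:
        return FallCategory.ONE_FALL
    return FallCategory.RECURRENT


def fall_frailty_group(category: FallCategory, frail: bool) -> FallFrailtyGroup:
    """Combine faller status (>= 1 fall) with frailty status into the 2x2 group."""
    faller = category in (FallCategory.ONE_FALL, FallCategory.RECURRENT)
    if faller:
        return FallFrailtyGroup.FALLER_FRAIL if frail else FallFrailtyGroup.FALLER_NONFRAIL
    return FallFrailtyGroup.NONFALLER_FRAIL if frail else FallFrailtyGroup.NONFALLER_NONFRAIL


@dataclass
class ContingencyTable:
    """Cross-classification counts with row percentages."""

    row_labels: list
    col_labels: list
    counts: np.ndarray  # shape (rows, cols), non-negative ints
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def cross_tabulate(
    df: pd.DataFrame,
    row: str,
    col: str,
    row_order: Sequence | None = None,
    col_order: Sequence | None = None,
) -> ContingencyTable:
    """Counts of ``row`` x ``col`` over rows where both are defined.

    Rows with a missing value on either variable are excluded and
    counted in ``n_excluded``.
    """
    if df.empty:
        raise ValueError("cannot tabulate an empty slice")
    sub = df[[row, col]]
    ok = sub.notna().all(axis=1)
    sub = sub.loc[ok]
    if sub.empty:
        raise ValueError("no rows with both variables defined")
    tab = pd.crosstab(sub[row], sub[col])
    if row_order is not None:
        tab = tab.reindex(index=list(row_order), fill_value=0)
    if col_order is not None:
        tab = tab.reindex(columns=list(col_order), fill_value=0)
    return ContingencyTable(
        row_labels=list(tab.index),
        col_labels=list(tab.columns),
        counts=tab.to_numpy(dtype=int),
        n_excluded=int((~ok).sum()),
    )


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, p).

    Expected counts must all be positive; otherwise the test is
    undefined and the caller should merge sparse categories.
    """
    counts = table.counts
    expected = stats.contingency.expected_freq(counts)
    if (expected <= 0).any():
        raise ValueError("zero expected count; merge sparse categories before testing")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class EffectEstimate:
    """An odds ratio with its 95% confidence interval and provenance."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    model: str  # table_2x2 | logistic_unadjusted | logistic_adjusted
    term: str = "exposure"
    p_value: float | None = None
    n: int | None = None
    n_excluded: int = 0
    adjusted_for: tuple[str, ...] = ()
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval must bracket the odds ratio")


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> EffectEstimate:
    """Odds ratio for a 2x2 table with Woolf 95% CI.

    Layout: exposed events a, exposed non-events b, unexposed events c,
    unexposed non-events d.  Any zero cell triggers the
    Haldane-Anscombe correction (0.5 added to every cell), flagged on
    the estimate.  A table with an empty margin has no defined OR.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("odds ratio undefined: an entire margin is zero")
    corrected = any(x == 0 for x in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        model="table_2x2",
        p_value=float(p),
        n=int(sum(cells)),
        continuity_corrected=corrected,
    )


def _covariate_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Expand an adjustment frame into numeric columns (smoking dummied, never = reference)."""
    parts = []
    for col in cov.columns:
        if col == "smoking":
            s = pd.Categorical(cov[col], categories=SMOKING_LEVELS)
            dummies = pd.get_dummies(pd.Series(s, index=cov.index), prefix="smoking")
            dummies = dummies.drop(columns=["smoking_never"])
            # preserve missingness: dummies of NaN rows must be NaN, not all-zero
            dummies[cov[col].isna()] = np.nan
            parts.append(dummies.astype(float))
        else:
            parts.append(pd.to_numeric(cov[col], errors="coerce").rename(col).to_frame())
    return pd.concat(parts, axis=1).astype(float)


def logistic_or(
    outcome: Sequence,
    exposure: Sequence,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
) -> dict[str, EffectEstimate]:
    """Binary logistic regression; ORs with Wald 95% CIs per term.

    Complete-case fit: rows missing the outcome, exposure or any
    covariate are dropped and counted in ``n_excluded``.  The returned
    mapping has one estimate per model term; the exposure's estimate is
    under ``exposure_name``.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="y").reset_index(drop=True)
    x = pd.Series(np.asarray(exposure, dtype=float), name=exposure_name).reset_index(drop=True)
    design = x.to_frame()
    if covariates is not None and len(covariates.columns):
        design = pd.concat(
            [design, _covariate_design(covariates.reset_index(drop=True))], axis=1
        )
    ok = y.notna() & design.notna().all(axis=1)
    n_excl = int((~ok).sum())
    y, design = y[ok], design.loc[ok]
    if len(y) == 0:
        raise ValueError("no complete cases to fit")
    if y.nunique() < 2:
        raise ValueError("outcome is constant; logistic model undefined")
    if x[ok].nunique() < 2:
        raise ValueError(f"exposure {exposure_name!r} has zero variance")
    X = sm.add_constant(design.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            # non-convergence / separation is converted to SeparationError below
            warnings.simplefilter("ignore")
            fit = sm.Logit(np.asarray(y), np.asarray(X)).fit(disp=0, maxiter=200, tol=1e-8)
    except Exception as exc:  # pragma: no cover - statsmodels raises various
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        worst = X.columns[int(np.argmax(np.abs(fit.params)))]
        raise SeparationError(f"logistic fit did not converge; check covariate {worst!r}")
    adjusted = tuple(c for c in design.columns if c != exposure_name)
    model = "logistic_adjusted" if adjusted else "logistic_unadjusted"
    out: dict[str, EffectEstimate] = {}
    for i, term in enumerate(X.columns):
        if term == "const":
            continue
        beta, se = float(fit.params[i]), float(fit.bse[i])
        out[term] = EffectEstimate(
            odds_ratio=math.exp(beta),
            ci_low=math.exp(beta - Z95 * se),
            ci_high=math.exp(beta + Z95 * se),
            model=model,
            term=term,
            p_value=float(fit.pvalues[i]),
            n=int(len(y)),
            n_excluded=n_excl,
            adjusted_for=adjusted,
        )
    return out


def frailty_increment_or(
    outcome: Sequence,
    index_values: Sequence,
    covariates: pd.DataFrame | None = None,
) -> EffectEstimate:
    """Odds ratio per 0.01 increment of the frailty index.

    The index is scaled by 100 before fitting, so the exponentiated
    coefficient is directly the per-0.01 OR.
    """
    fi = np.asarray(index_values, dtype=float) * 100.0
    fits = logistic_or(outcome, fi, covariates, exposure_name="fi_per_0.01")
    return fits["fi_per_0.01"]


# ---------------------------------------------------------------------------
# Full pipeline

_FALL_ORDER = ["no_falls", "one_fall", "two_falls", "three_plus"]
_GROUP_ORDER = [g.value for g in FallFrailtyGroup]

DEFAULT_ADJUSTMENT = ("bmi", "vitd_25oh", "smoking", "prior_fracture")


def _fall_category4(n: float) -> str:
    """Four-level falls grouping used for the quintile-gradient tables."""
    n = int(n)
    if n == 0:
        return "no_falls"
    if n == 1:
        return "one_fall"
    if n == 2:
        return "two_falls"
    return "three_plus"


@dataclass
class AnalysisReport:
    """Structured output of :func:`run_full_analysis`."""

    baseline_by_frailty: pd.DataFrame
    incidence: pd.DataFrame
    quintile_tables: dict[str, dict]
    group_summaries: dict[str, pd.DataFrame]
    estimates: dict[str, EffectEstimate]
    analysis_ns: dict[str, int]
    config: IndexConfig = field(default_factory=IndexConfig)

    def to_json(self, path) -> None:
        def est(e: EffectEstimate) -> dict:
            d = asdict(e)
            d["adjusted_for"] = list(e.adjusted_for)
            return d

        payload = {
            "config": asdict(self.config),
            "analysis_ns": self.analysis_ns,
            "baseline_by_frailty": self.baseline_by_frailty.to_dict(orient="index"),
            "incidence": self.incidence.to_dict(orient="records"),
            "quintile_tables": {
                key: {
                    "counts": tab["table"].counts.tolist(),
                    "row_labels": [str(r) for r in tab["table"].row_labels],
                    "col_labels": [str(c) for c in tab["table"].col_labels],
                    "row_percentages": np.round(tab["table"].row_percentages, 4).tolist(),
                    "chi2": tab["chi2"],
                    "df": tab["df"],
                    "p": tab["p"],
                }
                for key, tab in self.quintile_tables.items()
            },
            "group_summaries": {
                k: v.to_dict(orient="index") for k, v in self.group_summaries.items()
            },
            "estimates": {k: est(v) for k, v in self.estimates.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _analysis_slice(df: pd.DataFrame, age: int) -> pd.DataFrame:
    """Attendees at `age` with valid falls data and a defined index."""
    sub = df[(df["visit_age"] == age) & df["attended"].astype(bool)]
    return sub[sub["falls_12m"].notna() & sub["index"].notna()]


def _merged(cohort: Cohort, config: IndexConfig) -> pd.DataFrame:
    fi = build_index_table(cohort, config)
    df = cohort.data.merge(
        fi[["participant_id", "visit_age", "index", "frail"]],
        on=["participant_id", "visit_age"],
        how="left",
    )
    df["frail"] = df["frail"].astype(float)
    return df


def run_full_analysis(
    cohort: Cohort,
    config: IndexConfig = IndexConfig(),
    adjust: Sequence[str] = DEFAULT_ADJUSTMENT,
    visit_ages: Sequence[int] = (75, 80, 85),
) -> AnalysisReport:
    """Every summary the pipeline produces, on one cohort.

    Emits baseline characteristics split by frailty status, falls
    incidence per visit, quintile-by-falls gradient tables for each
    visit pairing, fall-frailty group proportions with unadjusted and
    adjusted odds ratios, frailty-status ORs for falls at follow-up,
    and per-0.01-index ORs.  Each table records its analysis n;
    excluded records are counted, never silently dropped.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    base_age, *follow_ages = list(visit_ages)
    df = _merged(cohort, config)
    ns: dict[str, int] = {}
    estimates: dict[str, EffectEstimate] = {}

    # --- (e) falls incidence per visit -------------------------------------
    inc_rows = []
    for age in visit_ages:
        att = df[(df["visit_age"] == age) & df["attended"].astype(bool)]
        valid = att[att["falls_12m"].notna()]
        n = len(valid)
        if n:
            any_fall = int((valid["falls_12m"] >= 1).sum())
            rec = int((valid["falls_12m"] >= 2).sum())
        else:
            any_fall = rec = 0
        inc_rows.append(
            {
                "visit_age": age,
                "n_attended": int(len(att)),
                "n_valid_falls": n,
                "n_missing_falls": int(len(att) - n),
                "n_any_fall": any_fall,
                "pct_any_fall": 100.0 * any_fall / n if n else np.nan,
                "n_recurrent": rec,
                "pct_recurrent": 100.0 * rec / n if n else np.nan,
            }
        )
    incidence = pd.DataFrame(inc_rows)

    # --- (a) baseline characteristics by frailty status ---------------------
    base = df[(df["visit_age"] == base_age) & df["index"].notna()].copy()
    if base.empty:
        raise ValueError(f"no baseline records with a defined index at age {base_age}")
    ns["baseline_indexed"] = len(base)
    rows = {}
    for label, grp in (
        ("non_frail", base[base["frail"] == 0.0]),
        ("frail", base[base["frail"] == 1.0]),
        ("all", base),
    ):
        falls = grp["falls_12m"].dropna().astype(int)
        nf = len(falls)
        rows[label] = {
            "n": len(grp),
            "fi_median": float(grp["index"].median()),
            "fi_iqr": float(grp["index"].quantile(0.75) - grp["index"].quantile(0.25)),
            "bmi_mean": float(grp["bmi"].mean()),
            "vitd_mean": float(grp["vitd_25oh"].mean()),
            "n_falls_valid": nf,
            "pct_one_fall": 100.0 * (falls == 1).sum() / nf if nf else np.nan,
            "pct_recurrent": 100.0 * (falls >= 2).sum() / nf if nf else np.nan,
            "pct_no_falls": 100.0 * (falls == 0).sum() / nf if nf else np.nan,
            "pct_prior_fracture": 100.0 * grp["prior_fracture"].astype(float).mean(),
        }
    baseline_by_frailty = pd.DataFrame(rows).T

    # --- (b) quintile x falls tables per visit pairing ----------------------
    pairings = [(base_age, base_age)] + [(base_age, a) for a in follow_ages]
    if len(follow_ages) >= 2:
        pairings.append((follow_ages[0], follow_ages[1]))
    quintile_tables: dict[str, dict] = {}
    for fr_age, fall_age in pairings:
        fr = df[(df["visit_age"] == fr_age) & df["index"].notna()][
            ["participant_id", "index"]
        ]
        fa = df[(df["visit_age"] == fall_age) & df["attended"].astype(bool)][
            ["participant_id", "falls_12m"]
        ].dropna(subset=["falls_12m"])
        merged = fr.merge(fa, on="participant_id")
        key = f"frailty{fr_age}_falls{fall_age}"
        ns[key] = len(merged)
        if len(merged) < 5:
            continue
        merged = merged.copy()
        merged["quintile"] = assign_quintiles(merged["index"].to_numpy())
        merged["fall_cat"] = merged["falls_12m"].map(_fall_category4)
        tab = cross_tabulate(
            merged, "quintile", "fall_cat", row_order=[1, 2, 3, 4, 5], col_order=_FALL_ORDER
        )
        stat, dof, p = chi_square(tab)
        quintile_tables[key] = {"table": tab, "chi2": stat, "df": dof, "p": p}

    # --- frailty-status ORs for falls at follow-up (d) ----------------------
    cov_cols = [c for c in adjust if c in df.columns]
    base_idx = base.set_index("participant_id")
    for fall_age in follow_ages:
        fa = df[(df["visit_age"] == fall_age) & df["attended"].astype(bool)].set_index(
            "participant_id"
        )
        joined = base_idx.join(fa[["falls_12m"]], rsuffix="_out", how="inner").dropna(
            subset=["falls_12m_out"]
        )
        if joined.empty:
            continue
        for outcome_name, thresh in (("any_fall", 1), ("recurrent", 2)):
            y = (joined["falls_12m_out"] >= thresh).astype(float)
            key = f"frail{base_age}_{outcome_name}{fall_age}"
            try:
                estimates[key] = logistic_or(y, joined["frail"], exposure_name="frail")[
                    "frail"
                ]
                if cov_cols:
                    estimates[key + "_adj"] = logistic_or(
                        y, joined["frail"], joined[cov_cols], exposure_name="frail"
                    )["frail"]
            except (ValueError, SeparationError):
                pass
            try:
                estimates[f"fi{base_age}_per001_{outcome_name}{fall_age}"] = (
                    frailty_increment_or(y, joined["index"])
                )
            except (ValueError, SeparationError):
                pass

    # --- (c) fall-frailty groups and their future-falls pattern --------------
    group_summaries: dict[str, pd.DataFrame] = {}
    group_ages = [base_age] + ([follow_ages[0]] if follow_ages else [])
    for g_age in group_ages:
        later = [a for a in visit_ages if a > g_age]
        gbase = _analysis_slice(df, g_age).copy()
        if gbase.empty:
            continue
        gbase["group"] = [
            fall_frailty_group(classify_falls(int(nf)), bool(fr)).value
            for nf, fr in zip(gbase["falls_12m"], gbase["frail"])
        ]
        gset = gbase.set_index("participant_id")
        for fall_age in later:
            fa = df[(df["visit_age"] == fall_age) & df["attended"].astype(bool)].set_index(
                "participant_id"
            )
            joined = gset.join(fa[["falls_12m"]], rsuffix="_out", how="inner").dropna(
                subset=["falls_12m_out"]
            )
            if joined.empty:
                continue
            key = f"groups{g_age}_falls{fall_age}"
            ns[key] = len(joined)
            rows = {}
            for outcome_name, thresh in (("any_fall", 1), ("recurrent", 2)):
                y = (joined["falls_12m_out"] >= thresh).astype(float)
                for grp in _GROUP_ORDER:
                    mask = joined["group"] == grp
                    n_g = int(mask.sum())
                    rows.setdefault(grp, {})[f"n_{outcome_name}"] = int(y[mask].sum())
                    rows[grp][f"pct_{outcome_name}"] = (
                        100.0 * y[mask].mean() if n_g else np.nan
                    )
                    rows[grp]["n_total"] = n_g
                # ORs of each frail group against its non-frail counterpart,
                # and robust (non-faller/non-frail) as overall reference
                contrasts = {
                    "faller_frail_vs_nonfrail": ("faller_frail", "faller_nonfrail"),
                    "nonfaller_frail_vs_nonfrail": ("nonfaller_frail", "nonfaller_nonfrail"),
                    "faller_frail_vs_robust": ("faller_frail", "nonfaller_nonfrail"),
                }
                for cname, (g1, g0) in contrasts.items():
                    sub = joined[joined["group"].isin([g1, g0])]
                    if sub.empty:
                        continue
                    exp = (sub["group"] == g1).astype(float)
                    ysub = (sub["falls_12m_out"] >= thresh).astype(float)
                    ekey = f"{key}_{outcome_name}_{cname}"
                    try:
                        estimates[ekey] = logistic_or(ysub, exp, exposure_name="frail_group")[
                            "frail_group"
                        ]
                        if cov_cols:
                            estimates[ekey + "_adj"] = logistic_or(
                                ysub, exp, sub[cov_cols], exposure_name="frail_group"
                            )["frail_group"]
                    except (ValueError, SeparationError):
                        pass
            group_summaries[key] = pd.DataFrame(rows).T.loc[_GROUP_ORDER]

    return AnalysisReport(
        baseline_by_frailty=baseline_by_frailty,
        incidence=incidence,
        quintile_tables=quintile_tables,
        group_summaries=group_summaries,
        estimates=estimates,
        analysis_ns=ns,
        config=config,
    )
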