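"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the falls-frailty analyses assume: a
right-skewed baseline frailty-index distribution in a single-age cohort
of 1044 women, frailty rising over two 5-year follow-ups,
frailty-dependent 12-month falls counts, frailty-dependent attrition
through death and non-attendance (1044 -> ~715 -> ~382 attendees), and
missing falls reports.

The design is latent-index-first: each participant gets a latent
frailty trajectory, the 13 raw deficit values are sampled consistently
with it, and all outcome models (falls, mortality, attendance) are then
driven by the index *rebuilt from the observed deficits* — exactly the
quantity the analysis regressions consume — so parameter-recovery
experiments are correctly specified.

Default constants are calibration (fitted once to the published
marginal targets), not published parameters; see the config docstring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import BASE_COLUMNS, Cohort, DeficitSpec
from .falls import frailty_increment_or, logistic_or, SeparationError
from .index import IndexConfig, build_index_table, score_items

__all__ = [
    "DEFAULT_DEFICIT_SPECS",
    "GeneratorConfig",
    "generate_cohort",
    "ten_year_mortality",
    "RecoverySummary",
    "recovery_experiment",
]

#: The 13 deficit variables: 9 continuous (min-max rescaled) and 4
#: binary, mirroring the domains of a musculoskeletal-health index
#: (activity, mobility, balance, strength, morbidity, medication,
#: inflammation, renal function, self-rated fall risk).
DEFAULT_DEFICIT_SPECS: list[DeficitSpec] = [
    DeficitSpec("physical_activity_score", "continuous", "lower_is_worse", v_min=0.0, v_max=10.0),
    DeficitSpec("outdoor_hours_per_week", "continuous", "lower_is_worse", v_min=0.0, v_max=28.0),
    DeficitSpec("walking_speed_ms", "continuous", "lower_is_worse", v_min=0.2, v_max=1.8),
    DeficitSpec("steps_to_walk_30m", "continuous", "higher_is_worse", v_min=21.0, v_max=160.0),
    DeficitSpec("balance_time_s", "continuous", "lower_is_worse", v_min=0.0, v_max=30.0),
    DeficitSpec("grip_strength_kg", "continuous", "lower_is_worse", v_min=4.0, v_max=40.0),
    DeficitSpec("medication_count", "continuous", "higher_is_worse", v_min=0.0, v_max=12.0),
    DeficitSpec("crp_mg_l", "continuous", "higher_is_worse", v_min=0.0, v_max=50.0),
    DeficitSpec("creatinine_umol_l", "continuous", "higher_is_worse", v_min=40.0, v_max=150.0),
    DeficitSpec("diabetes", "binary", "higher_is_worse", cutpoint=0.5),
    DeficitSpec("cancer", "binary", "higher_is_worse", cutpoint=0.5),
    DeficitSpec("balance_disease", "binary", "higher_is_worse", cutpoint=0.5),
    DeficitSpec("self_rated_fall_risk", "binary", "higher_is_worse", cutpoint=0.5),
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Latent baseline frailty is Beta(*latent_a*, *latent_b*); continuous
    item scores are Beta(kt, k(1-t)) around the latent value t with
    concentration *item_concentration*, binary items Bernoulli(t).
    These three constants were calibrated once so the *built* index at
    baseline has median 0.16, IQR ~0.15 and frail (>= 0.25) prevalence
    23.5%.  Falls follow marginal logistic models in the built index
    (odds ratios per 0.01 of index); 10-year mortality is piecewise
    linear in the baseline index with a knee at 0.25; attendance at
    each follow-up is logistic with a negative frailty slope,
    calibrated to expected attendee counts 1044 -> 715 -> 382.
    """

    n_baseline: int = 1044
    seed: int = 0
    # latent frailty distribution and item-noise (calibration)
    latent_a: float = 2.80
    latent_b: float = 12.91
    item_concentration: float = 62.0
    # per-5-year additive drift of the latent index and trajectory noise
    frailty_drift: tuple[float, float] = (0.0635, 0.0763)
    trajectory_sd: float = 0.015
    # falls model: marginal ORs per 0.01 of index, with intercepts
    # calibrated to baseline incidences 28.4% (any fall), 14.7% (recurrent)
    or_any_fall_per001: float = 1.04
    or_recurrent_per001: float = 1.05
    alpha_any_fall: float = -1.663
    alpha_recurrent: float = -2.732
    # extra falls beyond 2 for recurrent fallers: negative-binomial tail
    nb_tail_n: float = 1.0
    nb_tail_p: float = 0.6
    # 10-year mortality, piecewise linear in baseline index
    mortality_base: float = 0.18
    mortality_slope_low: float = 0.5
    mortality_slope_high: float = 2.2
    mortality_knee: float = 0.25
    # attendance at follow-ups: P(attend) = expit(a - slope * index)
    attendance_slope: float = 4.0
    attendance_a80: float = 2.555
    attendance_a85: float = 1.767
    # covariates (linear in baseline index, gaussian noise; smoking marginal)
    bmi_base: float = 25.3
    bmi_slope: float = 5.5
    bmi_sd: float = 4.1
    vitd_base: float = 67.5
    vitd_slope: float = -30.0
    vitd_sd: float = 18.5
    smoking_probs: tuple[float, float, float] = (0.657, 0.202, 0.141)
    fracture_logit_base: float = -0.9
    fracture_logit_slope: float = 2.05
    # missingness of the falls report per visit, and per deficit item
    missing_falls: tuple[float, float, float] = (0.125, 0.006, 0.0)
    missing_item: float = 0.01
    # calibration target recorded for tests (baseline frail prevalence)
    target_frail_prevalence: float = 0.235
    visit_ages: tuple[int, int, int] = (75, 80, 85)

    def __post_init__(self) -> None:
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        probs = list(self.missing_falls) + [self.missing_item] + list(self.smoking_probs)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.smoking_probs), 1.0, abs_tol=1e-9):
            raise ValueError("smoking_probs must sum to 1")

    @property
    def beta_any_per_unit(self) -> float:
        """Log-odds of >= 1 fall per unit of 100 x index."""
        return math.log(self.or_any_fall_per001)

    @property
    def beta_recurrent_per_unit(self) -> float:
        return math.log(self.or_recurrent_per001)


def _sample_deficits(
    rng: np.random.Generator,
    t: np.ndarray,
    specs: Sequence[DeficitSpec],
    kappa: float,
    missing_item: float,
) -> pd.DataFrame:
    """Raw deficit values whose rebuilt item scores centre on the latent index t."""
    t = np.clip(t, 1e-4, 1 - 1e-4)
    cols = {}
    for spec in specs:
        if spec.kind == "continuous":
            s = rng.beta(kappa * t, kappa * (1.0 - t))
            span = spec.v_max - spec.v_min
            if spec.direction == "higher_is_worse":
                v = spec.v_min + s * span
            else:
                v = spec.v_max - s * span
            v = np.round(v, 3)
        else:
            s = (rng.random(t.size) < t).astype(float)
            v = s  # 0/1 raw value, scored at cutpoint 0.5
        if missing_item > 0:
            v = np.where(rng.random(t.size) < missing_item, np.nan, v)
        cols[spec.name] = v
    return pd.DataFrame(cols)


def _built_index(deficits: pd.DataFrame, specs, index_config: IndexConfig) -> np.ndarray:
    scores = score_items(deficits, specs)
    n_items = scores.notna().sum(axis=1)
    fi = scores.mean(axis=1, skipna=True)
    fi = fi.where(n_items >= index_config.min_completeness * len(specs))
    return fi.to_numpy()


def _draw_falls(
    rng: np.random.Generator, fi: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """12-month falls counts with marginal logistic models in the index.

    A single shared uniform per woman makes P(>=1 fall) and
    P(recurrent) exactly the two configured logistic curves; recurrent
    fallers get 2 plus a negative-binomial tail.
    """
    x = 100.0 * np.nan_to_num(fi, nan=np.nanmean(fi) if np.isnan(fi).any() else 0.0)
    p_any = expit(config.alpha_any_fall + config.beta_any_per_unit * x)
    p_rec = expit(config.alpha_recurrent + config.beta_recurrent_per_unit * x)
    p_rec = np.minimum(p_rec, p_any)
    u = rng.random(fi.size)
    tail = rng.negative_binomial(config.nb_tail_n, config.nb_tail_p, fi.size)
    falls = np.zeros(fi.size, dtype=float)
    falls[u < p_any] = 1.0
    rec = u < p_rec
    falls[rec] = 2.0 + tail[rec]
    return falls


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    specs: Sequence[DeficitSpec] | None = None,
    index_config: IndexConfig = IndexConfig(),
) -> Cohort:
    """Generate a three-visit cohort; fully reproducible from ``config.seed``.

    Every participant has one row per visit age.  Deficits, falls and
    covariate-independent fields are observed only for attended visits;
    non-attended rows keep the alive/attended flags with deficits and
    falls missing.  Covariates are baseline measurements repeated on
    every row.
    """
    specs = list(specs) if specs is not None else list(DEFAULT_DEFICIT_SPECS)
    rng = np.random.default_rng(config.seed)
    n = config.n_baseline
    age75, age80, age85 = config.visit_ages

    t75 = rng.beta(config.latent_a, config.latent_b, n)
    d75 = _sample_deficits(rng, t75, specs, config.item_concentration, config.missing_item)
    fi75 = _built_index(d75, specs, index_config)
    falls75 = _draw_falls(rng, fi75, config)
    miss75 = rng.random(n) < config.missing_falls[0]

    # covariates, measured at baseline
    bmi = np.round(config.bmi_base + config.bmi_slope * fi75 + rng.normal(0, config.bmi_sd, n), 1)
    bmi = np.clip(bmi, 14.0, 55.0)
    vitd = np.round(
        np.clip(config.vitd_base + config.vitd_slope * fi75 + rng.normal(0, config.vitd_sd, n), 5.0, 200.0),
        1,
    )
    smoking = rng.choice(["never", "previous", "current"], size=n, p=config.smoking_probs)
    fracture = rng.random(n) < expit(config.fracture_logit_base + config.fracture_logit_slope * fi75)

    # mortality: P(die within 10y) piecewise linear in the baseline index,
    # split into two 5-year waves with equal conditional hazard
    fi_m = np.where(np.isnan(fi75), np.nanmean(fi75), fi75)
    p10 = np.clip(
        config.mortality_base
        + config.mortality_slope_low * fi_m
        + (config.mortality_slope_high - config.mortality_slope_low)
        * np.maximum(fi_m - config.mortality_knee, 0.0),
        0.01,
        0.95,
    )
    p5 = 1.0 - np.sqrt(1.0 - p10)
    died_wave1 = rng.random(n) < p5
    died_wave2 = rng.random(n) < p5  # applies only to wave-1 survivors
    alive80 = ~died_wave1
    alive85 = alive80 & ~died_wave2

    # five-year frailty trajectories
    t80 = np.clip(t75 + config.frailty_drift[0] + rng.normal(0, config.trajectory_sd, n), 1e-4, 1 - 1e-4)
    d80 = _sample_deficits(rng, t80, specs, config.item_concentration, config.missing_item)
    fi80 = _built_index(d80, specs, index_config)
    falls80 = _draw_falls(rng, fi80, config)
    miss80 = rng.random(n) < config.missing_falls[1]
    attend80 = alive80 & (
        rng.random(n) < expit(config.attendance_a80 - config.attendance_slope * np.where(np.isnan(fi80), np.nanmean(fi80), fi80))
    )

    t85 = np.clip(t80 + config.frailty_drift[1] + rng.normal(0, config.trajectory_sd, n), 1e-4, 1 - 1e-4)
    d85 = _sample_deficits(rng, t85, specs, config.item_concentration, config.missing_item)
    fi85 = _built_index(d85, specs, index_config)
    falls85 = _draw_falls(rng, fi85, config)
    miss85 = rng.random(n) < config.missing_falls[2]
    attend85 = attend80 & alive85 & (
        rng.random(n) < expit(config.attendance_a85 - config.attendance_slope * np.where(np.isnan(fi85), np.nanmean(fi85), fi85))
    )

    pid = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    frames = []
    visit_data = [
        (age75, np.ones(n, dtype=bool), np.ones(n, dtype=bool), d75, falls75, miss75),
        (age80, alive80, attend80, d80, falls80, miss80),
        (age85, alive85, attend85, d85, falls85, miss85),
    ]
    for age, alive, attended, deficits, falls, missing in visit_data:
        falls_col = np.where(missing | ~attended, np.nan, falls)
        base = pd.DataFrame(
            {
                "participant_id": pid,
                "visit_age": age,
                "falls_12m": falls_col,
                "alive": alive,
                "attended": attended,
                "bmi": bmi,
                "vitd_25oh": vitd,
                "smoking": smoking,
                "prior_fracture": fracture,
            }
        )
        dv = deficits.where(np.broadcast_to(attended[:, None], deficits.shape))
        frames.append(pd.concat([base, dv], axis=1))
    data = pd.concat(frames, ignore_index=True)
    data["falls_12m"] = data["falls_12m"].astype("Float64").round().astype("Int64")
    return Cohort(data=data, deficit_specs=specs)


def ten_year_mortality(cohort: Cohort) -> pd.DataFrame:
    """Baseline rows joined with a died-within-10-years flag.

    Death is read off the vital-status flag of the final visit row.
    """
    ages = sorted(cohort.data["visit_age"].unique())
    base = cohort.data[cohort.data["visit_age"] == ages[0]].set_index("participant_id")
    last = cohort.data[cohort.data["visit_age"] == ages[-1]].set_index("participant_id")
    died = ~last["alive"].astype(bool)
    return pd.DataFrame(
        {"died_within_10y": died.reindex(base.index).fillna(False).astype(bool)},
        index=base.index,
    ).reset_index()


def _implied_frail_recurrent_or(
    config: GeneratorConfig, index_config: IndexConfig, n: int = 200_000, seed: int = 987
) -> float:
    """Large-sample frail-vs-non-frail OR for recurrent falls implied by the config."""
    rng = np.random.default_rng(seed)
    t = rng.beta(config.latent_a, config.latent_b, n)
    d = _sample_deficits(rng, t, DEFAULT_DEFICIT_SPECS, config.item_concentration, 0.0)
    fi = _built_index(d, DEFAULT_DEFICIT_SPECS, index_config)
    x = 100.0 * fi
    p = np.minimum(
        expit(config.alpha_recurrent + config.beta_recurrent_per_unit * x),
        expit(config.alpha_any_fall + config.beta_any_per_unit * x),
    )
    frail = fi >= index_config.cutoff if index_config.frail_boundary == "ge" else fi > index_config.cutoff
    pf, pn = p[frail].mean(), p[~frail].mean()
    return float((pf / (1 - pf)) / (pn / (1 - pn)))


@dataclass
class RecoverySummary:
    """Bias and coverage of the analysis estimators over generated cohorts."""

    n_replicates: int
    true_or_per001: float
    mean_or_per001: float
    coverage_per001: float | None
    rejection_rate_per001: float
    implied_frail_or: float
    mean_frail_or: float
    coverage_frail: float | None
    per001_estimates: np.ndarray = field(repr=False, default=None)


def recovery_experiment(
    config: GeneratorConfig = GeneratorConfig(),
    index_config: IndexConfig = IndexConfig(),
    n_replicates: int = 100,
    seed: int = 0,
) -> RecoverySummary:
    """Generate-analyse-summarise loop for the two headline estimators.

    Each replicate draws a fresh cohort, restricts to baseline attendees
    with valid falls data and a defined index, and fits (i) the
    per-0.01-index logistic OR for recurrent falls and (ii) the
    frail-vs-non-frail logistic OR.  Reports mean estimates, Wald-CI
    coverage of the generator truth, and the rejection rate of the
    per-0.01 test at the 5% level.  With a single replicate no coverage
    is claimed (coverage fields are None).
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    true_or = config.or_recurrent_per001
    implied_frail = _implied_frail_recurrent_or(config, index_config)
    ors, covers, rejects = [], [], []
    frail_ors, frail_covers = [], []
    for s in seeds:
        cohort = generate_cohort(replace(config, seed=int(s)), index_config=index_config)
        fi = build_index_table(cohort, index_config)
        base_age = config.visit_ages[0]
        base = cohort.data[cohort.data["visit_age"] == base_age].reset_index(drop=True)
        fib = fi[fi["visit_age"] == base_age].reset_index(drop=True)
        ok = base["falls_12m"].notna() & fib["index"].notna()
        y = (base.loc[ok, "falls_12m"].astype(int) >= 2).astype(float).to_numpy()
        x = fib.loc[ok, "index"].to_numpy(dtype=float)
        try:
            est = frailty_increment_or(y, x)
        except (ValueError, SeparationError):
            continue
        ors.append(est.odds_ratio)
        covers.append(est.ci_low <= true_or <= est.ci_high)
        rejects.append(est.p_value is not None and est.p_value < 0.05)
        frail = (fib.loc[ok, "frail"].astype(float) == 1.0).astype(float).to_numpy()
        try:
            fe = logistic_or(y, frail, exposure_name="frail")["frail"]
            frail_ors.append(fe.odds_ratio)
            frail_covers.append(fe.ci_low <= implied_frail <= fe.ci_high)
        except (ValueError, SeparationError):
            pass
    n_ok = len(ors)
    return RecoverySummary(
        n_replicates=n_ok,
        true_or_per001=true_or,
        mean_or_per001=float(np.mean(ors)),
        coverage_per001=float(np.mean(covers)) if n_ok > 1 else None,
        rejection_rate_per001=float(np.mean(rejects)),
        implied_frail_or=implied_frail,
        mean_frail_or=float(np.mean(frail_ors)) if frail_ors else float("nan"),
        coverage_frail=float(np.mean(frail_covers)) if len(frail_covers) > 1 else None,
        per001_estimates=np.asarray(ors),
    )
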