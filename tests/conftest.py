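import numpy as np
import pandas as pd
import pytest

from frailfalls import Cohort, DeficitSpec, GeneratorConfig, generate_cohort


def make_cohort_frame(rows: list[dict], deficit_names: list[str]) -> pd.DataFrame:
    """Build a cohort table from sparse row dicts, filling schema defaults."""
    defaults = {
        "falls_12m": np.nan,
        "alive": True,
        "attended": True,
        "bmi": 26.0,
        "vitd_25oh": 62.0,
        "smoking": "never",
        "prior_fracture": False,
    }
    full = []
    for row in rows:
        r = dict(defaults)
        r.update({name: np.nan for name in deficit_names})
        r.update(row)
        full.append(r)
    return pd.DataFrame(full)


@pytest.fixture
def unit_specs() -> list[DeficitSpec]:
    """Two minimal deficits: one continuous on [0, 1], one binary."""
    return [
        DeficitSpec("score", "continuous", "higher_is_worse", v_min=0.0, v_max=1.0),
        DeficitSpec("disease", "binary", "higher_is_worse", cutpoint=0.5),
    ]


@pytest.fixture
def tiny_cohort(unit_specs) -> Cohort:
    rows = [
        {"participant_id": "A", "visit_age": 75, "score": 0.1, "disease": 0, "falls_12m": 0},
        {"participant_id": "B", "visit_age": 75, "score": 0.5, "disease": 1, "falls_12m": 2},
        {"participant_id": "C", "visit_age": 75, "score": 0.9, "disease": 1, "falls_12m": 1},
    ]
    return Cohort(make_cohort_frame(rows, ["score", "disease"]), unit_specs)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One default-sized synthetic cohort, shared across tests (read-only)."""
    return generate_cohort(GeneratorConfig(seed=0))
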