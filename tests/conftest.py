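from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from symptomnet.cohort import CohortConfig, simulate_cohort
from symptomnet.items import symptom_columns


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Hand-built respondent records with sensible defaults.

    Each row dict may override: sex, completed_w6/8, ar_w6/8, n_other_w6/8,
    and per-item symptom columns (``dep_w6`` etc., default 0).
    """
    defaults = {
        "sex": "F",
        "completed_w6": 1,
        "completed_w8": 1,
        "ar_w6": 0,
        "ar_w8": 0,
        "n_other_w6": 0,
        "n_other_w8": 0,
    }
    for col in symptom_columns(6) + symptom_columns(8):
        defaults[col] = 0
    out = []
    for k, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("id", f"h{k:04d}")
        out.append(rec)
    df = pd.DataFrame(out, columns=["id", *defaults])
    for col in symptom_columns(6) + symptom_columns(8):
        df[col] = df[col].astype("Int8")
    return df


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 3,000-respondent synthetic cohort under the default configuration."""
    return simulate_cohort(CohortConfig(n_respondents=3000, seed=11))


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """A 20,000-respondent cohort for distributional checks."""
    return simulate_cohort(CohortConfig(n_respondents=20_000, seed=5))
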