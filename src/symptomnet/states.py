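"""Health-state classification and transition tables.

Each respondent is assigned, per wave, one of five mutually exclusive health
states based on a self-reported arthritis flag (AR: rheumatoid arthritis,
osteoarthritis or other rheumatism) and a count of other surveyed chronic
conditions:

========  ===========================================
code      definition
========  ===========================================
``H``     healthy: no reported chronic condition
``A``     AR only
``O``     a single other disease, no AR
``AC``    AR plus at least one comorbidity
``OC``    two or more diseases, none of them AR
========  ===========================================

The ordered pair of states across the two waves defines one of 25 transition
groups (labels such as ``HA``, ``ACAC``), the strata of the downstream
association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STATE_CODES: tuple[str, ...] = ("H", "A", "O", "AC", "OC")

#: Display names used when rendering the transition table.
STATE_NAMES: dict[str, str] = {
    "H": "No disease",
    "A": "AR",
    "O": "Other disease",
    "AC": "AR and comorbidity",
    "OC": "Other disease and comorbidity",
}

#: A canonical (ar, n_other) witness for each state, used when expanding
#: count fixtures back into records.
STATE_TO_AR_NOTHER: dict[str, tuple[int, int]] = {
    "H": (0, 0),
    "A": (1, 0),
    "O": (0, 1),
    "AC": (1, 1),
    "OC": (0, 2),
}

#: All 25 transition-group labels, row-major in state order.
TRANSITION_LABELS: tuple[str, ...] = tuple(
    f + t for f in STATE_CODES for t in STATE_CODES
)


def classify_health_state(ar_flag: int, n_other_conditions: int) -> str:
    """Map an (AR flag, count of other conditions) pair to a state code.

    The mapping is total on the lattice {0,1} x {0,1,2,...}:
    (0,0)->H, (1,0)->A, (0,1)->O, (1,k>=1)->AC, (0,k>=2)->OC.
    """
    if n_other_conditions < 0:
        raise ValueError(
            f"n_other_conditions must be >= 0, got {n_other_conditions}"
        )
    if ar_flag not in (0, 1):
        raise ValueError(f"ar_flag must be 0 or 1, got {ar_flag}")
    if ar_flag:
        return "A" if n_other_conditions == 0 else "AC"
    if n_other_conditions == 0:
        return "H"
    return "O" if n_other_conditions == 1 else "OC"


def _classify_vec(ar: pd.Series, n_other: pd.Series) -> pd.Series:
    if (n_other < 0).any():
        raise ValueError("n_other_conditions must be >= 0")
    out = np.where(
        ar.to_numpy(dtype=int) == 1,
        np.where(n_other.to_numpy(dtype=int) == 0, "A", "AC"),
        np.where(
            n_other.to_numpy(dtype=int) == 0,
            "H",
            np.where(n_other.to_numpy(dtype=int) == 1, "O", "OC"),
        ),
    )
    return pd.Series(out, index=ar.index)


def add_states(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``state_w6``, ``state_w8`` and ``transition`` columns."""
    out = records.copy()
    out["state_w6"] = _classify_vec(out["ar_w6"], out["n_other_w6"])
    out["state_w8"] = _classify_vec(out["ar_w8"], out["n_other_w8"])
    out["transition"] = out["state_w6"] + out["state_w8"]
    return out


@dataclass(frozen=True)
class CompleteCaseReport:
    """Outcome of the complete-case filter."""

    n_in: int
    n_retained: int

    @property
    def dropout_pct(self) -> float:
        """Attrition percentage, 100 * (n_in - n_retained) / n_in."""
        if self.n_in == 0:
            return 0.0
        return 100.0 * (self.n_in - self.n_retained) / self.n_in

    @property
    def dropout_pct_rounded(self) -> int:
        """Headline attrition figure, rounded to the nearest integer."""
        return int(round(self.dropout_pct))


def filter_complete_cases(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, CompleteCaseReport]:
    """Keep respondents who completed both interviews in both waves.

    Returns the filtered frame together with a :class:`CompleteCaseReport`
    holding the retained count and the dropout percentage.
    """
    mask = (records["completed_w6"] == 1) & (records["completed_w8"] == 1)
    kept = records.loc[mask].copy()
    return kept, CompleteCaseReport(n_in=len(records), n_retained=len(kept))


@dataclass(frozen=True)
class TransitionTable:
    """5x5 table of health-state transitions with female percentages.

    ``counts`` and ``female_pct`` are indexed by wave-6 state (rows) and
    wave-8 state (columns) in canonical state order; ``female_pct`` is NaN
    for empty cells (an undefined ratio, not 0%).
    """

    counts: pd.DataFrame
    female_pct: pd.DataFrame

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_display(self, decimals: int = 1) -> pd.DataFrame:
        """Render ``count (female%)`` cells plus Total row/column."""
        disp = pd.DataFrame(index=list(STATE_CODES), columns=list(STATE_CODES))
        for r in STATE_CODES:
            for c in STATE_CODES:
                n = int(self.counts.loc[r, c])
                pct = self.female_pct.loc[r, c]
                disp.loc[r, c] = (
                    f"{n}" if np.isnan(pct) else f"{n} ({pct:.{decimals}f}%)"
                )
        disp["Total"] = self.row_totals.astype(int).astype(str).to_numpy()
        totals = [str(int(t)) for t in self.col_totals] + [str(self.grand_total)]
        disp.loc["Total"] = totals
        disp.index = [STATE_NAMES.get(s, s) for s in disp.index[:-1]] + ["Total"]
        disp.columns = [STATE_NAMES.get(s, s) for s in list(STATE_CODES)] + ["Total"]
        return disp


def build_transition_table(
    records: pd.DataFrame, sex: str | None = None
) -> TransitionTable:
    """Tabulate transitions between wave-6 and wave-8 states.

    Parameters
    ----------
    records
        Complete-case records; ``state_w6``/``state_w8`` columns are added
        on the fly if absent.
    sex
        Optional ``"M"``/``"F"`` filter applied before counting.
    """
    if "state_w6" not in records.columns:
        records = add_states(records)
    if sex is not None:
        records = records[records["sex"] == sex]

    idx = list(STATE_CODES)
    counts = pd.DataFrame(0, index=idx, columns=idx, dtype=np.int64)
    females = pd.DataFrame(0, index=idx, columns=idx, dtype=np.int64)
    grouped = records.groupby(["state_w6", "state_w8"], observed=True)
    for (r, c), grp in grouped:
        counts.loc[r, c] = len(grp)
        females.loc[r, c] = int((grp["sex"] == "F").sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * females.to_numpy() / counts.to_numpy()
    pct = pd.DataFrame(np.where(counts.to_numpy() > 0, pct, np.nan),
                       index=idx, columns=idx)
    return TransitionTable(counts=counts, female_pct=pct)


def assign_transition_groups(
    records: pd.DataFrame, by_sex: bool = False
) -> Mapping[str, pd.DataFrame] | Mapping[tuple[str, str], pd.DataFrame]:
    """Partition records by transition-group label (optionally crossed with sex).

    Every record lands in exactly one subset; empty groups are omitted.
    """
    if "transition" not in records.columns:
        records = add_states(records)
    keys: Iterable = ["transition", "sex"] if by_sex else ["transition"]
    out: dict = {}
    for key, grp in records.groupby(list(keys), observed=True):
        out[key if by_sex else key[0]] = grp
    return out
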