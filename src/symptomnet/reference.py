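"""Reference marginals from the SHARE wave 6 -> 8 arthritis panel.

These are the observed transition frequencies between the five health states
(rows: state in 2015, columns: state in 2019/2020) among the 30,084
complete-case respondents of the source cohort, together with the cell-wise
female percentages and the pre-filter panel size. They serve two purposes:

* default margins for the synthetic-cohort generator (initial state
  distribution and transition matrix), and
* an arithmetic fixture: aggregating these counts must reproduce the
  published row/column/grand totals exactly.
"""

from __future__ import annotations

import numpy as np

from .states import STATE_CODES

#: Panel size before the complete-case filter (responded in both waves).
PANEL_SIZE = 32_082

#: Respondents who completed both the mental- and physical-health interview
#: in both waves; equals the grand total of the transition table.
COMPLETE_CASES = 30_084

#: Observed 5x5 transition counts, rows/cols in ``STATE_CODES`` order
#: (H, A, O, AC, OC).
TRANSITION_COUNTS = np.array(
    [
        [3758, 306, 1894, 476, 955],
        [186, 268, 174, 323, 74],
        [1222, 187, 3008, 1109, 2207],
        [213, 164, 695, 3340, 1439],
        [377, 59, 1337, 1597, 4716],
    ],
    dtype=np.int64,
)

#: Cell-wise percentage of females for each transition cell.
TRANSITION_FEMALE_PCT = np.array(
    [
        [56.4, 68.3, 53.6, 64.7, 46.6],
        [64.5, 68.7, 66.1, 73.4, 70.3],
        [55.6, 64.2, 53.5, 63.0, 49.3],
        [64.8, 76.8, 65.8, 75.0, 66.5],
        [56.5, 71.2, 52.0, 63.4, 48.4],
    ]
)


def default_initial_state_probs() -> np.ndarray:
    """Wave-6 state margin: row totals of the reference table, normalized."""
    rows = TRANSITION_COUNTS.sum(axis=1)
    return rows / rows.sum()


def default_transition_probs() -> np.ndarray:
    """Row-stochastic transition matrix from the reference counts."""
    rows = TRANSITION_COUNTS.sum(axis=1, keepdims=True)
    return TRANSITION_COUNTS / rows


def reference_transition_records() -> "pd.DataFrame":
    """Expand the reference counts into one minimal record per respondent.

    Each record carries the (ar, n_other) combination inducing its from/to
    state plus a sex assignment reproducing the rounded female percentages as
    closely as integer counts allow. Useful as a deterministic fixture for
    the transition-table aggregation.
    """
    import pandas as pd

    from .states import STATE_TO_AR_NOTHER

    rows = []
    rid = 0
    for r, from_code in enumerate(STATE_CODES):
        for c, to_code in enumerate(STATE_CODES):
            n = int(TRANSITION_COUNTS[r, c])
            n_female = int(round(TRANSITION_FEMALE_PCT[r, c] * n / 100.0))
            ar6, k6 = STATE_TO_AR_NOTHER[from_code]
            ar8, k8 = STATE_TO_AR_NOTHER[to_code]
            for m in range(n):
                rows.append(
                    {
                        "id": f"r{rid}",
                        "sex": "F" if m < n_female else "M",
                        "completed_w6": 1,
                        "completed_w8": 1,
                        "ar_w6": ar6,
                        "ar_w8": ar8,
                        "n_other_w6": k6,
                        "n_other_w8": k8,
                    }
                )
                rid += 1
    return pd.DataFrame(rows)
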