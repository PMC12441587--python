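"""Pairwise symptom associations: odds ratios and Woolf confidence intervals.

For two binary symptoms *i* and *j* in a stratum, the association is the
cross-product ratio of the 2x2 co-occurrence table,

    OR = (N_ij * N_!i!j) / (N_i!j * N_!ij),

with log-scale standard error (Woolf)

    sigma = sqrt(1/N_ij + 1/N_i!j + 1/N_!ij + 1/N_!i!j)

and the log-normal confidence interval exp(ln OR +/- z_{a/2} sigma). Tables
with a zero cell are, by default, continuity-corrected by adding 0.5 to all
four cells (Haldane-Anscombe); a ``strict`` policy raises instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .items import ITEM_CODES, item_index


class DegenerateTableError(ValueError):
    """A 2x2 cell is zero and the zero policy is strict."""


class EmptyStratumError(ValueError):
    """All four cells of the 2x2 table are zero."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Co-occurrence counts for a symptom pair.

    ``n_ij``: both symptoms present; ``n_i_notj``: i only; ``n_noti_j``:
    j only; ``n_noti_notj``: neither. ``corrected`` marks tables to which
    the Haldane-Anscombe +0.5 correction has been applied.
    """

    n_ij: float
    n_i_notj: float
    n_noti_j: float
    n_noti_notj: float
    corrected: bool = False

    def __post_init__(self) -> None:
        for v in (self.n_ij, self.n_i_notj, self.n_noti_j, self.n_noti_notj):
            if v < 0:
                raise ValueError("2x2 cells must be nonnegative")

    @property
    def total(self) -> float:
        return self.n_ij + self.n_i_notj + self.n_noti_j + self.n_noti_notj

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.n_ij, self.n_i_notj, self.n_noti_j, self.n_noti_notj)

    def corrected_copy(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.n_ij + 0.5,
            self.n_i_notj + 0.5,
            self.n_noti_j + 0.5,
            self.n_noti_notj + 0.5,
            corrected=True,
        )

    def swapped(self) -> "ContingencyTable2x2":
        """The table for the pair (j, i): off-diagonal cells exchange."""
        return ContingencyTable2x2(
            self.n_ij, self.n_noti_j, self.n_i_notj, self.n_noti_notj,
            corrected=self.corrected,
        )


@dataclass(frozen=True)
class EdgeEstimate:
    """Odds-ratio estimate for one symptom pair in one wave and stratum."""

    item_i: str
    item_j: str
    wave: int
    stratum: str
    sex: str
    or_value: float
    log_or: float
    sigma: float
    ci_low: float
    ci_high: float
    alpha: float
    cooccurrence: int
    corrected: bool

    @property
    def significant_diff(self) -> bool:
        """CI excludes 1 (two-sided)."""
        return self.ci_low > 1.0 or self.ci_high < 1.0

    @property
    def significant_above(self) -> bool:
        """Lower CI bound exceeds 1 (association significantly positive)."""
        return self.ci_low > 1.0


def tabulate_pair(
    records: pd.DataFrame, item_i: str, item_j: str, wave: int
) -> ContingencyTable2x2:
    """Cross-tabulate two symptoms in one wave, pairwise-complete.

    Rows with either item missing in that wave are excluded.
    """
    if item_i == item_j:
        raise ValueError(f"items must be distinct, got {item_i!r} twice")
    ci, cj = f"{item_i}_w{wave}", f"{item_j}_w{wave}"
    xi = records[ci]
    xj = records[cj]
    ok = xi.notna() & xj.notna()
    xi = xi[ok].astype(int).to_numpy()
    xj = xj[ok].astype(int).to_numpy()
    return ContingencyTable2x2(
        n_ij=int(((xi == 1) & (xj == 1)).sum()),
        n_i_notj=int(((xi == 1) & (xj == 0)).sum()),
        n_noti_j=int(((xi == 0) & (xj == 1)).sum()),
        n_noti_notj=int(((xi == 0) & (xj == 0)).sum()),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    log_or: float
    sigma: float
    table: ContingencyTable2x2  # post-policy counts


def odds_ratio(
    table: ContingencyTable2x2, zero_policy: str = "haldane"
) -> OddsRatioResult:
    """Point estimate and Woolf SE for a 2x2 table.

    ``zero_policy``: ``"haldane"`` adds 0.5 to every cell when any cell is
    zero; ``"strict"`` raises :class:`DegenerateTableError` instead.
    """
    if zero_policy not in ("haldane", "strict"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if table.total == 0:
        raise EmptyStratumError("all four cells are zero")
    if min(table.cells) == 0:
        if zero_policy == "strict":
            raise DegenerateTableError(
                f"zero cell in table {table.cells} under strict policy"
            )
        table = table.corrected_copy()
    a, b, c, d = table.cells
    or_value = (a * d) / (b * c)
    sigma = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return OddsRatioResult(
        or_value=float(or_value),
        log_or=float(np.log(or_value)),
        sigma=sigma,
        table=table,
    )


def confidence_interval(
    log_or: float, sigma: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Log-normal CI: exp(ln OR +/- z_{alpha/2} sigma)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(np.exp(log_or - z * sigma)), float(np.exp(log_or + z * sigma))


def estimate_edge(
    table: ContingencyTable2x2,
    item_i: str,
    item_j: str,
    wave: int,
    stratum: str = "all",
    sex: str = "all",
    alpha: float = 0.05,
    zero_policy: str = "haldane",
) -> EdgeEstimate:
    """Full estimate (OR, SE, CI, flags) for one pair/wave/stratum."""
    raw_cooccurrence = int(table.n_ij)
    res = odds_ratio(table, zero_policy=zero_policy)
    lo, hi = confidence_interval(res.log_or, res.sigma, alpha)
    return EdgeEstimate(
        item_i=item_i,
        item_j=item_j,
        wave=wave,
        stratum=stratum,
        sex=sex,
        or_value=res.or_value,
        log_or=res.log_or,
        sigma=res.sigma,
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        cooccurrence=raw_cooccurrence,
        corrected=res.table.corrected,
    )


EDGE_COLUMNS = (
    "stratum", "sex", "wave", "item_i", "item_j",
    "n_ij", "n_i_notj", "n_noti_j", "n_noti_notj",
    "or", "log_or", "sigma", "ci_low", "ci_high",
    "sig_diff", "sig_above", "corrected",
)


def _canonical_pairs(items: Iterable[str]) -> list[tuple[str, str]]:
    codes = sorted(items, key=item_index)
    return list(itertools.combinations(codes, 2))


def estimate_all(
    records: pd.DataFrame,
    by: tuple[str, ...] = ("transition", "sex"),
    alpha: float = 0.05,
    zero_policy: str = "haldane",
    waves: tuple[int, ...] = (6, 8),
    adjust: str | None = None,
) -> pd.DataFrame:
    """Estimate every symptom pair in every stratum and wave.

    Parameters
    ----------
    records
        Complete-case records carrying ``transition`` (and ``sex``) columns.
    by
        Stratification columns; ``()`` pools everything.
    adjust
        ``"bh"`` appends Benjamini-Hochberg adjusted two-sided Wald
        p-values (``p_bh``) and a ``sig_diff_bh`` flag across all rows.

    Returns a tidy frame with one row per (stratum, sex, wave, pair), in a
    deterministic order (strata sorted, pairs in canonical EURO-D order);
    invariant under shuffling of the input rows. Pairs whose pairwise-complete
    table is entirely empty are skipped.
    """
    pairs = _canonical_pairs(ITEM_CODES)
    if by:
        grouped = records.groupby(list(by), observed=True, sort=True)
        groups = [
            (key if isinstance(key, tuple) else (key,), grp)
            for key, grp in grouped
        ]
        groups.sort(key=lambda kv: kv[0])
    else:
        groups = [((), records)]

    rows = []
    for key, grp in groups:
        meta = dict(zip(by, key))
        stratum = str(meta.get("transition", "all"))
        sex = str(meta.get("sex", "all"))
        if grp.empty:
            continue
        for wave in waves:
            # One pass per wave: pull the 12 columns once.
            cols = {c: grp[f"{c}_w{wave}"] for c in ITEM_CODES}
            for item_i, item_j in pairs:
                xi, xj = cols[item_i], cols[item_j]
                ok = xi.notna() & xj.notna()
                a = xi[ok].astype(int).to_numpy()
                b = xj[ok].astype(int).to_numpy()
                table = ContingencyTable2x2(
                    n_ij=int(((a == 1) & (b == 1)).sum()),
                    n_i_notj=int(((a == 1) & (b == 0)).sum()),
                    n_noti_j=int(((a == 0) & (b == 1)).sum()),
                    n_noti_notj=int(((a == 0) & (b == 0)).sum()),
                )
                if table.total == 0:
                    continue
                est = estimate_edge(
                    table, item_i, item_j, wave,
                    stratum=stratum, sex=sex,
                    alpha=alpha, zero_policy=zero_policy,
                )
                rows.append(
                    {
                        "stratum": stratum,
                        "sex": sex,
                        "wave": wave,
                        "item_i": item_i,
                        "item_j": item_j,
                        "n_ij": int(table.n_ij),
                        "n_i_notj": int(table.n_i_notj),
                        "n_noti_j": int(table.n_noti_j),
                        "n_noti_notj": int(table.n_noti_notj),
                        "or": est.or_value,
                        "log_or": est.log_or,
                        "sigma": est.sigma,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "sig_diff": est.significant_diff,
                        "sig_above": est.significant_above,
                        "corrected": est.corrected,
                    }
                )
    out = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    if adjust == "bh" and not out.empty:
        from statsmodels.stats.multitest import multipletests

        z = out["log_or"].to_numpy() / out["sigma"].to_numpy()
        p = 2.0 * norm.sf(np.abs(z))
        reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        out["p_bh"] = p_adj
        out["sig_diff_bh"] = reject
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjust {adjust!r}")
    return out
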