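"""Synthetic two-wave cohort generator.

Emulates the statistical structure of a SHARE-like panel of older adults:
five health states with a configurable wave-to-wave transition matrix, a
fixed sex composition, panel attrition, and 12 correlated binary depressive
symptoms per wave whose pairwise odds ratios are controllable.

Correlated binaries come from a latent Gaussian threshold model: for each
respondent a 12-variate standard normal vector is drawn with a correlation
matrix calibrated, pair by pair, so that thresholding at the per-item
prevalence quantiles reproduces the target pairwise log odds ratios. The
calibration is exact for each pair in the infinite-sample limit; the joint
12-variate law is the maximum-entropy-like Gaussian completion of those
pairwise constraints (three-way and higher interactions are not controlled,
and if the pairwise targets are jointly infeasible the correlation matrix is
projected to the nearest positive-definite one, which perturbs the realized
associations slightly).

All randomness flows from a single seed through named substreams (sex/states,
symptoms, dropout), so identical configurations yield byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .items import ITEM_CODES, N_ITEMS, symptom_columns
from .reference import default_initial_state_probs, default_transition_probs
from .states import STATE_CODES


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class CalibrationError(ValueError):
    """No latent correlation in (-1, 1) reproduces a target odds ratio."""


class CohortParseError(ValueError):
    """Malformed cohort CSV."""


# Per-item marginal prevalences for the baseline (no-AR) population: a
# plausible EURO-D profile for Europeans aged 50+ (fatigue, sleep problems
# and depressed mood common; suicidality rare). AR states use the same
# profile scaled up, reflecting the roughly doubled symptom burden observed
# in arthritis patients.
_BASE_PREVALENCE = np.array(
    [0.29, 0.17, 0.07, 0.08, 0.31, 0.10, 0.27, 0.09, 0.35, 0.12, 0.12, 0.20]
)
NONAR_PREVALENCE = np.round(_BASE_PREVALENCE * 0.95, 4)
AR_PREVALENCE = np.round(_BASE_PREVALENCE * 1.40, 4)

#: Default pairwise association strength between symptoms (log odds ratio).
DEFAULT_PAIR_LOG_OR = float(np.log(2.5))


def default_symptom_prevalence() -> dict[str, np.ndarray]:
    """Per-state prevalence profiles: AR states elevated over non-AR states."""
    return {
        "H": NONAR_PREVALENCE.copy(),
        "O": NONAR_PREVALENCE.copy(),
        "OC": NONAR_PREVALENCE.copy(),
        "A": AR_PREVALENCE.copy(),
        "AC": AR_PREVALENCE.copy(),
    }


def default_target_log_or() -> np.ndarray:
    """Uniform positive association (OR 2.5) between all symptom pairs."""
    t = np.full((N_ITEMS, N_ITEMS), DEFAULT_PAIR_LOG_OR)
    np.fill_diagonal(t, 0.0)
    return t


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_respondents
        Cohort size.
    female_fraction
        Share of females (the source panel is 58% female).
    initial_state_probs
        Wave-6 distribution over the five health states; defaults to the
        reference table's row margins.
    transition_probs
        Row-stochastic 5x5 matrix giving the wave-8 state distribution
        conditional on the wave-6 state; defaults to the reference table's
        row-normalized counts.
    symptom_prevalence
        Mapping from state code to a 12-vector of per-item marginal
        prevalences used for the wave in which the respondent occupies that
        state.
    target_log_or
        Symmetric 12x12 matrix of target pairwise log odds ratios between
        symptoms (diagonal ignored).
    dropout_prob
        Per-respondent probability of failing the interview battery in
        either wave (the source panel lost ~6%).
    female_prevalence_offset
        Optional additive shift applied to female symptom prevalences
        before thresholding (probit-scale recalibration of thresholds only).
    seed
        Root seed for all substreams.
    """

    n_respondents: int
    female_fraction: float = 0.58
    initial_state_probs: np.ndarray = field(
        default_factory=default_initial_state_probs
    )
    transition_probs: np.ndarray = field(default_factory=default_transition_probs)
    symptom_prevalence: dict[str, np.ndarray] = field(
        default_factory=default_symptom_prevalence
    )
    target_log_or: np.ndarray = field(default_factory=default_target_log_or)
    dropout_prob: float = 1998 / 32082
    female_prevalence_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.initial_state_probs = np.asarray(self.initial_state_probs, float)
        self.transition_probs = np.asarray(self.transition_probs, float)
        self.target_log_or = np.asarray(self.target_log_or, float)
        self.symptom_prevalence = {
            k: np.asarray(v, float) for k, v in self.symptom_prevalence.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_respondents <= 0:
            raise ConfigError("n_respondents must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigError("dropout_prob must be in [0, 1]")
        if self.initial_state_probs.shape != (5,):
            raise ConfigError("initial_state_probs must have length 5")
        if (self.initial_state_probs < 0).any() or not np.isclose(
            self.initial_state_probs.sum(), 1.0, atol=1e-9
        ):
            raise ConfigError("initial_state_probs must be a distribution")
        if self.transition_probs.shape != (5, 5):
            raise ConfigError("transition_probs must be 5x5")
        if (self.transition_probs < 0).any() or not np.allclose(
            self.transition_probs.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ConfigError("transition_probs rows must each sum to 1")
        if self.target_log_or.shape != (N_ITEMS, N_ITEMS):
            raise ConfigError("target_log_or must be 12x12")
        if not np.isfinite(self.target_log_or).all():
            raise ConfigError("target_log_or must be finite")
        if not np.allclose(self.target_log_or, self.target_log_or.T):
            raise ConfigError("target_log_or must be symmetric")
        for code in STATE_CODES:
            if code not in self.symptom_prevalence:
                raise ConfigError(f"symptom_prevalence missing state {code!r}")
            p = self.symptom_prevalence[code]
            if p.shape != (N_ITEMS,):
                raise ConfigError(
                    f"symptom_prevalence[{code!r}] must have length {N_ITEMS}"
                )
            if (p <= 0).any() or (p >= 1).any():
                raise ConfigError(
                    f"symptom_prevalence[{code!r}] must lie in (0, 1)"
                )


def _cell_probs(rho: float, p_i: float, p_j: float) -> tuple[float, ...]:
    """2x2 cell probabilities of thresholded bivariate standard normals."""
    t_i, t_j = norm.isf(p_i), norm.isf(p_j)
    # P(X > t_i, Y > t_j) = P(X < -t_i, Y < -t_j) by central symmetry.
    p11 = float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
            [-t_i, -t_j]
        )
    )
    eps = 1e-12
    p11 = min(max(p11, eps), min(p_i, p_j) - eps)
    p10 = p_i - p11
    p01 = p_j - p11
    p00 = 1.0 - p_i - p_j + p11
    return p11, p10, p01, max(p00, eps)


def latent_log_or(rho: float, p_i: float, p_j: float) -> float:
    """Log odds ratio implied by a latent correlation at given prevalences."""
    p11, p10, p01, p00 = _cell_probs(rho, p_i, p_j)
    return float(np.log(p11 * p00 / (p10 * p01)))


def calibrate_latent_correlation(
    p_i: float, p_j: float, target_log_or: float, tol: float = 1e-6
) -> float:
    """Find the latent Gaussian correlation matching a target log odds ratio.

    Solves ``latent_log_or(rho, p_i, p_j) = target_log_or`` for rho in
    (-0.999, 0.999) by Brent's method against the bivariate-normal orthant
    probability. The implied log OR is strictly increasing in rho, so the
    root is unique when it exists.
    """
    if not (0.0 < p_i < 1.0 and 0.0 < p_j < 1.0):
        raise CalibrationError("prevalences must lie in (0, 1)")
    if not np.isfinite(target_log_or):
        raise CalibrationError("target log OR must be finite")
    if target_log_or == 0.0:
        return 0.0
    lo, hi = -0.999, 0.999
    f_lo = latent_log_or(lo, p_i, p_j) - target_log_or
    f_hi = latent_log_or(hi, p_i, p_j) - target_log_or
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"no latent correlation in (-0.999, 0.999) attains log OR "
            f"{target_log_or:.4f} at prevalences ({p_i:.3f}, {p_j:.3f})"
        )
    rho = brentq(
        lambda r: latent_log_or(r, p_i, p_j) - target_log_or,
        lo,
        hi,
        xtol=tol * 1e-2,
    )
    return float(rho)


def latent_correlation_matrix(
    prevalence: np.ndarray, target_log_or: np.ndarray
) -> np.ndarray:
    """Pairwise-calibrated latent correlation matrix for one state profile.

    If the pairwise solutions do not form a positive-definite matrix, the
    matrix is projected onto the PD cone by eigenvalue clipping and
    re-normalized to unit diagonal (the joint calibration is then
    approximate; see module docstring).
    """
    R = np.eye(N_ITEMS)
    for i in range(N_ITEMS):
        for j in range(i + 1, N_ITEMS):
            try:
                rho = calibrate_latent_correlation(
                    float(prevalence[i]),
                    float(prevalence[j]),
                    float(target_log_or[i, j]),
                )
            except CalibrationError as err:
                raise CalibrationError(
                    f"pair ({ITEM_CODES[i]}, {ITEM_CODES[j]}): {err}"
                ) from None
            R[i, j] = R[j, i] = rho
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def _draw_symptoms(
    rng: np.random.Generator,
    states: np.ndarray,
    female: np.ndarray,
    config: CohortConfig,
    chol_by_state: dict[str, np.ndarray],
) -> np.ndarray:
    """Draw an (n, 12) binary symptom matrix for one wave.

    Respondents are processed in canonical state order; within a state the
    original record order is preserved, so draws are reproducible.
    """
    n = len(states)
    out = np.zeros((n, N_ITEMS), dtype=np.int64)
    for s_idx, code in enumerate(STATE_CODES):
        mask = states == s_idx
        m = int(mask.sum())
        if m == 0:
            continue
        z = rng.standard_normal((m, N_ITEMS)) @ chol_by_state[code].T
        prev = config.symptom_prevalence[code]
        thresh = norm.isf(prev)  # exceed => symptom present
        if config.female_prevalence_offset != 0.0:
            prev_f = np.clip(
                prev + config.female_prevalence_offset, 1e-4, 1 - 1e-4
            )
            thresh_f = norm.isf(prev_f)
            fem = female[mask]
            t = np.where(fem[:, None], thresh_f[None, :], thresh[None, :])
            out[mask] = (z > t).astype(np.int64)
        else:
            out[mask] = (z > thresh[None, :]).astype(np.int64)
    return out


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a two-wave cohort as a DataFrame in the cohort CSV schema.

    Wave-6 health states are drawn from ``initial_state_probs``; wave-8
    states from the respondent's row of ``transition_probs``. Symptoms are
    drawn per wave from the latent threshold model conditioned on that
    wave's state. Respondents who miss either wave's interview battery
    (probability ``dropout_prob``) have that wave's symptoms recorded as
    missing.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_states, rng_symptoms, rng_dropout = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    n = config.n_respondents

    female = rng_states.random(n) < config.female_fraction
    s6 = rng_states.choice(5, size=n, p=config.initial_state_probs)
    # Vectorized row-conditional draw via inverse CDF on per-row cumulative.
    cum = np.cumsum(config.transition_probs, axis=1)
    u = rng_states.random(n)
    s8 = (u[:, None] > cum[s6]).sum(axis=1)
    # Extra comorbidity-count dispersion so classification sees k >= 2 for AC.
    extra = rng_states.poisson(0.8, size=(n, 2))

    chol_by_state: dict[str, np.ndarray] = {}
    matrix_cache: dict[bytes, np.ndarray] = {}
    for code in STATE_CODES:
        key = (
            config.symptom_prevalence[code].tobytes()
            + config.target_log_or.tobytes()
        )
        if key not in matrix_cache:
            R = latent_correlation_matrix(
                config.symptom_prevalence[code], config.target_log_or
            )
            matrix_cache[key] = np.linalg.cholesky(R)
        chol_by_state[code] = matrix_cache[key]

    x6 = _draw_symptoms(rng_symptoms, s6, female, config, chol_by_state)
    x8 = _draw_symptoms(rng_symptoms, s8, female, config, chol_by_state)

    # One attrition event per respondent: a dropout misses the interview
    # battery in both waves, so the realized dropout fraction equals
    # dropout_prob (the complete-case filter removes anyone missing either).
    dropped = rng_dropout.random(n) < config.dropout_prob
    completed6 = ~dropped
    completed8 = ~dropped

    def ar_flag(states: np.ndarray) -> np.ndarray:
        return np.isin(states, [1, 3]).astype(np.int64)  # A, AC

    def n_other(states: np.ndarray, extra_col: np.ndarray) -> np.ndarray:
        base = np.select(
            [states == 0, states == 1, states == 2, states == 3, states == 4],
            [0, 0, 1, 1, 2],
        )
        grows = np.isin(states, [3, 4])  # AC, OC may carry more conditions
        return base + np.where(grows, extra_col, 0)

    df = pd.DataFrame(
        {
            "id": [f"p{k:06d}" for k in range(n)],
            "sex": np.where(female, "F", "M"),
            "completed_w6": completed6.astype(np.int64),
            "completed_w8": completed8.astype(np.int64),
            "ar_w6": ar_flag(s6),
            "ar_w8": ar_flag(s8),
            "n_other_w6": n_other(s6, extra[:, 0]),
            "n_other_w8": n_other(s8, extra[:, 1]),
        }
    )
    for w, x, comp in ((6, x6, completed6), (8, x8, completed8)):
        block = pd.DataFrame(
            x, columns=symptom_columns(w), dtype="Int8", index=df.index
        )
        block[~comp] = pd.NA  # symptoms unobserved when the wave was missed
        df = pd.concat([df, block], axis=1)
    return df


# --- CSV round trip ---------------------------------------------------------

COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "sex",
    "completed_w6",
    "completed_w8",
    "ar_w6",
    "ar_w8",
    "n_other_w6",
    "n_other_w8",
    *symptom_columns(6),
    *symptom_columns(8),
)


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV (UTF-8, comma-separated, blank = missing)."""
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise CohortParseError(f"cohort frame lacks columns: {missing}")
    records.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortParseError` with a line number for malformed rows,
    and on schema violations (wrong columns, duplicate ids, symptom values
    outside {0,1}, or missing symptoms in a completed wave).
    """
    try:
        df = pd.read_csv(path, dtype={"id": str, "sex": str})
    except pd.errors.EmptyDataError:
        raise CohortParseError(f"{path}: empty file without header") from None
    if tuple(df.columns) != COHORT_COLUMNS:
        raise CohortParseError(
            f"{path}: expected {len(COHORT_COLUMNS)} columns "
            f"{list(COHORT_COLUMNS[:8])}..., got {list(df.columns)}"
        )
    if df.empty:
        for col in symptom_columns(6) + symptom_columns(8):
            df[col] = df[col].astype("Int8")
        return df
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise CohortParseError(f"{path}: duplicate respondent id {dup!r}")

    def _bad_row(col: str, mask: pd.Series, why: str) -> None:
        row = int(mask.idxmax()) + 2  # header is line 1
        raise CohortParseError(f"{path}:{row}: {why} in column {col!r}")

    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        _bad_row("sex", bad_sex, "sex must be M or F")
    for col in ("completed_w6", "completed_w8", "ar_w6", "ar_w8"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            _bad_row(col, bad, "value must be 0 or 1")
    for col in ("n_other_w6", "n_other_w8"):
        bad = df[col].isna() | (df[col] < 0) | (df[col] != df[col].astype(int))
        if bad.any():
            _bad_row(col, bad, "value must be a nonnegative integer")
    for wave in (6, 8):
        comp = df[f"completed_w{wave}"] == 1
        for col in symptom_columns(wave):
            vals = df[col]
            bad = vals.notna() & ~vals.isin([0, 1])
            if bad.any():
                _bad_row(col, bad, "symptom must be 0, 1 or blank")
            bad = comp & vals.isna()
            if bad.any():
                _bad_row(col, bad, "missing symptom in a completed wave")
        df[symptom_columns(wave)] = df[symptom_columns(wave)].astype("Int8")
    for col in ("completed_w6", "completed_w8", "ar_w6", "ar_w8",
                "n_other_w6", "n_other_w8"):
        df[col] = df[col].astype(np.int64)
    return df
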