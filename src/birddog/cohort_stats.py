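"""Cohort-level validation statistics.

Reproduces the study-design analyses on any cohort table:

* Spearman rank correlations between each index and the therapists'
  qualitative clinical evaluation (TQCE).
* Standardized-coefficient OLS regression of TQCE on {SPB, AG, DT} versus
  DT alone, with the Spearman correlation of fitted values against TQCE as
  the model-comparison statistic.
* Test-time truncation: recompute the indices from the raw recordings for
  shortened test times and re-run the model comparison per time.
* ICC(2,1) interrater reliability (two-way random effects, absolute
  agreement, single measure) of the rater table.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ScoringConfig
from .errors import (
    CollinearityError,
    ConstantInputError,
    FormatError,
    MissingRatingError,
)
from .indices import CohortStandardizer, prepare_trial, trial_metrics
from .keypoint_io import TrialRecording

logger = logging.getLogger(__name__)

CV_PREDICTORS = ("SPB", "AG", "DT")
DT_PREDICTORS = ("DT",)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks.

    The p-value uses the t approximation with n-2 degrees of freedom; with
    ``exact=True`` (n <= 10 only) it is computed from the full permutation
    distribution of one margin instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("rank correlation of a constant sequence is undefined")
    rs, p = stats.spearmanr(x, y)
    rs, p = float(rs), float(p)
    if exact:
        n = len(x)
        if n > 10:
            raise ValueError(f"exact permutation p-value only supported for n <= 10, got {n}")
        rx = stats.rankdata(x) - (n + 1) / 2.0
        ry = stats.rankdata(y) - (n + 1) / 2.0
        perms = np.array(list(itertools.permutations(range(n))))
        rs_all = (ry[perms] @ rx) / (np.linalg.norm(rx) * np.linalg.norm(ry))
        p = float(np.mean(np.abs(rs_all) >= abs(rs) - 1e-12))
    return rs, p


# ---------------------------------------------------------------------------
# Regression models
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """A fitted TQCE model with coefficients on the standardized scale.

    ``beta``/``se`` are from the fit of z-scored response on z-scored
    predictors (so a single-predictor beta equals the Pearson correlation);
    ``raw_beta``/``raw_se``/``intercept`` are on the original scale for
    transparency.  ``fitted`` are predicted TQCE values on the original
    scale.
    """

    predictors: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    adj_r2: float
    r2: float
    fitted: np.ndarray
    raw_beta: np.ndarray = field(default=None)  # type: ignore[assignment]
    raw_se: np.ndarray = field(default=None)  # type: ignore[assignment]
    intercept: float = float("nan")
    n: int = 0


def _zscore_cols(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def fit_model(table: pd.DataFrame, predictors=CV_PREDICTORS, response: str = "TQCE") -> RegressionResult:
    """OLS of TQCE on the given predictors with standardized coefficients.

    Response and predictors are z-scored (sample sd) before the fit, which
    makes the slope coefficients standardized betas; adjusted R^2 is
    1 - (1 - R^2)(n - 1)/(n - p - 1).

    Raises
    ------
    CollinearityError
        If the z-scored design matrix has condition number above 1e8.
    """
    predictors = tuple(predictors)
    missing = [c for c in (*predictors, response) if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table lacks column(s) {missing}")
    n = len(table)
    if n < len(predictors) + 2:
        raise ValueError(f"need at least {len(predictors) + 2} trials, got {n}")

    X = table.loc[:, list(predictors)].astype(float)
    y = table[response].astype(float)
    Xz = _zscore_cols(X)
    if np.linalg.cond(Xz.to_numpy()) > 1e8:
        raise CollinearityError(f"predictors {predictors} are numerically collinear")
    yz = (y - y.mean()) / y.std(ddof=1)

    fit_z = sm.OLS(yz.to_numpy(), sm.add_constant(Xz.to_numpy())).fit()
    fit_raw = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    return RegressionResult(
        predictors=predictors,
        beta=fit_z.params[1:].copy(),
        se=fit_z.bse[1:].copy(),
        adj_r2=float(fit_z.rsquared_adj),
        r2=float(fit_z.rsquared),
        fitted=fit_raw.fittedvalues.copy(),
        raw_beta=fit_raw.params[1:].copy(),
        raw_se=fit_raw.bse[1:].copy(),
        intercept=float(fit_raw.params[0]),
        n=n,
    )


def predicted_correlation(result: RegressionResult, table: pd.DataFrame, response: str = "TQCE") -> tuple[float, float]:
    """Spearman correlation between a model's fitted values and TQCE."""
    return spearman(result.fitted, table[response].astype(float))


# ---------------------------------------------------------------------------
# Test-time truncation
# ---------------------------------------------------------------------------

@dataclass
class TruncationCurve:
    """Model-vs-TQCE correlation as a function of allowed test time."""

    times: tuple[float, ...]
    r_cv: tuple[float, ...]
    p_cv: tuple[float, ...]
    r_dt: tuple[float, ...]
    p_dt: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_time_s": self.times,
                "r_cv": self.r_cv,
                "p_cv": self.p_cv,
                "r_dt": self.r_dt,
                "p_dt": self.p_dt,
            }
        )


DEFAULT_TRUNCATION_TIMES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def truncate_and_reanalyze(
    recordings: list[TrialRecording],
    tqce,
    times=DEFAULT_TRUNCATION_TIMES,
    config: ScoringConfig | None = None,
    restandardize: bool = True,
) -> TruncationCurve:
    """Re-run the model comparison for shortened test times.

    For each time T the per-trial indices are *recomputed* on the frames up
    to min(fall, T) past the posture start — DT is capped at T and D'/a are
    measured inside the truncated window — and both models are refitted.
    TQCE keeps its full-observation value throughout (the human ratings are
    not re-collected).  With ``restandardize=True`` (default) SPB/AG are
    z-scored within each truncated cohort; otherwise the full-length
    cohort's mu/sigma are reused.

    Times above the task cap are clipped to the cap with a warning.
    """
    config = config or ScoringConfig()
    tqce = np.asarray(tqce, dtype=float)
    if len(tqce) != len(recordings):
        raise ValueError("tqce must have one value per recording")

    prepared = [prepare_trial(rec, config) for rec in recordings]

    std_spb = std_ag = None
    if not restandardize:
        full = [trial_metrics(p, config) for p in prepared]
        std_spb = CohortStandardizer.fit(
            np.log(1.0 / np.maximum([m["D_prime"] for m in full], config.d_prime_floor))
        )
        std_ag = CohortStandardizer.fit([m["a_raw"] for m in full])

    r_cv, p_cv, r_dt, p_dt, used_times = [], [], [], [], []
    for t in times:
        if t > config.task_cap_s:
            logger.warning("truncation time %g s exceeds task cap %g s; clipping", t, config.task_cap_s)
            t = config.task_cap_s
        used_times.append(float(t))
        metrics = [trial_metrics(p, config, test_time_s=t) for p in prepared]
        table = pd.DataFrame(
            {
                "DT": [m["DT"] for m in metrics],
                "D_prime": [m["D_prime"] for m in metrics],
                "a_raw": [m["a_raw"] for m in metrics],
                "TQCE": tqce,
            }
        )
        log_inv = np.log(1.0 / np.maximum(table["D_prime"], config.d_prime_floor))
        if restandardize:
            table["SPB"] = CohortStandardizer.fit(log_inv)(log_inv)
            table["AG"] = CohortStandardizer.fit(table["a_raw"])(table["a_raw"])
        else:
            table["SPB"] = std_spb(log_inv)
            table["AG"] = std_ag(table["a_raw"])

        cv = fit_model(table, CV_PREDICTORS)
        dt = fit_model(table, DT_PREDICTORS)
        rc, pc = predicted_correlation(cv, table)
        rd, pdt = predicted_correlation(dt, table)
        r_cv.append(rc)
        p_cv.append(pc)
        r_dt.append(rd)
        p_dt.append(pdt)

    return TruncationCurve(
        times=tuple(used_times),
        r_cv=tuple(r_cv), p_cv=tuple(p_cv),
        r_dt=tuple(r_dt), p_dt=tuple(p_dt),
    )


# ---------------------------------------------------------------------------
# Interrater reliability
# ---------------------------------------------------------------------------

def icc_2_1(ratings: pd.DataFrame) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a complete trials-by-raters table (one row per trial, one
    column per rater).
    """
    if ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError(f"need >= 2 trials and >= 2 raters, got {ratings.shape}")
    if ratings.isna().to_numpy().any():
        bad = ratings.index[ratings.isna().any(axis=1)].tolist()
        raise MissingRatingError(f"missing ratings for trial(s) {bad}")
    import pingouin as pg  # deferred: pingouin's import pulls in plotting stacks

    long = ratings.reset_index(names="trial").melt(
        id_vars="trial", var_name="rater", value_name="score"
    )
    import warnings

    with warnings.catch_warnings():
        # zero error variance (identical raters) makes pingouin's CI math
        # divide by zero; the point estimate is still exact
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="trial", raters="rater", ratings="score"
        ).set_index("Type")
    # ICC(A,1): two-way, absolute agreement, single rater == ICC(2,1)
    return float(table.loc["ICC(A,1)", "ICC"])


# ---------------------------------------------------------------------------
# Cohort table assembly
# ---------------------------------------------------------------------------

def build_cohort_table(indices_df: pd.DataFrame, ratings_df: pd.DataFrame) -> pd.DataFrame:
    """Join per-trial indices with rater scores on (participant_id, side).

    ``ratings_df`` must carry participant_id, side and rater columns named
    ``r1..rK`` (or a precomputed ``TQCE``).  TQCE is the across-rater mean
    and must land in [1, 7].
    """
    keys = ["participant_id", "side"]
    for df, name in ((indices_df, "indices"), (ratings_df, "ratings")):
        missing = [k for k in keys if k not in df.columns]
        if missing:
            raise FormatError(f"{name} table lacks column(s) {missing}")
    merged = indices_df.merge(ratings_df, on=keys, how="outer", indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", keys]
    if len(unmatched):
        ids = [tuple(r) for r in unmatched.itertuples(index=False)]
        raise FormatError(f"indices and ratings tables do not match for {ids}")
    merged = merged.drop(columns="_merge")

    rater_cols = sorted(c for c in ratings_df.columns if c.startswith("r") and c[1:].isdigit())
    if rater_cols:
        if merged[rater_cols].isna().to_numpy().any():
            raise MissingRatingError("rater columns contain missing values")
        merged["TQCE"] = merged[rater_cols].mean(axis=1)
    if "TQCE" not in merged.columns:
        raise FormatError("ratings table must carry rater columns r1..rK or a TQCE column")
    tq = merged["TQCE"].astype(float)
    if tq.isna().any() or (tq < 1).any() or (tq > 7).any():
        raise FormatError("TQCE must lie in [1, 7] with no missing values")
    return merged


def correlation_table(cohort: pd.DataFrame, indices=("SPB", "AG", "DT")) -> pd.DataFrame:
    """Spearman correlation of each index with TQCE (the analysis-1 table)."""
    rows = []
    for name in indices:
        rs, p = spearman(cohort[name].astype(float), cohort["TQCE"].astype(float))
        rows.append({"index": name, "rs": rs, "p": p, "n": len(cohort)})
    return pd.DataFrame(rows)


def regression_table(cv: RegressionResult, dt: RegressionResult) -> pd.DataFrame:
    """Side-by-side standardized-coefficient table for the two models."""
    rows = []
    for name in CV_PREDICTORS:
        row = {"variable": name}
        if name in cv.predictors:
            i = cv.predictors.index(name)
            row["beta_cv"], row["se_cv"] = float(cv.beta[i]), float(cv.se[i])
        else:
            row["beta_cv"] = row["se_cv"] = math.nan
        if name in dt.predictors:
            i = dt.predictors.index(name)
            row["beta_dt"], row["se_dt"] = float(dt.beta[i]), float(dt.se[i])
        else:
            row["beta_dt"] = row["se_dt"] = math.nan
        rows.append(row)
    rows.append(
        {
            "variable": "adj_R2",
            "beta_cv": cv.adj_r2, "se_cv": math.nan,
            "beta_dt": dt.adj_r2, "se_dt": math.nan,
        }
    )
    return pd.DataFrame(rows)
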