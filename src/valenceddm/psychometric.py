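"""Logistic psychometric function linking evidence strength to judgments.

The function fitted per (group, TV-desirability) condition is

    P(TV) = 1 / (1 + exp(-(beta1 * X - beta0)))

where X is the centered proportion of TV items observed on a trial (0.5
when every item was a TV, -0.5 when every item was a phone), beta1 is the
slope and beta0 the indifference parameter: P(TV) = 0.5 exactly at
X = beta0 / beta1.

Note on sign conventions: the formula above is implemented verbatim.  Under
it a *larger* beta0 shifts the curve right (more TV evidence needed); the
task literature sometimes describes the direction of beta0 shifts
informally in the opposite sense, so comparisons across reports should be
made on the indifference point beta0/beta1, not on prose descriptions.

Fitting is pooled maximum likelihood per condition (statsmodels Logit) with
subject-resampling (cluster) bootstrap confidence intervals; complete
separation falls back to a small ridge penalty on the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from .simulate import BehavioralDataset

__all__ = ["EvidenceStrength", "PsychometricFit", "center_evidence",
           "predict", "fit_psychometric", "indifference_point",
           "fit_all_conditions"]


@dataclass(frozen=True)
class EvidenceStrength:
    """Centered TV proportion observed in a trial, in [-0.5, 0.5]."""

    x_centered: float

    def __post_init__(self) -> None:
        if not -0.5 <= self.x_centered <= 0.5:
            raise ValueError("centered evidence must lie in [-0.5, 0.5]")


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted logistic parameters for one condition with bootstrap CIs."""

    beta0: float
    beta1: float
    ci_beta0: tuple
    ci_beta1: tuple
    condition: tuple  # (group, tv_desirable)
    n_trials: int = 0
    n_subjects: int = 0
    penalized: bool = False

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            warnings.warn(
                "fitted slope is not positive; task-consistent data should "
                "yield increasing psychometric functions", UserWarning,
                stacklevel=2)


def center_evidence(trial) -> EvidenceStrength:
    """Centered proportion of TV items: n_tv / n_observed - 0.5.

    ``trial`` may be anything exposing ``n_tv_observed``/``n_observed``
    (a TrialRecord, a DataFrame row) or an ``(n_tv, n_observed)`` pair.
    """
    if isinstance(trial, (tuple, list)):
        n_tv, n_obs = trial
    else:
        get = trial.get if hasattr(trial, "get") else \
            lambda k: getattr(trial, k)
        n_tv, n_obs = get("n_tv_observed"), get("n_observed")
    if n_obs < 1:
        raise ValueError("n_observed must be >= 1")
    if not 0 <= n_tv <= n_obs:
        raise ValueError("n_tv_observed must lie in [0, n_observed]")
    return EvidenceStrength(n_tv / n_obs - 0.5)


def _betas(fit) -> tuple[float, float]:
    if isinstance(fit, PsychometricFit):
        return fit.beta0, fit.beta1
    return float(fit[0]), float(fit[1])


def predict(fit, x) -> float | np.ndarray:
    """P(TV judgment) at evidence x: logistic of (beta1 * x - beta0)."""
    beta0, beta1 = _betas(fit)
    if not np.isfinite([beta0, beta1]).all():
        raise ValueError("psychometric parameters must be finite")
    xv = x.x_centered if isinstance(x, EvidenceStrength) else x
    return expit(beta1 * np.asarray(xv, dtype=float) - beta0)


def indifference_point(fit) -> float:
    """Evidence level at which P(TV) = 0.5: beta0 / beta1."""
    beta0, beta1 = _betas(fit)
    if beta1 == 0:
        raise ValueError("indifference point undefined for zero slope")
    return beta0 / beta1


def _judged_tv(df: pd.DataFrame) -> np.ndarray:
    choice_desirable = (df["choice"] == "desirable").to_numpy()
    tv_des = df["tv_desirable"].to_numpy().astype(bool)
    return (choice_desirable == tv_des).astype(float)


def _mle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pooled logistic MLE; returns (beta0, beta1, penalized)."""
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        c0, c1 = res.params
        if np.isfinite([c0, c1]).all() and abs(c1) < 500 and abs(c0) < 100:
            return float(-c0), float(c1), False
    except Exception:
        pass
    # separation: small ridge penalty, mostly on the slope
    def nll(b):
        eta = b[1] * x - b[0]
        return (np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta)
                + 1e-3 * b[1] ** 2 + 1e-4 * b[0] ** 2)
    opt = minimize(nll, x0=np.array([0.0, 1.0]), method="BFGS")
    return float(opt.x[0]), float(opt.x[1]), True


def fit_psychometric(trials, condition: tuple | None = None,
                     n_boot: int = 200, seed: int = 0,
                     ci_level: float = 0.95) -> PsychometricFit:
    """Fit the logistic psychometric function for one condition.

    ``trials`` is a trial table (BehavioralDataset or DataFrame);
    ``condition = (group, tv_desirable)`` filters it (None uses all rows).
    Confidence intervals are percentile intervals over ``n_boot``
    subject-resampling bootstrap replicates.  Fits with complete separation
    are ridge-penalized and flagged.
    """
    df = trials.df if isinstance(trials, BehavioralDataset) else trials
    if condition is not None:
        grp, tvd = condition
        df = df[(df["group"] == grp) & (df["tv_desirable"] == int(tvd))]
    if len(df) == 0:
        raise ValueError(f"no trials in condition {condition}")
    x = (df["n_tv_observed"] / df["n_observed"] - 0.5).to_numpy(float)
    y = _judged_tv(df)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct evidence levels")
    if np.unique(y).size < 2:
        warnings.warn("only one response category present; fit is "
                      "separated and penalized", UserWarning, stacklevel=2)
    beta0, beta1, pen = _mle(x, y)
    if pen:
        warnings.warn("complete separation detected; returning penalized "
                      "fit", UserWarning, stacklevel=2)

    subjects = df["subject_id"].unique()
    rng = np.random.default_rng(seed)
    groups = {sid: np.flatnonzero(df["subject_id"].to_numpy() == sid)
              for sid in subjects}
    b0s, b1s = [], []
    for _ in range(n_boot):
        take = rng.choice(subjects, size=subjects.size, replace=True)
        idx = np.concatenate([groups[sid] for sid in take])
        xb, yb = x[idx], y[idx]
        if np.unique(xb).size < 2 or np.unique(yb).size < 2:
            continue
        b0, b1, _ = _mle(xb, yb)
        b0s.append(b0)
        b1s.append(b1)
    alpha = (1 - ci_level) / 2
    if len(b0s) >= 10:
        ci0 = (float(np.quantile(b0s, alpha)),
               float(np.quantile(b0s, 1 - alpha)))
        ci1 = (float(np.quantile(b1s, alpha)),
               float(np.quantile(b1s, 1 - alpha)))
    else:
        ci0 = (np.nan, np.nan)
        ci1 = (np.nan, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        fit = PsychometricFit(beta0=beta0, beta1=beta1, ci_beta0=ci0,
                              ci_beta1=ci1,
                              condition=condition or ("all", None),
                              n_trials=len(df), n_subjects=subjects.size,
                              penalized=pen)
    if beta1 <= 0:
        warnings.warn("fitted slope is not positive", UserWarning,
                      stacklevel=2)
    return fit


def fit_all_conditions(trials, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Fit every (group, tv_desirable) cell present in the data; returns a
    per-condition table with beta0, beta1, CIs and sample sizes."""
    df = trials.df if isinstance(trials, BehavioralDataset) else trials
    rows = []
    for grp in sorted(df["group"].unique()):
        for tvd in sorted(df["tv_desirable"].unique()):
            sub = df[(df["group"] == grp) & (df["tv_desirable"] == tvd)]
            if len(sub) == 0:
                continue
            f = fit_psychometric(sub, None, n_boot=n_boot, seed=seed)
            rows.append({
                "group": grp, "tv_desirable": tvd,
                "beta0": f.beta0, "beta1": f.beta1,
                "beta0_lo": f.ci_beta0[0], "beta0_hi": f.ci_beta0[1],
                "beta1_lo": f.ci_beta1[0], "beta1_hi": f.ci_beta1[1],
                "indifference": indifference_point(f),
                "n_trials": f.n_trials, "n_subjects": f.n_subjects,
                "penalized": f.penalized,
            })
    return pd.DataFrame(rows)
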