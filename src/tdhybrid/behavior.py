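"""Behavioral statistics: accuracy, chance tests, model-weight regressions.

Accuracy is the proportion of valid choices matching the action with the
greater exact probability of eventual reward, excluding each active state's
first (informationless) encounter per block, error trials, and blocks where
both actions are exactly tied.  Model-derived analyses regress choices and
reaction times on differences in the fitted model's net action weights,
normalized per subject by the maximum absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import TIE_SENTINEL, TaskSpec, better_action

__all__ = [
    "AccuracyResult",
    "RegressionResult",
    "accuracy_score",
    "binomial_chance_test",
    "choice_weight_logistic",
    "stay_switch_logistic",
    "rt_weight_regression",
    "choice_curve",
    "CHOICE_CURVE_EDGES",
    "one_sample_one_tailed_t",
    "behavior_report",
]


class AccuracyResult(NamedTuple):
    accuracy: float
    n_scored: int
    n_correct: int
    n_excluded_first: int
    n_excluded_error: int
    n_excluded_tie: int


def accuracy_score(
    session: pd.DataFrame,
    task_spec: TaskSpec,
    exclude_first_encounter_per_block: bool = True,
) -> AccuracyResult:
    """Proportion of scored choices matching the objectively better action.

    With ``exclude_first_encounter_per_block`` (default) the first completed
    visit to each active state is excluded anew after every reversal, since
    contingencies reset; otherwise only the session-initial encounters are
    excluded.
    """
    best_cache: dict = {}
    seen: set = set()
    scored = correct = n_first = n_err = n_tie = 0
    for tt, blk, state, action, err in zip(
        session["trial_type"], session["block_index"], session["first_state"],
        session["action"], session["error_flag"],
    ):
        if tt != "active":
            continue
        if err != "none":
            n_err += 1
            continue
        block = int(blk)
        key = (block, state)
        if key not in best_cache:
            best_cache[key] = better_action(task_spec, block, state)
        best = best_cache[key]
        if best == TIE_SENTINEL:
            n_tie += 1
            continue
        enc_key = key if exclude_first_encounter_per_block else state
        if enc_key not in seen:
            seen.add(enc_key)
            n_first += 1
            continue
        scored += 1
        correct += int(action == best)
    if scored == 0:
        raise ValueError("no scorable choices in session")
    return AccuracyResult(correct / scored, scored, correct, n_first, n_err, n_tie)


def binomial_chance_test(n_correct: int, n_scored: int) -> float:
    """Exact one-tailed binomial p-value, P(X >= n_correct | p = 0.5)."""
    if n_scored < 1:
        raise ValueError("need at least one scored choice")
    return stats.binomtest(n_correct, n_scored, 0.5, alternative="greater").pvalue


@dataclass
class RegressionResult:
    """``coef`` is the tested coefficient; ``slope`` carries the weight-
    difference slope when the tested coefficient is the intercept."""

    coef: float
    se: float
    t: float
    p_one_tailed: float  # tail toward the sign predicted by the model
    n: int
    intercept: float
    slope: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "coef": self.coef,
            "se": self.se,
            "t": self.t,
            "p_one_tailed": self.p_one_tailed,
            "n": self.n,
            "intercept": self.intercept,
            "slope": self.slope,
        }


def _one_tailed(t: float, p_two: float, positive: bool) -> float:
    if (t > 0) == positive:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


def _normalize(x: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(x))
    if m == 0 or not np.isfinite(m):
        raise ValueError("degenerate predictor: all weight differences are zero")
    return x / m


def choice_weight_logistic(session: pd.DataFrame, trace) -> RegressionResult:
    """Logistic regression of right-action choice on the normalized
    right-minus-left net action weight difference (intercept included)."""
    ch = trace.choices
    if len(ch) == 0:
        raise ValueError("no choices in trace")
    y = (ch["action"] == "R").to_numpy(dtype=float)
    x = _normalize((ch["W_R"] - ch["W_L"]).to_numpy(dtype=float))
    X = sm.add_constant(x)
    fit = sm.Logit(y, X).fit(disp=0, method="lbfgs", maxiter=500)
    return RegressionResult(
        coef=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p_one_tailed=_one_tailed(float(fit.tvalues[1]), float(fit.pvalues[1]), True),
        n=len(y),
        intercept=float(fit.params[0]),
    )


def stay_switch_logistic(session: pd.DataFrame, trace) -> RegressionResult:
    """Logistic regression of staying (repeating the previous action in the
    current state) on the normalized stay-minus-switch net weight difference.
    A positive coefficient evidences weight-independent perseveration."""
    ch = trace.choices
    prev: dict = {}
    ys, xs = [], []
    for _, row in ch.iterrows():
        state = row["state"]
        if state in prev:
            stay_action = prev[state]
            w_stay = row["W_L"] if stay_action == "L" else row["W_R"]
            w_switch = row["W_R"] if stay_action == "L" else row["W_L"]
            ys.append(float(row["action"] == stay_action))
            xs.append(w_stay - w_switch)
        prev[state] = row["action"]
    if not ys:
        raise ValueError("no repeat visits to any active state")
    x = np.asarray(xs)
    m = np.max(np.abs(x))
    x = x / m if m > 0 else x
    X = sm.add_constant(x, has_constant="add")
    fit = sm.Logit(np.asarray(ys), X).fit(disp=0, method="lbfgs", maxiter=500)
    # the intercept is the weight-independent stay tendency (perseveration)
    return RegressionResult(
        coef=float(fit.params[0]),
        se=float(fit.bse[0]),
        t=float(fit.tvalues[0]),
        p_one_tailed=_one_tailed(float(fit.tvalues[0]), float(fit.pvalues[0]), True),
        n=len(ys),
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
    )


def rt_weight_regression(
    session: pd.DataFrame, trace, rt_threshold_ms: float = 300.0
) -> RegressionResult:
    """Linear regression of RT on the normalized absolute net-weight
    difference; contaminant RTs below ``rt_threshold_ms`` are omitted.
    A negative slope means faster choices when the options separate."""
    ch = trace.choices
    rts = session.set_index("trial_index").loc[ch["trial"], "rt_ms"].to_numpy(dtype=float)
    dw = np.abs((ch["W_R"] - ch["W_L"]).to_numpy(dtype=float))
    keep = np.isfinite(rts) & (rts >= rt_threshold_ms)
    if not keep.any():
        raise ValueError("no RTs remain after the contaminant cutoff")
    rts, dw = rts[keep], dw[keep]
    x = _normalize(dw)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: |dW| is constant")
    fit = sm.OLS(rts, sm.add_constant(x)).fit()
    return RegressionResult(
        coef=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p_one_tailed=_one_tailed(float(fit.tvalues[1]), float(fit.pvalues[1]), False),
        n=int(keep.sum()),
        intercept=float(fit.params[0]),
    )


#: Bin edges on the normalized weight difference: edge bins span 0.3 of the
#: maximum, inner bins 0.2.
CHOICE_CURVE_EDGES = (-1.0, -0.7, -0.5, -0.3, -0.1, 0.1, 0.3, 0.5, 0.7, 1.0)


def choice_curve(
    choices: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    edges: Sequence[float] = CHOICE_CURVE_EDGES,
) -> pd.DataFrame:
    """Binned probability of a right choice against the normalized net-weight
    difference.  ``choices`` is one subject's trace.choices frame or a list of
    them; with several subjects the bin means average per-subject means and
    the s.e.m. is across subjects.  Empty bins report NaN, not zero."""
    if isinstance(choices, pd.DataFrame):
        choices = [choices]
    edges = np.asarray(edges, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    per_subject = []
    counts = np.zeros(len(centers), dtype=int)
    for ch in choices:
        dw = _normalize((ch["W_R"] - ch["W_L"]).to_numpy(dtype=float))
        y = (ch["action"] == "R").to_numpy(dtype=float)
        idx = np.clip(np.searchsorted(edges, dw, side="right") - 1, 0, len(centers) - 1)
        means = np.full(len(centers), np.nan)
        for b in range(len(centers)):
            sel = idx == b
            counts[b] += int(sel.sum())
            if sel.any():
                means[b] = y[sel].mean()
        per_subject.append(means)
    arr = np.vstack(per_subject)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        n_sub = np.sum(np.isfinite(arr), axis=0)
        sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_sub, 1))
    sem[n_sub < 2] = np.nan
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "bin_center": centers,
            "n_obs": counts,
            "n_subjects": n_sub,
            "p_right": mean,
            "sem": sem,
        }
    )


def one_sample_one_tailed_t(
    values: Sequence[float], popmean: float = 0.0, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sample t test with a single tail; returns (t, p)."""
    res = stats.ttest_1samp(np.asarray(values, dtype=float), popmean, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def behavior_report(session: pd.DataFrame, trace, task_spec: TaskSpec) -> dict:
    """JSON-serializable per-subject behavioral summary."""
    acc = accuracy_score(session, task_spec)
    report: dict = {
        "accuracy": acc.accuracy,
        "n_scored": acc.n_scored,
        "n_correct": acc.n_correct,
        "n_excluded_first_encounter": acc.n_excluded_first,
        "n_excluded_error": acc.n_excluded_error,
        "n_excluded_tie": acc.n_excluded_tie,
        "p_chance": binomial_chance_test(acc.n_correct, acc.n_scored),
    }
    for key, fn in (
        ("choice_weight_logistic", choice_weight_logistic),
        ("stay_switch_logistic", stay_switch_logistic),
        ("rt_weight_regression", rt_weight_regression),
    ):
        try:
            report[key] = fn(session, trace).to_dict()
        except ValueError as exc:
            report[key] = {"error": str(exc)}
    curve = choice_curve(trace.choices)
    report["choice_curve"] = curve.to_dict(orient="list")
    return report
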