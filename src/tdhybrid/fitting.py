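"""Per-subject maximum-likelihood fitting and AICc model comparison.

Each model is fitted to one subject's valid choices by minimizing the
negative log-likelihood with Nelder-Mead restarts from randomized start
points.  Bounded parameters are optimized through an unconstrained
reparameterization (logistic transform for unit-interval parameters, log for
the temperature), so every candidate point the simplex visits is feasible.
Models are compared with the small-sample-corrected Akaike information
criterion, AICc = 2*NLL + 2k + 2k(k+1)/(n-k-1), where n counts valid choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import behavior
from .models import (
    COMPARISON_MODELS,
    MODEL_REGISTRY,
    ModelSpec,
    ParamVector,
    UNIT_PARAMS,
    encode_session,
    get_model,
    session_log_likelihood,
)

__all__ = [
    "FitResult",
    "ComparisonTable",
    "negative_log_likelihood",
    "fit_subject",
    "aicc",
    "compare_models",
    "sensitivity",
    "classify_subject",
]


# -- parameter transforms ---------------------------------------------------

_TAU_LOG_RANGE = (math.log(0.05), math.log(5.0))


def _to_unconstrained(name: str, value: float) -> float:
    if name in UNIT_PARAMS:
        v = min(max(value, 1e-9), 1 - 1e-9)
        return math.log(v / (1.0 - v))
    if name == "tau":
        return math.log(value)
    return value


def _from_unconstrained(name: str, x: float) -> float:
    if name in UNIT_PARAMS:
        if x >= 0:
            return 1.0 / (1.0 + math.exp(-x))
        e = math.exp(x)
        return e / (1.0 + e)
    if name == "tau":
        return math.exp(min(x, 50.0))
    return x


@dataclass
class FitResult:
    """Best fit of one model to one subject's session."""

    model: str
    params: ParamVector
    nll: float
    n_obs: int
    k: int
    aicc: float
    converged: bool
    restarts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.as_dict(),
            "nll": self.nll,
            "n_obs": self.n_obs,
            "k": self.k,
            "aicc": self.aicc,
            "converged": self.converged,
            "restarts": self.restarts,
        }


def negative_log_likelihood(
    model_spec: Union[str, ModelSpec],
    params: ParamVector,
    session: Union[pd.DataFrame, Sequence[tuple]],
) -> float:
    """-sum(log pi(chosen)) over valid choices; +inf for out-of-bounds params."""
    spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    enc = encode_session(session) if isinstance(session, pd.DataFrame) else list(session)
    if not any(e[0] for e in enc):
        raise ValueError("session contains no valid choices")
    if not params.in_bounds():
        return math.inf
    return -session_log_likelihood(spec, params, enc)


def aicc(nll: float, k: int, n_obs: int) -> float:
    """Akaike information criterion with finite-sample correction."""
    if n_obs <= k + 1:
        raise ValueError(f"AICc undefined for n={n_obs} <= k+1={k + 1}")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def _random_start(rng: np.random.Generator, free: Sequence[str]) -> np.ndarray:
    x0 = np.empty(len(free))
    for i, name in enumerate(free):
        if name in UNIT_PARAMS:
            x0[i] = rng.uniform(-2.5, 2.5)
        elif name == "tau":
            x0[i] = rng.uniform(*_TAU_LOG_RANGE)
        else:  # beta_r, beta_0
            x0[i] = rng.uniform(-1.0, 1.0)
    return x0


def fit_subject(
    model_spec: Union[str, ModelSpec],
    session: Union[pd.DataFrame, Sequence[tuple]],
    n_restarts: int = 20,
    seed: int = 0,
    xatol: float = 1e-6,
    fatol: float = 1e-8,
    maxfev: Optional[int] = None,
    x0: Optional[Sequence[float]] = None,
) -> FitResult:
    """Fit one model to one session by restarted Nelder-Mead.

    Start points are drawn uniformly in the unconstrained space under a
    dedicated generator seeded by ``seed``; passing ``x0`` adds a
    caller-supplied start (e.g. a previous optimum) to the restart set.
    Fully reproducible given ``seed``.
    """
    spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    enc = encode_session(session) if isinstance(session, pd.DataFrame) else list(session)
    n_obs = sum(e[0] for e in enc)
    if n_obs < 1:
        raise ValueError("session contains no valid choices")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    free = spec.free

    def objective(x: np.ndarray) -> float:
        pv = spec.params([_from_unconstrained(n, v) for n, v in zip(free, x)])
        return -session_log_likelihood(spec, pv, enc)

    rng = np.random.default_rng(seed)
    starts = [_random_start(rng, free) for _ in range(n_restarts)]
    if x0 is not None:
        starts.insert(0, np.asarray([_to_unconstrained(n, v) for n, v in zip(free, x0)]))

    options = {
        "xatol": xatol,
        "fatol": fatol,
        "maxfev": maxfev if maxfev is not None else 400 * len(free),
    }
    best = None
    log = []
    for i, start in enumerate(starts):
        res = minimize(objective, start, method="Nelder-Mead", options=options)
        log.append({"restart": i, "fun": float(res.fun), "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    def canonical(x: np.ndarray) -> np.ndarray:
        # round-trip through the clipped transform so saturated coordinates
        # land on the same finite point a refit from the optimum would use
        vals = [_from_unconstrained(n, v) for n, v in zip(free, x)]
        return np.asarray([_to_unconstrained(n, v) for n, v in zip(free, vals)])

    # polish: re-run from the winning point until the simplex can no longer
    # improve, so the returned optimum is idempotent under refitting
    for _ in range(3):
        res = minimize(objective, canonical(best.x), method="Nelder-Mead",
                       options=options)
        improved = res.fun < best.fun - 1e-9
        if res.fun < best.fun:
            best = res
        if not improved:
            break
    values = [_from_unconstrained(n, v) for n, v in zip(free, best.x)]
    pv = spec.params(values)
    nll = float(best.fun)
    return FitResult(
        model=spec.name,
        params=pv,
        nll=nll,
        n_obs=n_obs,
        k=spec.k,
        aicc=aicc(nll, spec.k, n_obs),
        converged=any(r["converged"] for r in log),
        restarts=log,
    )


@dataclass
class ComparisonTable:
    """Factorial model comparison over the 22 alternatives (plus null)."""

    table: pd.DataFrame  # long: subject, model, nll, aicc, k, d_aicc_hyst
    best: pd.DataFrame  # per subject: best model, class (MF / MB / MF+MB / HYST)
    summary: pd.DataFrame  # per model: mean residual fit vs HYST, raw & penalized

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _model_class(name: str) -> str:
    spec = MODEL_REGISTRY[name]
    if not spec.is_learning:
        return name  # HYST or NULL
    if spec.has_mb and (spec.has_critic or spec.has_q):
        return "MF+MB"
    return "MB" if spec.has_mb else "MF"


def compare_models(
    fits: Mapping[str, Mapping[str, FitResult]],
    models: Sequence[str] = COMPARISON_MODELS,
) -> ComparisonTable:
    """Assemble NLL/AICc tables, per-subject winners, and the group-level
    residual fit relative to the hysteresis benchmark.

    ``fits`` maps subject id -> model name -> :class:`FitResult`; every
    subject must carry all requested models.  AICc ties break toward the
    model with fewer free parameters.
    """
    rows = []
    best_rows = []
    for subject, per_model in fits.items():
        missing = [m for m in models if m not in per_model]
        if missing:
            raise ValueError(f"subject {subject!r} missing fits for {missing}")
        hyst = per_model.get("HYST")
        for m in models:
            f = per_model[m]
            rows.append(
                {
                    "subject": subject,
                    "model": m,
                    "nll": f.nll,
                    "k": f.k,
                    "aicc": f.aicc,
                    "d_nll_hyst": (hyst.nll - f.nll) if hyst else np.nan,
                    "d_aicc_hyst": (hyst.aicc - f.aicc) if hyst else np.nan,
                }
            )
        ranked = sorted(
            (m for m in models), key=lambda m: (per_model[m].aicc, per_model[m].k)
        )
        winner = ranked[0]
        best_rows.append(
            {"subject": subject, "best_model": winner, "class": _model_class(winner)}
        )
    table = pd.DataFrame(rows)
    best = pd.DataFrame(best_rows)
    summary = (
        table.groupby("model")
        .agg(
            mean_nll=("nll", "mean"),
            mean_aicc=("aicc", "mean"),
            mean_residual_raw=("d_nll_hyst", lambda s: 2 * s.mean()),
            mean_residual_penalized=("d_aicc_hyst", "mean"),
        )
        .reset_index()
    )
    return ComparisonTable(table=table, best=best, summary=summary)


def sensitivity(params: Union[ParamVector, Mapping[str, float]]) -> float:
    """Outcome sensitivity log(alpha * (1 + lambda) / tau).

    Zero balances the eligibility-adjusted learning rate against the
    temperature; alpha = 0 (absolute outcome insensitivity) maps to -inf.
    """
    if isinstance(params, ParamVector):
        alpha, lam, tau = params.alpha, params.lam, params.tau
    else:
        alpha, lam, tau = params["alpha"], params["lam"], params["tau"]
    if tau <= 0:
        raise ValueError("tau must be positive")
    if alpha == 0:
        return -math.inf
    return math.log(alpha * (1.0 + lam) / tau)


def classify_subject(
    session: pd.DataFrame,
    fits: Mapping[str, FitResult],
    task_spec,
    alpha_level: float = 0.05,
) -> str:
    """Good / Poor / Nonperformer grouping.

    Good: accuracy significantly above chance by a one-tailed binomial test;
    otherwise Poor; a Poor subject whose lowest AICc belongs to the
    hysteresis model is a Nonperformer (outcome-insensitive).
    """
    acc = behavior.accuracy_score(session, task_spec)
    p = behavior.binomial_chance_test(acc.n_correct, acc.n_scored)
    if p < alpha_level:
        return "good"
    if fits:
        winner = min(fits.values(), key=lambda f: (f.aicc, f.k))
        if winner.model == "HYST":
            return "nonperformer"
    return "poor"
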