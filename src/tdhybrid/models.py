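"""Nested family of reinforcement-learning models for the two-stage task.

The family spans four learning modules that can operate alone or in parallel:

- a *critic* caching state values ``V(s)`` taught by the state-value
  prediction error (SVPE) ``dV = r + V(s') - V(s)`` (discounting omitted,
  gamma = 1, because exactly one reward can occur per trial at a fixed delay);
- an *actor* whose policy preferences ``p(s, a)`` are taught by the same SVPE;
- a *Q-learner* caching action values ``Q(s, a)`` taught by the action-value
  prediction error (AVPE) ``dQ = r + max_a' Q(s', a') - Q(s, a)``, where
  action-less states carry a formal pseudoaction ``A0`` whose value aliases
  the state value, ``Q(s, A0) == V(s)``;
- a *model-based* planner learning the transition function ``T(s, a, s')``
  from state-prediction errors ``d* = 1 - T(s, a, s')`` and evaluating the
  Bellman optimality equation by backward induction on every trial.

Within a trial the TD(lambda) eligibility trace credits earlier states and
state-action pairs with weight ``alpha * lambda**n``; traces never cross
trial boundaries (each trial is one episode).  Choices follow a softmax over
net action weights ``W* = w_star * Q* + (1 - w_star) * (w_q * Q +
(1 - w_q) * p)`` augmented by a per-state perseveration bias (magnitude
``beta_0``, per-visit geometric decay with inverse rate ``lambda_beta``) and
a constant rightward bias ``beta_r``, all scaled by temperature ``tau``.

The registry enumerates 21 learning models (Q(0), AC(0/1/lambda),
CQ(0/1/lambda), ACQ(0/1/lambda), MB, and each model-free variant +MB), a
4-parameter hysteresis model with learning rates fixed at zero, and a null
intercept model with the single parameter P(A1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, MutableMapping, Sequence, Union

import pandas as pd

from .task import ACTIONS, FIRST_STATES, SECOND_STATES, TERMINAL_STATES

__all__ = [
    "ModelSpec",
    "ParamVector",
    "LatentTrace",
    "MODEL_REGISTRY",
    "COMPARISON_MODELS",
    "LEARNING_MODELS",
    "get_model",
    "normalize_model_name",
    "compute_svpe",
    "compute_avpe",
    "apply_eligibility_updates",
    "mb_observe",
    "mb_plan",
    "net_weights",
    "net_action_value",
    "net_avpe",
    "perseveration_bias",
    "action_probabilities",
    "Agent",
    "encode_session",
    "forward_pass",
    "session_log_likelihood",
]

# ---------------------------------------------------------------------------
# Parameters and model registry

#: Parameters constrained to the closed unit interval.
UNIT_PARAMS = ("alpha", "lam", "w_q", "alpha_star", "w_star", "lam_beta", "p_a1")
#: Order used for free-parameter vectors.
PARAM_ORDER = (
    "alpha",
    "lam",
    "w_q",
    "alpha_star",
    "w_star",
    "tau",
    "beta_r",
    "beta_0",
    "lam_beta",
    "p_a1",
)


@dataclass(frozen=True)
class ParamVector:
    """Full parameter vector; models fix a subset and free the rest.

    alpha: model-free learning rate; lam: eligibility; w_q: action-value
    weight; alpha_star: model-based learning rate; w_star: model-based
    weight; tau: softmax temperature; beta_r: rightward bias; beta_0:
    perseveration magnitude; lam_beta: perseveration inverse decay; p_a1:
    constant choice probability of the null intercept model.
    """

    alpha: float = 0.0
    lam: float = 0.0
    w_q: float = 0.0
    alpha_star: float = 0.0
    w_star: float = 0.0
    tau: float = 1.0
    beta_r: float = 0.0
    beta_0: float = 0.0
    lam_beta: float = 0.0
    p_a1: float = 0.5

    def validate(self) -> None:
        for name in UNIT_PARAMS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.tau > 0.0:
            raise ValueError(f"tau={self.tau} must be positive")

    def in_bounds(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ModelSpec:
    """One member of the nested family: active modules plus parameter mask."""

    name: str
    has_critic: bool
    has_actor: bool
    has_q: bool
    has_mb: bool
    free: tuple
    fixed: Mapping[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        """Number of free parameters (AICc degrees of freedom)."""
        return len(self.free)

    @property
    def is_learning(self) -> bool:
        return self.has_critic or self.has_q or self.has_mb

    @property
    def is_null(self) -> bool:
        return self.name == "NULL"

    def params(self, values: Union[Sequence[float], Mapping[str, float]]) -> ParamVector:
        """Build a full :class:`ParamVector` from free-parameter values."""
        if isinstance(values, Mapping):
            unknown = set(values) - set(self.free)
            if unknown:
                raise ValueError(f"parameters {sorted(unknown)} are not free in {self.name}")
            merged = {**self.fixed, **values}
        else:
            if len(values) != self.k:
                raise ValueError(f"{self.name} expects {self.k} values, got {len(values)}")
            merged = {**self.fixed, **dict(zip(self.free, values))}
        return ParamVector(**merged)


_POLICY_FREE = ("tau", "beta_r", "beta_0", "lam_beta")


def _mf_spec(base: str, suffix: str, with_mb: bool) -> ModelSpec:
    has_critic = base in ("AC", "CQ", "ACQ")
    has_actor = base in ("AC", "ACQ")
    has_q = base in ("Q", "CQ", "ACQ")
    free = ["alpha"]
    fixed: dict = {}
    if base == "Q":
        fixed["w_q"] = 1.0
        fixed["lam"] = 0.0
    else:
        if base == "AC":
            fixed["w_q"] = 0.0
        elif base == "CQ":
            fixed["w_q"] = 1.0
        else:  # ACQ
            free.append("w_q")
        if suffix == "lambda":
            free.append("lam")
        else:
            fixed["lam"] = float(suffix)
    if with_mb:
        free += ["alpha_star", "w_star"]
    else:
        fixed["alpha_star"] = 0.0
        fixed["w_star"] = 0.0
    free += list(_POLICY_FREE)
    name = base if base == "Q" else base
    label = f"{base}({suffix})" if base != "Q" else "Q(0)"
    if with_mb:
        label += "+MB"
    return ModelSpec(
        name=label,
        has_critic=has_critic,
        has_actor=has_actor,
        has_q=has_q,
        has_mb=with_mb,
        free=tuple(free),
        fixed=fixed,
    )


def _build_registry() -> dict:
    registry: dict[str, ModelSpec] = {}
    bases = [("Q", "0"), ("AC", "0"), ("AC", "1"), ("AC", "lambda"), ("CQ", "0"),
             ("CQ", "1"), ("CQ", "lambda"), ("ACQ", "0"), ("ACQ", "1"), ("ACQ", "lambda")]
    for base, suffix in bases:
        for with_mb in (False, True):
            spec = _mf_spec(base, suffix, with_mb)
            registry[spec.name] = spec
    registry["MB"] = ModelSpec(
        name="MB",
        has_critic=False,
        has_actor=False,
        has_q=False,
        has_mb=True,
        free=("alpha_star",) + _POLICY_FREE,
        fixed={"alpha": 0.0, "lam": 0.0, "w_q": 0.0, "w_star": 1.0},
    )
    registry["HYST"] = ModelSpec(
        name="HYST",
        has_critic=False,
        has_actor=False,
        has_q=False,
        has_mb=False,
        free=_POLICY_FREE,
        fixed={"alpha": 0.0, "lam": 0.0, "w_q": 0.0, "alpha_star": 0.0, "w_star": 0.0},
    )
    registry["NULL"] = ModelSpec(
        name="NULL",
        has_critic=False,
        has_actor=False,
        has_q=False,
        has_mb=False,
        free=("p_a1",),
        fixed={k: 0.0 for k in ("alpha", "lam", "w_q", "alpha_star", "w_star",
                                "beta_r", "beta_0", "lam_beta")} | {"tau": 1.0},
    )
    return registry


MODEL_REGISTRY: Mapping[str, ModelSpec] = _build_registry()
#: The 21 learning models.
LEARNING_MODELS = tuple(n for n, s in MODEL_REGISTRY.items() if s.is_learning)
#: The 22 alternatives entering the factorial comparison (learning + hysteresis).
COMPARISON_MODELS = LEARNING_MODELS + ("HYST",)


def normalize_model_name(name: str) -> str:
    name = name.strip().replace("λ", "lambda").replace(" ", "")
    name = name.replace("(L)", "(lambda)").replace("(l)", "(lambda)")
    upper = name.upper().replace("LAMBDA", "lambda")
    return upper


def get_model(name: str) -> ModelSpec:
    key = normalize_model_name(name)
    try:
        return MODEL_REGISTRY[key]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}") from None


# ---------------------------------------------------------------------------
# Primitive update rules (reference implementations over mappings)


def _state_value(V: Mapping[str, float], state: str) -> float:
    if state in TERMINAL_STATES:
        return 0.0
    if state not in V:
        raise KeyError(f"unknown state {state!r}")
    return V[state]


def compute_svpe(V: Mapping[str, float], s_t: str, s_next: str, r_next: float) -> float:
    """State-value prediction error ``dV = r + V(s') - V(s)`` (terminal V = 0)."""
    return r_next + _state_value(V, s_next) - _state_value(V, s_t)


def compute_avpe(
    Q: Mapping[tuple, float], s_t: str, a_t: str, s_next: str, r_next: float
) -> float:
    """Action-value prediction error ``dQ = r + max_a' Q(s', a') - Q(s, a)``.

    The max-term scans every ``(s_next, a)`` entry present in ``Q``; for an
    action-less successor this is the pseudoaction entry aliasing ``V``, and
    for a learner with no representation of the successor at all (pure Q(0))
    it is zero.
    """
    if (s_t, a_t) not in Q:
        raise KeyError(f"unknown state-action pair {(s_t, a_t)!r}")
    successors = [v for (s, _), v in Q.items() if s == s_next]
    bootstrap = max(successors) if successors else 0.0
    return r_next + bootstrap - Q[(s_t, a_t)]


def apply_eligibility_updates(
    values: MutableMapping, delta: float, alpha: float, lam: float, episode_steps: Sequence
) -> MutableMapping:
    """Credit each entry in ``episode_steps`` (most-recent-first) by
    ``alpha * lam**n * delta``.  Steps never reach before trial onset."""
    for n, key in enumerate(episode_steps):
        values[key] = values.get(key, 0.0) + alpha * lam**n * delta
    return values


def mb_observe(
    T_row: Mapping[str, float], s_next: str, alpha_star: float
) -> tuple[dict, float]:
    """Transition-row update from a state-prediction error.

    The observed successor's probability moves toward 1 by ``alpha_star *
    (1 - T)``; every other entry shrinks by the factor ``1 - alpha_star`` so
    the row still sums to 1.  Returns the new row and the SPE.
    """
    if s_next not in T_row:
        raise KeyError(f"{s_next!r} is not a feasible successor")
    delta = 1.0 - T_row[s_next]
    new_row = {
        s: (p + alpha_star * delta) if s == s_next else p * (1.0 - alpha_star)
        for s, p in T_row.items()
    }
    return new_row, delta


def mb_plan(
    T: Mapping[tuple, Mapping[str, float]], R: Mapping[str, float]
) -> dict:
    """Bellman backward induction over the episode DAG.

    ``Q*(s, a) = sum_s' T(s, a, s') * (R(s') + max_a' Q*(s', a'))`` with
    terminal values zero.  Rejects cyclic transition structures.
    """
    actions_of: dict[str, list] = {}
    for s, a in T:
        actions_of.setdefault(s, []).append(a)

    memo: dict[str, float] = {}
    visiting: set = set()

    def state_value(s: str) -> float:
        if s not in actions_of:
            return 0.0  # terminal
        if s in memo:
            return memo[s]
        if s in visiting:
            raise ValueError("cyclic state graph")
        visiting.add(s)
        memo[s] = max(pair_value(s, a) for a in actions_of[s])
        visiting.discard(s)
        return memo[s]

    def pair_value(s: str, a) -> float:
        return sum(p * (R.get(s2, 0.0) + state_value(s2)) for s2, p in T[(s, a)].items())

    return {(s, a): pair_value(s, a) for s, a in T}


def net_weights(p: float, Q: float, Q_star: float, w_q: float, w_star: float) -> tuple:
    """Net model-free weight ``W`` and net weight ``W*`` entering the softmax."""
    W = w_q * Q + (1.0 - w_q) * p
    return W, w_star * Q_star + (1.0 - w_star) * W


def net_action_value(Q: float, V: float, w_q: float) -> float:
    """Diagnostic net action value ``Q^V = w_q * Q + (1 - w_q) * V``."""
    return w_q * Q + (1.0 - w_q) * V


def net_avpe(dQ: float, dV: float, w_q: float) -> float:
    """Diagnostic net prediction error ``d(Q,V) = w_q * dQ + (1 - w_q) * dV``."""
    return w_q * dQ + (1.0 - w_q) * dV


def perseveration_bias(
    choice_history: Sequence[str], beta_0: float, lam_beta: float,
    actions: Sequence[str] = ACTIONS,
) -> dict:
    """Cumulative perseveration bias after the visits in ``choice_history``.

    ``choice_history`` is ordered oldest-first; the bias on action ``a`` is
    ``sum_n beta_0 * lam_beta**n`` over past visits where ``a`` was chosen,
    with ``n`` counting visits back from the most recent.
    """
    bias = {a: 0.0 for a in actions}
    for n, chosen in enumerate(reversed(choice_history)):
        bias[chosen] += beta_0 * lam_beta**n
    return bias


def action_probabilities(
    W_star: Mapping[str, float],
    biases: Mapping[str, float],
    beta_r: float,
    tau: float,
    right_action: str = "R",
) -> dict:
    """Softmax policy over actions with perseveration and side biases."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    logits = {
        a: (W_star[a] + biases.get(a, 0.0) + (beta_r if a == right_action else 0.0)) / tau
        for a in W_star
    }
    m = max(logits.values())
    exps = {a: math.exp(x - m) for a, x in logits.items()}
    z = sum(exps.values())
    return {a: e / z for a, e in exps.items()}


# ---------------------------------------------------------------------------
# Fast incremental agent used for likelihood evaluation and simulation

_S1_INDEX = {s: i for i, s in enumerate(FIRST_STATES)}
_S2_INDEX = {s: i for i, s in enumerate(SECOND_STATES)}
_A_INDEX = {"L": 0, "R": 1}
# V slots: 0-3 first-stage, 4-5 second-stage, 6 ITI, 7 passive cue, 8 active cue
_V_ITI, _V_CUE_P, _V_CUE_A = 6, 7, 8
V_STATE_NAMES = FIRST_STATES + SECOND_STATES + ("iti", "cue_passive", "cue_active")


class Agent:
    """Online learner: holds latents, emits choice probabilities, updates.

    The same object serves maximum-likelihood evaluation (choices fed from a
    session) and closed-loop simulation (choices sampled from the policy).
    """

    __slots__ = (
        "spec", "pv", "alpha", "lam", "w_q", "alpha_star", "w_star", "tau",
        "beta_r", "beta_0", "lam_beta", "p_a1", "V", "p", "Q", "bias", "C",
        "history", "Tp", "Ta", "T2", "qs_p", "qs_a", "qs_s",
    )

    def __init__(self, spec: ModelSpec, pv: ParamVector):
        pv.validate()
        self.spec = spec
        self.pv = pv
        self.alpha = pv.alpha
        self.lam = pv.lam
        self.w_q = pv.w_q
        self.alpha_star = pv.alpha_star
        self.w_star = pv.w_star if spec.has_mb else 0.0
        self.tau = pv.tau
        self.beta_r = pv.beta_r
        self.beta_0 = pv.beta_0
        self.lam_beta = pv.lam_beta
        self.p_a1 = pv.p_a1
        self.V = [0.0] * 9
        self.p = [[0.0, 0.0], [0.0, 0.0]]
        self.Q = [[0.0, 0.0], [0.0, 0.0]]
        self.bias = [[0.0, 0.0], [0.0, 0.0]]
        self.C = [0, 0]
        self.history: tuple[list, list] = ([], [])
        # transition function rows initialized to the uniform prior 1/2
        self.Tp = [[0.5, 0.5], [0.5, 0.5]]
        self.Ta = [[[0.5, 0.5], [0.5, 0.5]], [[0.5, 0.5], [0.5, 0.5]]]
        self.T2 = [[0.5, 0.5], [0.5, 0.5]]
        self.qs_s = [0.5, 0.5]
        self.qs_p = [0.5, 0.5]
        self.qs_a = [[0.5, 0.5], [0.5, 0.5]]

    # -- policy ------------------------------------------------------------

    def weights(self, fi: int) -> tuple:
        """(W_L, W_R, W*_L, W*_R) at active first-stage slot ``fi`` (2 or 3)."""
        ai = fi - 2
        wq, ws = self.w_q, self.w_star
        q, pr = self.Q[ai], self.p[ai]
        w_l = wq * q[0] + (1.0 - wq) * pr[0]
        w_r = wq * q[1] + (1.0 - wq) * pr[1]
        if self.spec.has_mb:
            qs = self.qs_a[ai]
            return w_l, w_r, ws * qs[0] + (1.0 - ws) * w_l, ws * qs[1] + (1.0 - ws) * w_r
        return w_l, w_r, w_l, w_r

    def policy(self, fi: int) -> tuple:
        """(pi_L, pi_R) at active first-stage slot ``fi``."""
        if self.spec.is_null:
            return self.p_a1, 1.0 - self.p_a1
        _, _, ws_l, ws_r = self.weights(fi)
        b = self.bias[fi - 2]
        x_l = (ws_l + b[0]) / self.tau
        x_r = (ws_r + b[1] + self.beta_r) / self.tau
        m = x_l if x_l > x_r else x_r
        e_l = math.exp(x_l - m)
        e_r = math.exp(x_r - m)
        z = e_l + e_r
        return e_l / z, e_r / z

    def register_choice(self, fi: int, a: int) -> None:
        """Perseveration bookkeeping after a completed choice at ``fi``."""
        ai = fi - 2
        b = self.bias[ai]
        lb = self.lam_beta
        b[0] *= lb
        b[1] *= lb
        b[a] += self.beta_0
        self.C[ai] += 1
        self.history[ai].append(a)

    # -- learning ----------------------------------------------------------

    def learn(self, active: int, fi: int, a: int, si: int, r: int,
              extended: bool = False) -> dict:
        """Apply one completed trial's updates; returns the emitted errors.

        ``extended`` chains ITI -> pre-trial cue -> first stage into the TD
        episode (extra critic states used only for fMRI regressors; choice
        probabilities and first/second-stage dynamics are unaffected).
        """
        spec = self.spec
        alpha, lam = self.alpha, self.lam
        V = self.V
        out: dict = {}
        ci = _V_CUE_A if active else _V_CUE_P
        if extended and spec.has_critic:
            d_cue = V[ci] - V[_V_ITI]
            V[_V_ITI] += alpha * d_cue
            d_first = V[fi] - V[ci]
            V[ci] += alpha * d_first
            V[_V_ITI] += alpha * lam * d_first
            out["dV_cue"] = d_cue
            out["dV_first"] = d_first
        v1 = V[fi]
        v2 = V[4 + si]
        ai = fi - 2
        # step 1: arrival at the second-stage state (no reward yet)
        if spec.has_critic:
            d_v1 = v2 - v1
            V[fi] += alpha * d_v1
            if extended:
                V[ci] += alpha * lam * d_v1
                V[_V_ITI] += alpha * lam * lam * d_v1
            if spec.has_actor and active:
                self.p[ai][a] += alpha * d_v1
            out["dV1"] = d_v1
        if spec.has_q and active:
            if spec.has_critic:
                d_q1 = v2 - self.Q[ai][a]
                self.Q[ai][a] += alpha * d_q1
                out["dQ1"] = d_q1
            # pure Q(0): no cached second-stage value, no step-1 update
        # step 2: arrival at the terminal outcome state
        if spec.has_critic:
            d_v2 = r - v2
            V[4 + si] += alpha * d_v2
            V[fi] += alpha * lam * d_v2
            if extended:
                V[ci] += alpha * lam * lam * d_v2
                V[_V_ITI] += alpha * lam ** 3 * d_v2
            if spec.has_actor and active:
                self.p[ai][a] += alpha * lam * d_v2
            out["dV2"] = d_v2
        if spec.has_q and active:
            if spec.has_critic:
                # AVPE at the action-less second stage: predictor is the
                # pseudoaction value Q(s2, A0) == V(s2); the eligibility trace
                # carries it back to the preceding real state-action pair.
                d_q2 = r - v2
                self.Q[ai][a] += alpha * lam * d_q2
            else:
                # pure Q(0) bridges the action-less gap: one update at outcome
                d_q2 = r - self.Q[ai][a]
                self.Q[ai][a] += alpha * d_q2
            out["dQ2"] = d_q2
        if spec.has_mb:
            as_ = self.alpha_star
            row = self.Ta[ai][a] if active else self.Tp[fi]
            out["dStar1"] = 1.0 - row[si]
            row[si] += as_ * out["dStar1"]
            row[1 - si] *= 1.0 - as_
            row2 = self.T2[si]
            j = 0 if r else 1
            out["dStar2"] = 1.0 - row2[j]
            row2[j] += as_ * out["dStar2"]
            row2[1 - j] *= 1.0 - as_
            self._replan()
        return out

    def _replan(self) -> None:
        """Backward induction over the two-step DAG (all pairs, every trial)."""
        qs = self.qs_s
        qs[0] = self.T2[0][0]
        qs[1] = self.T2[1][0]
        for i in (0, 1):
            tp = self.Tp[i]
            self.qs_p[i] = tp[0] * qs[0] + tp[1] * qs[1]
            for a in (0, 1):
                ta = self.Ta[i][a]
                self.qs_a[i][a] = ta[0] * qs[0] + ta[1] * qs[1]


# ---------------------------------------------------------------------------
# Session encoding and forward pass


def encode_session(session: pd.DataFrame) -> list:
    """Compact the valid trials of a session into ``(active, fi, a, si, r)``
    tuples for the likelihood loop.  Error trials carry no choice term and no
    updates (the trial aborts before any transition is shown), so they are
    dropped here."""
    enc = []
    for tt, fs, act, ss, rew, err in zip(
        session["trial_type"], session["first_state"], session["action"],
        session["second_state"], session["reward"], session["error_flag"],
    ):
        if err != "none":
            continue
        active = 1 if tt == "active" else 0
        a = _A_INDEX[act] if active else -1
        enc.append((active, _S1_INDEX[fs], a, _S2_INDEX[ss], int(rew)))
    return enc


def session_log_likelihood(spec: ModelSpec, pv: ParamVector, enc: Sequence[tuple]) -> float:
    """Sum of log choice probabilities over the valid active trials."""
    agent = Agent(spec, pv)
    ll = 0.0
    log = math.log
    for active, fi, a, si, r in enc:
        if active:
            pi_l, pi_r = agent.policy(fi)
            pr = pi_l if a == 0 else pi_r
            ll += log(pr if pr > 1e-300 else 1e-300)
            agent.register_choice(fi, a)
        agent.learn(active, fi, a, si, r)
    return ll


@dataclass
class LatentTrace:
    """Tidy per-event latents plus per-choice policy snapshot.

    ``events`` has one row per within-trial state arrival with the value
    estimates held on entry and the prediction errors emitted on arrival;
    ``choices`` has one row per valid active trial with both actions' net
    weights, biases and softmax probabilities at decision time.
    """

    events: pd.DataFrame
    choices: pd.DataFrame
    loglik: float

    def to_tsv(self, events_path, choices_path=None) -> None:
        self.events.to_csv(events_path, sep="\t", index=False, na_rep="")
        if choices_path is not None:
            self.choices.to_csv(choices_path, sep="\t", index=False, na_rep="")


_EVENT_COLS = ["trial", "step", "state", "action", "V", "Q", "p", "W", "Wstar",
               "dV", "dQ", "dStar"]


def forward_pass(
    model_spec: ModelSpec,
    params: ParamVector,
    session: pd.DataFrame,
    extended: bool = False,
) -> LatentTrace:
    """Replay a session through a model, recording latents and choice
    probabilities.  Deterministic; error trials contribute no events."""
    agent = Agent(model_spec, params)
    nan = float("nan")
    ev_rows: list = []
    ch_rows: list = []
    ll = 0.0
    for _, row in session.iterrows():
        if row["error_flag"] != "none":
            continue
        trial = int(row["trial_index"])
        active = 1 if row["trial_type"] == "active" else 0
        fi = _S1_INDEX[row["first_state"]]
        si = _S2_INDEX[row["second_state"]]
        r = int(row["reward"])
        a = _A_INDEX[row["action"]] if active else -1
        ai = fi - 2

        if extended:
            ci = _V_CUE_A if active else _V_CUE_P
            ev_rows.append((trial, "iti", "iti", None, agent.V[_V_ITI], nan, nan,
                            nan, nan, nan, nan, nan))
            cue_state = "cue_active" if active else "cue_passive"
            cue_v = agent.V[ci]
        v_first = agent.V[fi]
        v_second = agent.V[4 + si]

        if active:
            w_l, w_r, ws_l, ws_r = agent.weights(fi)
            pi_l, pi_r = agent.policy(fi)
            pr = pi_l if a == 0 else pi_r
            ll += math.log(max(pr, 1e-300))
            b = agent.bias[ai]
            ch_rows.append(
                (trial, row["first_state"], row["action"], w_l, w_r, ws_l, ws_r,
                 b[0], b[1], pi_l, pi_r, pr)
            )
            agent.register_choice(fi, a)
            q_here, p_here = agent.Q[ai][a], agent.p[ai][a]
            w_here, ws_here = (w_l, ws_l) if a == 0 else (w_r, ws_r)
        else:
            q_here = p_here = w_here = ws_here = nan

        deltas = agent.learn(active, fi, a, si, r, extended=extended)
        if extended:
            ev_rows.append((trial, "cue", cue_state, None, cue_v, nan, nan, nan,
                            nan, deltas.get("dV_cue", nan), nan, nan))
        ev_rows.append(
            (trial, "first", row["first_state"], row["action"] if active else None,
             v_first, q_here, p_here, w_here, ws_here,
             deltas.get("dV_first", nan), nan, nan)
        )
        ev_rows.append(
            (trial, "second", row["second_state"], None, v_second, nan, nan, nan,
             nan, deltas.get("dV1", nan), deltas.get("dQ1", nan),
             deltas.get("dStar1", nan))
        )
        ev_rows.append(
            (trial, "outcome", "reward" if r else "no_reward", None, 0.0, nan,
             nan, nan, nan, deltas.get("dV2", nan), deltas.get("dQ2", nan),
             deltas.get("dStar2", nan))
        )
    events = pd.DataFrame(ev_rows, columns=_EVENT_COLS)
    choices = pd.DataFrame(
        ch_rows,
        columns=["trial", "state", "action", "W_L", "W_R", "Wstar_L", "Wstar_R",
                 "bias_L", "bias_R", "pi_L", "pi_R", "pi_chosen"],
    )
    return LatentTrace(events=events, choices=choices, loglik=ll)
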