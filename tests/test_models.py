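"""Model-family primitives, forward-pass semantics, and nesting relations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdhybrid import models
from tdhybrid.models import (
    COMPARISON_MODELS,
    LEARNING_MODELS,
    MODEL_REGISTRY,
    Agent,
    ParamVector,
    action_probabilities,
    apply_eligibility_updates,
    compute_avpe,
    compute_svpe,
    encode_session,
    forward_pass,
    get_model,
    mb_observe,
    mb_plan,
    net_weights,
    perseveration_bias,
    session_log_likelihood,
)


def make_session(rows):
    """Build a minimal session frame from (type, first, action, second, reward)."""
    recs = []
    for i, (tt, fs, a, ss, r) in enumerate(rows):
        recs.append(
            {
                "trial_index": i,
                "trial_type": tt,
                "first_state": fs,
                "action": a,
                "second_state": ss,
                "reward": r,
                "error_flag": "none",
            }
        )
    return pd.DataFrame(recs)


class TestRegistry:
    def test_enumeration(self):
        assert len(LEARNING_MODELS) == 21
        assert len(COMPARISON_MODELS) == 22
        assert "HYST" in COMPARISON_MODELS and "NULL" not in COMPARISON_MODELS

    @pytest.mark.parametrize(
        "name,k",
        [("ACQ(lambda)", 7), ("ACQ(lambda)+MB", 9), ("HYST", 4), ("NULL", 1),
         ("MB", 5), ("Q(0)", 5), ("AC(lambda)", 6), ("CQ(1)", 5)],
    )
    def test_free_parameter_counts(self, name, k):
        assert get_model(name).k == k

    def test_name_normalization(self):
        assert get_model("ACQ(λ)+MB").name == "ACQ(lambda)+MB"

    def test_lambda_suffix_fixing(self):
        assert get_model("AC(0)").fixed["lam"] == 0.0
        assert get_model("AC(1)").fixed["lam"] == 1.0
        assert "lam" in get_model("AC(lambda)").free

    def test_param_bounds_enforced(self):
        with pytest.raises(ValueError):
            ParamVector(alpha=1.2).validate()
        with pytest.raises(ValueError):
            ParamVector(tau=0.0).validate()


class TestPrimitives:
    def test_svpe(self):
        assert compute_svpe({"s1": 0.0, "s2": 0.0}, "s1", "s2", 1.0) == 1.0
        assert compute_svpe({"s1": 0.2, "s2": 0.6}, "s1", "s2", 0.0) == pytest.approx(0.4)
        # terminal successor carries V = 0
        assert compute_svpe({"s2": 0.6}, "s2", "reward", 1.0) == pytest.approx(0.4)
        with pytest.raises(KeyError):
            compute_svpe({"s1": 0.0}, "s1", "unknown", 0.0)

    def test_avpe(self):
        assert compute_avpe({("s1", "a"): 0.0}, "s1", "a", "reward", 1.0) == 1.0
        # pseudoaction bootstrapping: max over successor entries equals V(s2)
        q = {("s1", "a"): 0.3, ("s2", "A0"): 0.5}
        assert compute_avpe(q, "s1", "a", "s2", 0.0) == pytest.approx(0.2)
        # pure Q(0): no successor representation, bridged at outcome
        assert compute_avpe({("s1", "a"): 0.3}, "s1", "a", "no_reward", 1.0) == pytest.approx(0.7)

    def test_eligibility_geometric_weights(self):
        v = {"s2": 0.0, "s1": 0.0}
        apply_eligibility_updates(v, 1.0, alpha=0.5, lam=0.5, episode_steps=["s2", "s1"])
        assert v == {"s2": 0.5, "s1": 0.25}

    def test_eligibility_lambda_limits(self):
        v0 = apply_eligibility_updates({}, 1.0, 0.5, 0.0, ["b", "a"])
        assert v0 == {"b": 0.5, "a": 0.0}
        v1 = apply_eligibility_updates({}, 1.0, 0.5, 1.0, ["b", "a"])
        assert v1 == {"b": 0.5, "a": 0.5}

    def test_mb_observe(self):
        row, d = mb_observe({"x": 0.5, "y": 0.5}, "x", 0.2)
        assert d == pytest.approx(0.5)
        assert row == pytest.approx({"x": 0.6, "y": 0.4})
        row0, d0 = mb_observe({"x": 0.3, "y": 0.7}, "x", 0.0)
        assert row0 == {"x": 0.3, "y": 0.7} and d0 == pytest.approx(0.7)
        with pytest.raises(KeyError):
            mb_observe({"x": 1.0}, "z", 0.1)

    def test_mb_observe_converges_and_keeps_rows_normalized(self):
        row = {"x": 0.5, "y": 0.5}
        for _ in range(20):
            row, _ = mb_observe(row, "x", 0.5)
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
        assert row["x"] == pytest.approx(1.0, abs=1e-5)

    def test_mb_plan_backward_induction(self):
        T = {
            ("active", "L"): {"sec1": 1.0, "sec2": 0.0},
            ("active", "R"): {"sec1": 0.0, "sec2": 1.0},
            ("sec1", "A0"): {"reward": 0.7, "no_reward": 0.3},
            ("sec2", "A0"): {"reward": 0.2, "no_reward": 0.8},
        }
        q = mb_plan(T, {"reward": 1.0})
        assert q[("active", "L")] == pytest.approx(0.7)
        assert q[("active", "R")] == pytest.approx(0.2)

    def test_mb_plan_uniform_prior_gives_half(self):
        T = {
            ("active", "L"): {"sec1": 0.5, "sec2": 0.5},
            ("active", "R"): {"sec1": 0.5, "sec2": 0.5},
            ("sec1", "A0"): {"reward": 0.5, "no_reward": 0.5},
            ("sec2", "A0"): {"reward": 0.5, "no_reward": 0.5},
        }
        q = mb_plan(T, {"reward": 1.0})
        assert all(v == pytest.approx(0.5) for v in q.values())

    def test_mb_plan_rejects_cycles(self):
        T = {("a", "x"): {"b": 1.0}, ("b", "x"): {"a": 1.0}}
        with pytest.raises(ValueError):
            mb_plan(T, {})

    def test_net_weights_limits(self):
        assert net_weights(p=0.2, Q=0.6, Q_star=0.9, w_q=0.0, w_star=0.0) == (0.2, 0.2)
        assert net_weights(0.2, 0.6, 0.9, 1.0, 0.0) == (0.6, 0.6)
        W, Ws = net_weights(0.2, 0.6, 0.9, 0.25, 0.5)
        assert W == pytest.approx(0.3)
        assert Ws == pytest.approx(0.5 * 0.9 + 0.5 * 0.3)

    def test_perseveration_bias(self):
        assert perseveration_bias([], 0.1, 0.5) == {"L": 0.0, "R": 0.0}
        assert perseveration_bias(["L"], 0.1, 0.5)["L"] == pytest.approx(0.1)
        b = perseveration_bias(["L", "L"], 0.1, 0.5)
        assert b["L"] == pytest.approx(0.15) and b["R"] == 0.0

    def test_perseveration_matches_incremental_agent(self):
        rng = np.random.default_rng(0)
        agent = Agent(get_model("HYST"), ParamVector(tau=1.0, beta_0=0.17, lam_beta=0.62))
        history = []
        for _ in range(30):
            a = int(rng.integers(2))
            agent.register_choice(2, a)
            history.append("L" if a == 0 else "R")
        ref = perseveration_bias(history, 0.17, 0.62)
        assert agent.bias[0][0] == pytest.approx(ref["L"], abs=1e-12)
        assert agent.bias[0][1] == pytest.approx(ref["R"], abs=1e-12)

    def test_softmax(self):
        assert action_probabilities({"L": 0.0, "R": 0.0}, {}, 0.0, 1.0) == {
            "L": 0.5,
            "R": 0.5,
        }
        pi = action_probabilities({"L": 0.0, "R": 1.0}, {}, 0.0, 1.0)
        assert pi["R"] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-6)
        pi_cold = action_probabilities({"L": 0.0, "R": 1.0}, {}, 0.0, 1e-4)
        assert pi_cold["R"] == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            action_probabilities({"L": 0.0, "R": 0.0}, {}, 0.0, 0.0)


class TestForwardPass:
    def test_hysteresis_keeps_values_at_zero(self, acq_session):
        spec = get_model("HYST")
        pv = spec.params({"tau": 0.5, "beta_r": 0.3, "beta_0": 0.4, "lam_beta": 0.9})
        trace = forward_pass(spec, pv, acq_session)
        for col in ("V", "Q", "p"):
            vals = trace.events[col].dropna()
            assert (vals == 0).all()
        # yet choices are still biased by perseveration/side terms
        assert trace.choices["pi_R"].std() > 0

    def test_null_model_constant_probability(self, acq_session):
        spec = get_model("NULL")
        trace = forward_pass(spec, spec.params({"p_a1": 0.8}), acq_session)
        assert (trace.choices["pi_L"] == 0.8).all()

    def test_policy_probabilities_sum_to_one(self, acq_session, acq_lambda,
                                             good_learner_params):
        trace = forward_pass(acq_lambda, good_learner_params, acq_session)
        assert np.allclose(trace.choices["pi_L"] + trace.choices["pi_R"], 1.0)

    def test_one_trial_convergence_alpha_lambda_one(self):
        # with alpha=1, lambda=1 every visited state's V equals the trial's return
        spec = get_model("AC(1)")
        pv = spec.params({"alpha": 1.0, "tau": 1.0, "beta_r": 0, "beta_0": 0,
                          "lam_beta": 0})
        session = make_session(
            [("passive", "passive_1", None, "second_1", 1),
             ("passive", "passive_1", None, "second_1", 0)]
        )
        agent = Agent(spec, pv)
        for active, fi, a, si, r in encode_session(session):
            agent.learn(active, fi, a, si, r)
            assert agent.V[fi] == r
            assert agent.V[4 + si] == r

    def test_error_trials_contribute_nothing(self, acq_lambda, good_learner_params):
        session = make_session(
            [("active", "active_1", "L", "second_1", 1),
             ("active", "active_2", "R", "second_2", 0)]
        )
        witherr = session.copy()
        err_row = {
            "trial_index": 2, "trial_type": "active", "first_state": "active_1",
            "action": None, "second_state": None, "reward": None,
            "error_flag": "missed",
        }
        witherr = pd.concat([witherr, pd.DataFrame([err_row])], ignore_index=True)
        t0 = forward_pass(acq_lambda, good_learner_params, session)
        t1 = forward_pass(acq_lambda, good_learner_params, witherr)
        assert t0.loglik == t1.loglik
        assert len(t0.events) == len(t1.events)

    def test_transition_rows_stay_normalized_during_learning(self, acq_session):
        spec = get_model("ACQ(lambda)+MB")
        pv = spec.params(
            {"alpha": 0.6, "lam": 0.5, "w_q": 0.4, "alpha_star": 0.7, "w_star": 0.5,
             "tau": 0.3, "beta_r": 0.1, "beta_0": 0.1, "lam_beta": 0.5}
        )
        agent = Agent(spec, pv)
        for step in encode_session(acq_session):
            agent.learn(*step)
            rows = agent.Tp + agent.T2 + [r for pair in agent.Ta for r in pair]
            for row in rows:
                assert abs(sum(row) - 1.0) < 1e-12

    def test_mb_prior_is_one_half(self):
        agent = Agent(get_model("MB"), ParamVector(tau=1.0, w_star=1.0))
        assert agent.Tp[0][0] == 0.5 and agent.T2[1][1] == 0.5
        assert agent.qs_a[0][0] == 0.5


NEST_CASES = [
    # (larger model, pinned params, smaller model)
    ("ACQ(lambda)", {"w_q": 0.0}, "AC(lambda)"),
    ("ACQ(lambda)", {"w_q": 1.0}, "CQ(lambda)"),
    ("ACQ(lambda)", {"lam": 0.0}, "ACQ(0)"),
    ("ACQ(lambda)", {"lam": 1.0}, "ACQ(1)"),
    ("ACQ(lambda)+MB", {"w_star": 0.0, "alpha_star": 0.3}, "ACQ(lambda)"),
    ("CQ(lambda)", {"lam": 0.0}, "CQ(0)"),
    ("AC(lambda)", {"lam": 1.0}, "AC(1)"),
    ("ACQ(lambda)+MB", {"w_q": 1.0, "w_star": 1.0, "alpha": 0.0, "lam": 0.0}, "MB"),
]


@pytest.mark.parametrize("big,pins,small", NEST_CASES)
def test_nesting_equivalences(acq_session, big, pins, small):
    """At boundary parameter values the larger model reproduces the smaller
    model's likelihood and latent trace exactly."""
    shared = {"alpha": 0.57, "lam": 0.33, "w_q": 0.71, "alpha_star": 0.44,
              "w_star": 0.26, "tau": 0.41, "beta_r": 0.12, "beta_0": 0.08,
              "lam_beta": 0.66}
    big_spec, small_spec = get_model(big), get_model(small)
    big_vals = {k: pins.get(k, shared[k]) for k in big_spec.free}
    small_vals = {k: pins.get(k, shared[k]) for k in small_spec.free}
    pv_big = big_spec.params(big_vals)
    pv_small = small_spec.params(small_vals)
    enc = encode_session(acq_session)
    ll_big = session_log_likelihood(big_spec, pv_big, enc)
    ll_small = session_log_likelihood(small_spec, pv_small, enc)
    assert ll_big == pytest.approx(ll_small, abs=1e-12)
    tr_big = forward_pass(big_spec, pv_big, acq_session)
    tr_small = forward_pass(small_spec, pv_small, acq_session)
    pd.testing.assert_series_equal(
        tr_big.choices["pi_R"], tr_small.choices["pi_R"], atol=1e-12, rtol=0
    )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    alpha=st.floats(0, 1), lam=st.floats(0, 1), w_q=st.floats(0, 1),
    tau=st.floats(0.02, 5.0), beta_r=st.floats(-2, 2), beta_0=st.floats(-2, 2),
    lam_beta=st.floats(0, 1),
)
def test_likelihood_finite_inside_bounds(alpha, lam, w_q, tau, beta_r, beta_0, lam_beta):
    """Log-likelihood is finite everywhere inside the parameter box."""
    session = make_session(
        [("active", "active_1", "L", "second_1", 1),
         ("passive", "passive_2", None, "second_2", 0),
         ("active", "active_2", "R", "second_1", 0),
         ("active", "active_1", "R", "second_2", 1)]
    )
    spec = get_model("ACQ(lambda)")
    pv = spec.params({"alpha": alpha, "lam": lam, "w_q": w_q, "tau": tau,
                      "beta_r": beta_r, "beta_0": beta_0, "lam_beta": lam_beta})
    ll = session_log_likelihood(spec, pv, encode_session(session))
    assert math.isfinite(ll)


def test_forward_pass_matches_hand_unrolled_equations():
    """Three-trial golden test: the forward-pass likelihood equals a fully
    hand-unrolled evaluation of every update equation for ACQ(lambda)+MB."""
    alpha, lam, w_q = 0.5, 0.4, 0.3
    a_star, w_star = 0.2, 0.25
    tau, beta_r, beta_0, lam_beta = 0.7, 0.15, 0.1, 0.5
    session = make_session(
        [("active", "active_1", "L", "second_1", 1),
         ("passive", "passive_2", None, "second_2", 0),
         ("active", "active_1", "R", "second_1", 0)]
    )

    # ---- hand unroll -----------------------------------------------------
    # trial 0 choice at active_1 (everything at initialization)
    qs_prior = 0.5  # uniform transition prior -> all Q* = 1/2
    ws = w_star * qs_prior  # + (1 - w_star) * 0
    x_l, x_r = ws / tau, (ws + beta_r) / tau
    pi_l0 = math.exp(x_l) / (math.exp(x_l) + math.exp(x_r))
    ll = math.log(pi_l0)
    bias_l = beta_0  # decay of zero bias, then increment for chosen L

    # trial 0 learning: active_1 --L--> second_1 --> reward
    d_v2 = 1.0  # r=1, all values zero; step-1 SVPE/AVPE are zero
    V_sec1 = alpha * d_v2
    V_act1 = alpha * lam * d_v2
    p_l = alpha * lam * d_v2
    Q_l = alpha * lam * 1.0  # AVPE at outcome: r - V(second_1)_pre = 1
    # model-based: observe (active_1, L) -> second_1 and second_1 -> reward
    Ta_l_sec1 = 0.5 + a_star * 0.5
    Ta_l_sec2 = 0.5 * (1 - a_star)
    T2_s1_rew = 0.5 + a_star * 0.5

    # trial 1 (passive_2 -> second_2 -> no reward): SVPEs are all zero since
    # V(passive_2) = V(second_2) = 0 and r = 0; only the MB module learns
    Tp2_sec2 = 0.5 + a_star * 0.5
    Tp2_sec1 = 0.5 * (1 - a_star)
    T2_s2_rew = 0.5 * (1 - a_star)

    # trial 2 choice at active_1
    qs_sec1, qs_sec2 = T2_s1_rew, T2_s2_rew
    qstar_l = Ta_l_sec1 * qs_sec1 + Ta_l_sec2 * qs_sec2
    qstar_r = 0.5 * qs_sec1 + 0.5 * qs_sec2  # (active_1, R) row untouched
    w_l = w_q * Q_l + (1 - w_q) * p_l
    w_r = 0.0
    ws_l = w_star * qstar_l + (1 - w_star) * w_l
    ws_r = w_star * qstar_r + (1 - w_star) * w_r
    x_l = (ws_l + bias_l) / tau
    x_r = (ws_r + beta_r) / tau
    pi_r2 = math.exp(x_r) / (math.exp(x_l) + math.exp(x_r))
    ll += math.log(pi_r2)

    # ---- implementation --------------------------------------------------
    spec = get_model("ACQ(lambda)+MB")
    pv = spec.params({"alpha": alpha, "lam": lam, "w_q": w_q,
                      "alpha_star": a_star, "w_star": w_star, "tau": tau,
                      "beta_r": beta_r, "beta_0": beta_0, "lam_beta": lam_beta})
    trace = forward_pass(spec, pv, session)
    assert trace.loglik == pytest.approx(ll, abs=1e-12)
    # spot-check latents after trial 0 against the unroll
    assert trace.choices["pi_L"].iloc[0] == pytest.approx(pi_l0, abs=1e-12)
    assert trace.choices["W_L"].iloc[1] == pytest.approx(w_l, abs=1e-12)
    assert trace.choices["Wstar_L"].iloc[1] == pytest.approx(ws_l, abs=1e-12)
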