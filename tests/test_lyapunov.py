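"""Rosenstein MLE estimation: analytic oracles and gating invariants."""

import numpy as np
import pytest

from vtemaze import MLEEstimate, extract_module_series, mle_rosenstein, session_mle
from vtemaze.fixtures import logistic_series, sine_series
from vtemaze.lyapunov import R_SQUARED_GATE, mean_period
from vtemaze.trial import NeuralLog, TrialRecord

LN2 = np.log(2.0)


def test_logistic_map_exponent_recovered():
    """r = 4 logistic map has lambda1 = ln 2 exactly; the estimator recovers
    it within 0.05 on a 2500-point series (m = 2)."""
    x = logistic_series(2500)
    est = mle_rosenstein(x, m=2, J=1, fit_len=10)
    assert est.accepted
    assert est.lambda1 == pytest.approx(LN2, abs=0.05)


def test_periodic_series_yields_zero():
    est = mle_rosenstein(sine_series(2000, period=50.0), m=5, J=1, fit_len=10)
    assert est.lambda1 == 0.0  # no exponential divergence on a closed orbit


def test_white_noise_rejected_by_r_squared_gate():
    x = np.random.default_rng(0).standard_normal(2000)
    est = mle_rosenstein(x, m=5, J=1, fit_len=10)
    assert not est.accepted  # divergence curve saturates immediately
    assert est.lambda1 == 0.0


def test_estimate_invariant_under_affine_rescaling():
    x = logistic_series(1200)
    a = mle_rosenstein(x, m=2, J=1, fit_len=10)
    b = mle_rosenstein(5.0 * x - 3.0, m=2, J=1, fit_len=10)
    assert b.lambda1 == pytest.approx(a.lambda1, rel=1e-9)
    assert b.r_squared == pytest.approx(a.r_squared, rel=1e-9)


def test_reported_lambda_nonnegative_and_gate_consistent():
    """On arbitrary series: lambda1 >= 0 always, accepted iff R^2 > 0.8."""
    rng = np.random.default_rng(4)
    series = [rng.standard_normal(300),
              np.cumsum(rng.standard_normal(300)),
              sine_series(300, period=17.0),
              logistic_series(300),
              np.linspace(0, 1, 300)]
    for x in series:
        est = mle_rosenstein(x, m=4, J=1, fit_len=8)
        assert est.lambda1 >= 0.0
        assert est.accepted == (est.r_squared > R_SQUARED_GATE)


def test_constant_series_rejected_not_crashing():
    est = mle_rosenstein(np.full(200, 0.7), m=3, J=1, fit_len=8)
    assert not est.accepted and est.lambda1 == 0.0


def test_too_short_series_is_a_precondition_error():
    with pytest.raises(ValueError):
        mle_rosenstein(np.arange(10.0), m=5, J=3, fit_len=10)


def test_mean_period_of_pure_tone():
    """A pure sinusoid's power-weighted mean frequency is its own frequency."""
    assert mean_period(sine_series(4000, period=40.0)) == pytest.approx(40.0, rel=0.01)
    assert mean_period(sine_series(4000, period=40.0),
                       method="dominant") == pytest.approx(40.0, rel=0.01)


def _fake_record(v: dict, s: dict, index=0) -> TrialRecord:
    log = NeuralLog(s={m: np.asarray(a, dtype=float) for m, a in s.items()},
                    v={m: np.asarray(a, dtype=float) for m, a in v.items()},
                    u=np.asarray(v["motor"], dtype=float)[:, 0])
    return TrialRecord(trial_index=index, phase="maze_solving", outcome="reward",
                       env_steps=10 * len(log), trajectory=np.zeros((1, 3)),
                       neural_log=log)


def _toy_record(n=30, vision_v=None, vision_s=None):
    shapes = {"tactile": 32, "vision": 20, "ir": 6, "reward": 1, "motor": 1}
    v = {m: np.zeros((n, k)) for m, k in shapes.items()}
    s = {m: np.zeros((n, k)) for m, k in shapes.items()}
    if vision_v is not None:
        v["vision"] = vision_v
        s["vision"] = vision_s
    return v, s


def test_extract_motor_series_is_the_logged_output():
    v, s = _toy_record(n=25)
    v["motor"] = np.linspace(0.1, 0.9, 25)[:, None]
    series = extract_module_series([_fake_record(v, s)])[0]
    assert np.array_equal(series["motor"], v["motor"][:, 0])


def test_extract_sensory_series_is_mean_mismatch():
    """v = s everywhere -> zero series; a 3-neuron hand case checks the mean."""
    v, s = _toy_record(n=4)
    v["ir"] = s["ir"] = np.ones((4, 6))
    vv = np.zeros((4, 20))
    sv = np.zeros((4, 20))
    vv[:, 0] = [1.0, 2.0, 3.0, 4.0]
    vv[:, 1] = [0.0, 1.0, 0.0, 1.0]
    sv[:, 2] = [3.0, 3.0, 3.0, 3.0]
    series = extract_module_series([_fake_record({**v, "vision": vv},
                                                 {**s, "vision": sv})])[0]
    assert np.array_equal(series["ir"], np.zeros(4))
    want = (vv - sv).mean(axis=1)
    assert np.allclose(series["vision"], want)


def test_session_mle_aggregates_and_short_series_count_as_rejected():
    """Logistic-map surrogates in the motor channel: positive mean near
    ln 2 (short-series bias documented); constant channels average 0; a
    too-short trial contributes a rejected 0.0 estimate."""
    records = []
    for k in range(6):
        v, s = _toy_record(n=150)
        v["motor"] = logistic_series(150, x0=0.11 + 0.07 * k)[:, None]
        records.append(_fake_record(v, s, index=k))
    v, s = _toy_record(n=8)  # too short for the embedding
    v["motor"] = np.full((8, 1), 0.3)
    records.append(_fake_record(v, s, index=6))
    out = session_mle(records, m=2, J=1, fit_len=10)
    assert out["motor"]["n_trials"] == 7
    assert out["motor"]["n_accepted"] <= 6
    assert out["vision"]["mean"] == 0.0
    # mean over accepted-or-rejected estimates stays in a broad band around
    # ln 2, dragged down by the rejected short trial
    assert 0.3 <= out["motor"]["mean"] <= 1.0


def test_module_rank_order_stable_across_embedding_parameters():
    """Chaotic motor channel vs periodic vision channel: the ordering of
    module mean MLEs survives perturbing (m, J)."""
    records = []
    for k in range(4):
        v, s = _toy_record(n=150)
        v["motor"] = logistic_series(150, x0=0.21 + 0.05 * k)[:, None]
        vis = np.zeros((150, 20))
        vis[:, :] = sine_series(150, period=25.0)[:, None]
        v["vision"] = vis
        records.append(_fake_record(v, s, index=k))
    for (m, J) in [(2, 1), (3, 1), (4, 1), (2, 2)]:
        out = session_mle(records, m=m, J=J, fit_len=10)
        assert out["motor"]["mean"] > out["vision"]["mean"]
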