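"""Hebbian controller: hand-computed update oracles and structural invariants."""

import math

import numpy as np
import pytest

from vtemaze import (ALL_PAIRS, MINIMAL_PAIRS, MODULE_SIZES,
                     ControllerParams, HebbianController, SensorFrame)


def zero_frame(reward: int = 0) -> SensorFrame:
    return SensorFrame(whiskers=np.zeros(32), camera=np.zeros(20),
                       ir=np.zeros(6), reward=reward)


def make(eta=0.5, zeta=0.1, topology="full", **kw):
    params = ControllerParams.uniform(eta=eta, zeta=zeta, **kw)
    return HebbianController(params, topology=topology)


def test_fresh_controller_emits_half():
    """Zero weights => every virtual unit sits at sigma(0) = 0.5."""
    ctl = make()
    u = ctl.tick(zero_frame())
    assert u == 0.5
    for m in ("tactile", "vision", "ir", "motor"):
        assert np.all(ctl.v[m] == 0.5)
    assert ctl.v["reward"][0] == 1.0


def test_phase_reset_contract():
    ctl = make()
    for _ in range(5):
        ctl.tick(zero_frame(reward=1))
    ctl.reset_phase()
    assert all(not w.any() for w in ctl.W.values())
    assert ctl.v["reward"][0] == 1.0
    assert all(not ctl.v[m].any() for m in MODULE_SIZES if m != "reward")
    assert len(ctl._history) == 0


def test_state_units_proportional_to_signals():
    ctl = make(k_touch=2.0, k_reward=1.5)
    whiskers = np.zeros(32)
    whiskers[5] = 1.0
    frame = SensorFrame(whiskers=whiskers, camera=np.zeros(20),
                        ir=np.zeros(6), reward=-1)
    ctl.tick(frame)
    assert ctl.s["tactile"][5] == 2.0
    assert not np.delete(ctl.s["tactile"], 5).any()
    assert ctl.s["reward"][0] == -1.5  # punishment scales to -k_reward


def test_hebbian_scalar_hand_computation():
    """eta=0.5, zeta=0.1, s_j=1, ds_i=0.4, W=0.2 -> W' = 0.38."""
    ctl = make(eta=0.5, zeta=0.1, tau=1)
    pair = ("reward", "motor")
    ctl.W[pair][0, 0] = 0.2
    # craft the state/history so ds_motor = 0.4 and s_reward = 1
    ctl.s = {m: np.zeros(MODULE_SIZES[m]) for m in MODULE_SIZES}
    ctl.s["reward"][0] = 1.0
    ctl.s["motor"][0] = 0.9
    ctl._history.append({m: np.zeros(MODULE_SIZES[m]) for m in MODULE_SIZES})
    delayed = {m: np.zeros(MODULE_SIZES[m]) for m in MODULE_SIZES}
    delayed["motor"][0] = 0.5
    ctl._history[-1] = delayed
    ctl._history.append({m: ctl.s[m].copy() for m in MODULE_SIZES})
    ctl.hebbian_update()
    assert ctl.W[pair][0, 0] == pytest.approx(0.2 + 0.5 * 0.4 * 1.0 - 0.1 * 0.2)


def test_virtual_update_sigmoid_hand_computation():
    """One enabled scalar path: W=2, e_j=0.3, a=1 -> v = sigma(0.6)."""
    ctl = HebbianController(
        ControllerParams.uniform(eta=0.0, zeta=0.0, slope=1.0,
                                 pairs=[("reward", "motor")]),
        topology=[("reward", "motor")])
    ctl.W[("reward", "motor")][0, 0] = 2.0
    ctl.s["reward"][0] = 0.7  # e_reward = v - s = 1 - 0.7 = 0.3
    ctl.virtual_update()
    assert ctl.v["motor"][0] == pytest.approx(1.0 / (1.0 + math.exp(-0.6)))
    assert ctl.v["reward"][0] == 1.0  # pinned under any weights


def test_two_tick_scalar_scenario_through_both_rules():
    """Pencil-and-paper run of a single reward->motor path over two ticks."""
    ctl = HebbianController(
        ControllerParams.uniform(eta=0.5, zeta=0.1, slope=1.0, tau=1,
                                 pairs=[("reward", "motor")]),
        topology=[("reward", "motor")])
    # tick 1: reward on. s_r=1 (ds_r=1), s_m=u=0.5 (ds_m=0.5, empty history)
    u1 = ctl.tick(zero_frame(reward=1))
    assert ctl.W[("reward", "motor")][0, 0] == pytest.approx(0.5 * 0.5 * 1.0)
    # e_reward = 1 - 1 = 0 -> net 0 -> u = 0.5
    assert u1 == 0.5
    # tick 2: reward off. ds_m = 0 -> pure decay W = 0.25*0.9 = 0.225;
    # e_reward = 1 - 0 = 1 -> u = sigma(0.225)
    u2 = ctl.tick(zero_frame(reward=0))
    assert ctl.W[("reward", "motor")][0, 0] == pytest.approx(0.225)
    assert u2 == pytest.approx(1.0 / (1.0 + math.exp(-0.225)))


def test_weights_decay_geometrically_with_zero_state_change():
    """Frozen zero inputs: after a burn-in, every weight decays at exactly
    (1 - zeta) per neural step."""
    zeta = 0.05
    ctl = make(eta=0.3, zeta=zeta, tau=2)
    ctl.W[("tactile", "vision")][3, 7] = 1.0
    ctl.W[("vision", "motor")][0, 2] = -0.4
    for _ in range(ctl.params.tau + 2):  # burn in: u settles, history fills
        ctl.tick(zero_frame())
    before = {p: w.copy() for p, w in ctl.W.items()}
    for k in range(1, 6):
        ctl.tick(zero_frame())
        for p, w0 in before.items():
            assert np.allclose(ctl.W[p], w0 * (1 - zeta) ** k, atol=1e-12)


def test_presynaptic_silence_blocks_potentiation():
    """s_j = 0 => no weight growth on j->i regardless of ds_i."""
    ctl = make(eta=1.0, zeta=0.0)
    frame = SensorFrame(whiskers=np.zeros(32), camera=np.ones(20),
                        ir=np.zeros(6), reward=0)
    ctl.tick(frame)
    ctl.tick(zero_frame())  # vision changes, tactile stays silent
    assert not ctl.W[("tactile", "vision")].any()
    assert not ctl.W[("tactile", "motor")].any()


def test_virtual_units_never_enter_the_learning_rule():
    """Perturbing virtual units leaves the weight trajectory unchanged as
    long as the state-unit sequence is the same."""
    rng = np.random.default_rng(0)
    a = make(eta=0.4, zeta=0.02)
    b = make(eta=0.4, zeta=0.02)
    for step in range(12):
        frame = SensorFrame(whiskers=(rng.random(32) < 0.2).astype(float),
                            camera=rng.random(20), ir=rng.random(6),
                            reward=int(rng.integers(-1, 2)))
        ua = a.tick(frame)
        b.tick(frame)
        # scramble b's virtual units, then force identical held outputs so
        # both controllers see the same motor state sequence next tick
        for m in ("tactile", "vision", "ir"):
            b.v[m] = rng.random(MODULE_SIZES[m])
        b.u = ua
        for p in a.W:
            assert np.array_equal(a.W[p], b.W[p]), (step, p)


def test_motor_output_stays_in_unit_interval():
    """u is sigma of the net input: open (0,1) mathematically, and never
    outside [0,1] even when float saturation rounds sigma to 0.0 or 1.0."""
    rng = np.random.default_rng(1)
    mild = make(eta=0.2, zeta=0.05, slope=1.0)
    hot = make(eta=1.0, zeta=0.0, slope=8.0)
    for _ in range(50):
        frame = SensorFrame(whiskers=(rng.random(32) < 0.5).astype(float),
                            camera=rng.random(20), ir=3 * rng.random(6),
                            reward=int(rng.integers(-1, 2)))
        assert 0.0 < mild.tick(frame) < 1.0
        assert 0.0 <= hot.tick(frame) <= 1.0


def test_minimal_topology_stores_only_five_pairs():
    ctl = make(topology="minimal")
    assert set(ctl.W) == set(MINIMAL_PAIRS)
    assert len(ALL_PAIRS) == 20
    full = make(topology="full")
    assert set(full.W) == set(ALL_PAIRS)


def test_learning_flag_freezes_weights():
    ctl = make()
    ctl.learning = False
    ctl.W[("reward", "motor")][0, 0] = 0.3
    before = {p: w.copy() for p, w in ctl.W.items()}
    ctl.tick(zero_frame(reward=1))
    assert all(np.array_equal(ctl.W[p], before[p]) for p in before)


def test_frame_size_mismatch_rejected():
    ctl = make()
    bad = SensorFrame(whiskers=np.zeros(30), camera=np.zeros(20),
                      ir=np.zeros(6), reward=0)
    with pytest.raises(ValueError):
        ctl.tick(bad)


def test_parameter_vector_counts_forty_nine():
    assert make().params.n_scalars() == 49
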