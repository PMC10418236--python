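import numpy as np
import pandas as pd
import pytest

import odorpop as op
from odorpop.preprocess import TrialTensor, response_magnitude
from odorpop.responsiveness import (_call_one, call_responsiveness,
                                    cross_day_transition, ddff_similarity,
                                    framewise_response_test, holm_bonferroni,
                                    identity_line_r2, us_response_test)


def holm_oracle(p, alpha=0.05):
    """Step-down threshold enumeration: reject ordered p_(k) while
    p_(k) <= alpha/(m-k+1)."""
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, bool)
    for k, i in enumerate(order):
        if p[i] <= alpha / (m - k):
            reject[i] = True
        else:
            break
    return reject


@pytest.mark.parametrize("p", [
    [0.004, 0.006, 0.008, 0.02, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95],
    [1e-6] * 10,
    [0.04] * 10,
    [0.005, 0.011, 0.02, 0.03, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7],
])
def test_holm_matches_enumeration_oracle(p):
    p = np.array(p)
    assert np.array_equal(holm_bonferroni(p), holm_oracle(p))


def test_holm_specific_example():
    """Step-down thresholds alpha/(m-k+1): 0.004 <= 0.05/10 is rejected but
    0.006 > 0.05/9 stops the procedure, so exactly one rejection."""
    p = np.array([0.004, 0.006, 0.008, 0.02, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
    rej = holm_bonferroni(p)
    assert list(np.flatnonzero(rej)) == [0]


def _tensor_from_trials(per_trial_frames, roles, fs=5.0):
    """per_trial_frames: list of (n_neurons, 35) arrays."""
    values = np.stack(per_trial_frames, axis=1)
    return TrialTensor(values, pd.DataFrame({"role": roles}), 2.0, 5.0, fs)


def test_null_data_gives_no_significant_frames():
    rng = np.random.default_rng(0)
    frames = [rng.standard_normal((1, 35)) for _ in range(30)]
    t = _tensor_from_trials(frames, ["A"] * 30)
    ft = framewise_response_test(t, 0, "A")
    assert not ft.significant.any()


def test_strong_response_all_frames_significant():
    rng = np.random.default_rng(1)
    frames = []
    for _ in range(30):
        f = rng.standard_normal((1, 35)) * 0.1
        f[0, 10:20] += 5.0
        frames.append(f)
    t = _tensor_from_trials(frames, ["A"] * 30)
    ft = framewise_response_test(t, 0, "A")
    assert ft.significant.all()
    assert (ft.direction == 1).all()


def test_responsiveness_threshold_rule():
    class FakeTest:
        pass

    for n_sig, expected in [(3, False), (4, True), (10, True)]:
        ft = FakeTest()
        ft.significant = np.zeros(10, bool)
        ft.significant[:n_sig] = True
        ft.direction = np.ones(10, int)
        resp, d, k, mixed = _call_one(ft)
        assert resp == expected and k == n_sig and not mixed
    # 4 significant frames of mixed sign: not responsive, flagged
    ft = FakeTest()
    ft.significant = np.array([True] * 4 + [False] * 6)
    ft.direction = np.array([1, 1, -1, -1] + [1] * 6)
    resp, d, k, mixed = _call_one(ft)
    assert not resp and mixed


def test_responsiveness_timecourse_shape_and_signal():
    from odorpop.responsiveness import responsiveness_timecourse
    rng = np.random.default_rng(2)
    frames = []
    for _ in range(20):
        f = rng.standard_normal((3, 35)) * 0.1
        f[0, 10:20] += 4.0          # neuron 0 responds to the odor
        frames.append(f)
    t = _tensor_from_trials(frames, ["A"] * 20)
    tc = responsiveness_timecourse(t)
    assert set(tc["odor"]) == {"A"} and len(tc) == 10
    assert tc["percent_significant"].max() == pytest.approx(100 / 3)


def test_call_responsiveness_invariant_to_trial_order(vp_tensor):
    calls = call_responsiveness(vp_tensor, odors=["S_K"])
    rng = np.random.default_rng(3)
    perm = rng.permutation(vp_tensor.n_trials)
    shuffled = TrialTensor(vp_tensor.values[:, perm],
                           vp_tensor.labels.iloc[perm].reset_index(drop=True),
                           vp_tensor.pre_s, vp_tensor.post_s,
                           vp_tensor.frame_rate)
    calls2 = call_responsiveness(shuffled, odors=["S_K"])
    pd.testing.assert_series_equal(calls["responsive"], calls2["responsive"])


def test_valence_population_called_responsive_to_both_s(vp_tensor, vp_session):
    """High-SNR valence neurons should be called responsive to both sucrose
    cues in the same direction at close to the true valence fraction."""
    from odorpop.responsiveness import responsiveness_summary
    calls = call_responsiveness(vp_tensor)
    summary = responsiveness_summary(calls)
    truth = np.isin(vp_session.ground_truth.classes,
                    ["valence_pos", "valence_neg"]).mean()
    assert abs(summary["pct_both_s_same_direction"] / 100 - truth) < 0.10


def test_us_to_cs_transition_recovers_configured_fraction(day3_schedule):
    """us_sucrose neurons that become valence (CS) coders by day 3 are
    recovered by the transition analysis."""
    sch1 = op.build_conditioning_schedule("six_odor", 30, day=1, seed=51)
    cfg1 = op.PopulationConfig(
        n_neurons=30,
        class_fractions={"us_sucrose": 1.0} |
        {c: 0.0 for c in op.ground_truth.ENCODING_CLASSES if c != "us_sucrose"})
    pop1 = op.sample_ground_truth_population(cfg1, 52)
    # by day 3 half the tracked neurons gained CS (valence) responses
    cfg3 = op.PopulationConfig(
        n_neurons=30,
        class_fractions={"valence_pos": 0.5, "us_sucrose": 0.5} |
        {c: 0.0 for c in op.ground_truth.ENCODING_CLASSES
         if c not in ("valence_pos", "us_sucrose")})
    pop3 = op.sample_ground_truth_population(cfg3, 53)
    ses1 = op.synthesize_session(sch1, pop1, 54)
    ses3 = op.synthesize_session(day3_schedule, pop3, 55)
    _, t1 = op.preprocess_session(ses1)
    _, t3 = op.preprocess_session(ses3)
    matching = {i: i for i in range(30)}
    res = cross_day_transition(t1, t3, matching)
    target = (pop3.classes == "valence_pos").mean()
    assert abs(res["fraction_transition"] - target) < 0.10
    with pytest.raises(ValueError):
        cross_day_transition(t1, t3, {})


def test_identity_line_r2_closed_form():
    rng = np.random.default_rng(5)
    x, y = rng.standard_normal(50), rng.standard_normal(50)
    direct = 1 - np.sum((y - x) ** 2) / np.sum((y - y.mean()) ** 2)
    assert identity_line_r2(x, y) == pytest.approx(direct)
    assert identity_line_r2(x, x) == pytest.approx(1.0)


def test_identity_line_r2_negative_for_independent_data():
    """y independent of x: E[SS_res] = 2*SS_tot, so R2 <= 0 on average."""
    rng = np.random.default_rng(6)
    r2s = [identity_line_r2(rng.standard_normal(500), rng.standard_normal(500))
           for _ in range(50)]
    assert np.mean(r2s) < 0


def test_ddff_similarity_valence_ordering(vp_tensor):
    """Valence-dominated population: S_K vs S_T responses lie near the
    identity line; S_K vs X_K do not."""
    rm = response_magnitude(vp_tensor)
    s_pair = ddff_similarity(rm, pair=("S_K", "S_T"))
    x_pair = ddff_similarity(rm, pair=("S_K", "X_K"))
    assert s_pair["r2_identity_line"] > x_pair["r2_identity_line"]
    assert s_pair["fraction_pair_closer"] > 0.5
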