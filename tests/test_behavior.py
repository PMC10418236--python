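import numpy as np
import pandas as pd
import pytest

import odorpop as op
from odorpop import _windows as W
from odorpop.behavior import (accuracy_vs_behavior, detect_licks_from_face,
                              dlm_predict, face_feature_matrix,
                              lick_selectivity, lip_distance, moving_average,
                              omission_r2, range_normalize)
from odorpop.simulate import make_face_features, spout_present_mask


def test_lip_distance_arithmetic():
    assert lip_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0


def test_moving_average_preserves_mean():
    rng = np.random.default_rng(0)
    x = rng.normal(2.0, 1.0, 57)
    sm = moving_average(x, 10)
    assert abs(sm.mean() - x.mean()) < 0.1
    assert np.allclose(moving_average(np.ones(20), 10), 1.0)


def test_s_fraction_all_s_licks(day3_schedule):
    n_frames = int(day3_schedule.duration_s * 5)
    licks = np.zeros(n_frames, int)
    for tr in day3_schedule.trials.itertuples():
        f = W.frames_in_window(tr.onset_s, tr.offset_s, 5.0)
        if tr.contingency == "S":
            licks[f] = 1
    s = lick_selectivity(day3_schedule, licks, 5.0)
    assert s.s_fraction == pytest.approx(1.0)


def test_s_fraction_uniform_licking(day3_schedule):
    n_frames = int(day3_schedule.duration_s * 5)
    licks = np.ones(n_frames, int)
    s = lick_selectivity(day3_schedule, licks, 5.0)
    assert s.s_fraction == pytest.approx(1 / 3)   # 2 of 6 odors are S


def test_learned_lick_fraction_increases_day1_to_day3():
    """Anticipatory-lick coupling strengthens with training: the sucrose-cue
    lick fraction rises from day 1 to day 3 in nearly all simulations."""
    from odorpop.simulate import generate_licks
    wins, n = 0, 40
    sch1 = op.build_conditioning_schedule("six_odor", 30, day=1, seed=61)
    sch3 = op.build_conditioning_schedule("six_odor", 30, day=3, seed=62)
    for s in range(n):
        rng = np.random.default_rng(1000 + s)
        f1 = lick_selectivity(
            sch1, generate_licks(sch1, 5.0, int(sch1.duration_s * 5), rng),
            5.0).s_fraction
        f3 = lick_selectivity(
            sch3, generate_licks(sch3, 5.0, int(sch3.duration_s * 5), rng),
            5.0).s_fraction
        wins += f3 > f1
    assert wins >= 0.95 * n


def test_face_lick_detector_recovers_licking(lick_nolick_session):
    ses = lick_nolick_session
    mask = spout_present_mask(ses.schedule, ses.frame_rate, ses.n_frames)
    det = detect_licks_from_face(ses.face, ses.licks, train_mask=mask)
    assert det.cv_accuracy > 0.95
    # inferred licking on spout-absent frames matches the hidden truth
    pred = det.predict(face_feature_matrix(ses.face)[~mask])
    truth = (ses.licks_true[~mask] > 0).astype(int)
    assert (pred == truth).mean() > 0.95


def test_face_detector_chance_when_uninformative():
    rng = np.random.default_rng(3)
    n = 4000
    licks = rng.poisson(0.3, n)
    face = make_face_features(np.zeros(n, int), rng)  # features carry no signal
    face += 0.01 * rng.standard_normal(face.shape)
    det = detect_licks_from_face(face, licks)
    prior = max((licks > 0).mean(), 1 - (licks > 0).mean())
    assert abs(det.cv_accuracy - prior) < 0.05
    with pytest.raises(ValueError):
        detect_licks_from_face(face, np.zeros(n, int))


def test_dlm_recovers_known_lag():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(2000)
    y = np.roll(x, 3)
    res = dlm_predict(y, x, max_lag_frames=10)
    peak = res["lags"][np.argmax(np.abs(res["coefficients"][0]))]
    assert peak == 3
    assert res["r2_out_of_sample"] > 0.99


def test_dlm_null_r2_small():
    rng = np.random.default_rng(5)
    for s in range(20):
        y = rng.standard_normal(1500)
        x = rng.standard_normal(1500)
        res = dlm_predict(y, x, max_lag_frames=10)
        assert res["r2_out_of_sample"] <= 0.05


def test_dlm_zero_lag_is_static_regression():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(500)
    y = 2 * x + 0.1 * rng.standard_normal(500)
    res = dlm_predict(y, x, max_lag_frames=0)
    assert res["coefficients"].shape == (1, 1)
    assert res["r2_out_of_sample"] > 0.95
    with pytest.raises(ValueError):
        dlm_predict(y, x, max_lag_frames=300)


def test_omission_r2_contingency_driven():
    rng = np.random.default_rng(7)
    n_tr = 120
    p_s = rng.choice([0.0, 0.5, 1.0], n_tr)
    lick = rng.normal(2.0, 0.5, n_tr)               # independent of response
    resp = 1.5 * p_s + 0.05 * rng.standard_normal(n_tr)
    df = omission_r2(resp, p_s, lick)
    assert df.loc[0, "dr2_valence"] > 0.8 * df.loc[0, "r2_full"]
    assert df.loc[0, "dr2_licking"] < 0.1


def test_omission_r2_licking_driven():
    rng = np.random.default_rng(8)
    n_tr = 120
    p_s = rng.choice([0.0, 0.5, 1.0], n_tr)
    lick = rng.normal(2.0, 0.5, n_tr)
    resp = 1.2 * lick + 0.05 * rng.standard_normal(n_tr)
    df = omission_r2(resp, p_s, lick)
    assert df.loc[0, "dr2_licking"] > 0.8 * df.loc[0, "r2_full"]
    assert df.loc[0, "dr2_valence"] < 0.1


def test_omission_r2_null_and_nonnegative():
    rng = np.random.default_rng(9)
    n_tr = 200
    p_s = rng.choice([0.0, 0.5, 1.0], n_tr)
    lick = rng.normal(2.0, 0.5, n_tr)
    resp = rng.standard_normal((5, n_tr))
    df = omission_r2(resp, p_s, lick)
    assert (df["dr2_valence"] > -1e-10).all()
    assert (df["dr2_licking"] > -1e-10).all()
    assert df["dr2_valence"].mean() < 0.1
    with pytest.raises(ValueError):
        omission_r2(resp[:, :5], p_s[:5], lick[:5])
    flagged = omission_r2(resp, np.ones(n_tr), lick)
    assert flagged["flag_constant_contingency"].all()
    assert flagged["dr2_valence"].isna().all()


def test_accuracy_vs_behavior_recovery():
    rng = np.random.default_rng(10)
    n = 75
    dp = rng.uniform(0, 1, n)
    dl = rng.uniform(0, 1, n)
    acc = 0.5 + 0.3 * dp + 0.02 * rng.standard_normal(n)
    res = accuracy_vs_behavior(acc, dl, dp)
    assert abs(res["contingency"]["coefficients"][0] - 0.3) < 0.05
    assert res["lick"]["r2"] < 0.2
    assert res["combined"]["r2"] >= res["contingency"]["r2"]


def test_accuracy_vs_behavior_errors():
    with pytest.raises(ValueError):
        accuracy_vs_behavior(np.ones(5), np.ones(5), np.ones(5))
    with pytest.raises(ValueError):
        accuracy_vs_behavior(np.full(20, 0.7), np.zeros(20), np.zeros(20))


def test_day_of_highest_lick_differential():
    from odorpop.behavior import LickSummary, day_of_highest_lick_differential
    import pandas as pd

    def summary(hi, lo):
        df = pd.DataFrame({"role": ["L_hi", "N_hi"],
                           "anticipatory_rate": [hi, lo]})
        return LickSummary(per_trial=df, s_fraction=0.5,
                           smoothed_by_odor=pd.DataFrame(), n_undefined=0)

    days = {1: summary(3.0, 2.5), 2: summary(6.0, 1.0), 3: summary(4.0, 3.0)}
    assert day_of_highest_lick_differential(days) == 2


def test_range_normalize():
    d = np.array([0.5, 1.0, 2.0])
    assert np.allclose(range_normalize(d), [0.25, 0.5, 1.0])


def test_anticipatory_window_shared_with_decoding():
    """The behavior module's anticipatory frames equal the decoding window
    used for lick/no-lick scalar summaries."""
    from odorpop.pop_decoding import build_design
    ant = W.anticipatory_window(5.0)
    assert list(ant) == [8, 9, 10, 11, 12]
    # build_design with lick_nolick paradigm uses the same relative frames
    assert np.array_equal(ant, W.anticipatory_window(5.0))
    assert np.array_equal(W.frames_in_window(1.5, 2.5, 5.0), ant)
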