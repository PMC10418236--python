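"""Lick quantification, face-based lick detection, distributed-lag models,
and the reward-contingency vs. licking-vigor disentangling regressions.

"Anticipatory licking" on a trial is the lick rate over the last 0.5 s of
the odor plus the first 0.5 s of the trace-reward delay — the same frames
(via the shared window utility) used by the population-decoding scalar
summaries in the lick/no-lick paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from . import _windows
from .schedule import TrialSchedule


def moving_average(x: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered moving average with shrink-window edge handling (the mean of
    the filtered series equals the mean of the input)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    half = window // 2
    for i in range(len(x)):
        a, b = max(0, i - half), min(len(x), i - half + window)
        out[i] = x[a:b].mean()
    return out


def lip_distance(upper_xy: np.ndarray, lower_xy: np.ndarray) -> np.ndarray:
    """Euclidean distance between upper- and lower-lip coordinates."""
    return np.linalg.norm(np.asarray(upper_xy) - np.asarray(lower_xy), axis=-1)


@dataclass
class LickSummary:
    per_trial: pd.DataFrame       # trial, role, odor licks, anticipatory rate
    s_fraction: float             # licks during S odors / licks during any odor
    smoothed_by_odor: pd.DataFrame  # moving-average odor-lick series per role
    n_undefined: int              # trials excluded from rate averages


def lick_selectivity(schedule: TrialSchedule, licks: np.ndarray,
                     frame_rate: float, ma_window: int = 10) -> LickSummary:
    """Per-trial odor-period lick counts, anticipatory rates, and the
    sucrose-cue lick fraction."""
    licks = np.asarray(licks)
    rows = []
    for tr in schedule.trials.itertuples():
        odor_f = _windows.frames_in_window(tr.onset_s, tr.offset_s, frame_rate)
        odor_f = odor_f[odor_f < len(licks)]
        ant_rel = _windows.anticipatory_window(frame_rate)
        ant_f = _windows.time_to_frame(tr.onset_s, frame_rate) + ant_rel
        ant_f = ant_f[(ant_f >= 0) & (ant_f < len(licks))]
        rows.append(dict(
            trial=tr.trial, role=tr.role, contingency=tr.contingency,
            reward_probability=tr.reward_probability,
            odor_licks=int(licks[odor_f].sum()),
            anticipatory_rate=licks[ant_f].sum() * frame_rate / len(ant_f)
            if len(ant_f) else np.nan,
        ))
    per_trial = pd.DataFrame(rows)
    total = per_trial["odor_licks"].sum()
    s_licks = per_trial.loc[per_trial["contingency"] == "S", "odor_licks"].sum()
    s_fraction = s_licks / total if total > 0 else np.nan
    n_undefined = int(per_trial["anticipatory_rate"].isna().sum()
                      + (0 if total > 0 else len(per_trial)))
    smoothed = per_trial.groupby("role")["odor_licks"] \
        .apply(lambda s: pd.Series(moving_average(s.to_numpy(), ma_window))) \
        .reset_index().rename(columns={"level_1": "occurrence",
                                       "odor_licks": "smoothed_licks"})
    return LickSummary(per_trial=per_trial, s_fraction=float(s_fraction)
                       if np.isfinite(s_fraction) else np.nan,
                       smoothed_by_odor=smoothed, n_undefined=n_undefined)


def day_of_highest_lick_differential(summaries: dict[int, LickSummary],
                                     hi_role: str = "L_hi",
                                     ref_role: str = "N_hi") -> int:
    """Day maximizing mean(anticipatory rate | hi_role) - mean(| ref_role)."""
    best_day, best = None, -np.inf
    for day, s in summaries.items():
        g = s.per_trial.groupby("role")["anticipatory_rate"].mean()
        diff = g.get(hi_role, np.nan) - g.get(ref_role, np.nan)
        if np.isfinite(diff) and diff > best:
            best_day, best = day, diff
    return best_day


@dataclass
class LickDetector:
    model: LogisticRegression
    cv_accuracy: float
    confusion: np.ndarray         # row-normalized 2x2 (no-lick, lick)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(features)


def face_feature_matrix(face: np.ndarray) -> np.ndarray:
    """3-feature design: tongue confidence, mouth-corner confidence,
    upper/lower lip distance."""
    face = np.asarray(face)
    return np.column_stack([
        face[:, 0], face[:, 1],
        lip_distance(face[:, 2:4], face[:, 4:6]),
    ])


def detect_licks_from_face(face: np.ndarray, sensor_licks: np.ndarray,
                           train_mask: np.ndarray | None = None,
                           k: int = 5, seed: int = 0) -> LickDetector:
    """Logistic lick detector from tracked face features.

    Trained on frames with sensor ground truth (``train_mask``, e.g. the
    spout-present frames); cross-validated framewise accuracy and confusion
    are reported, and the fitted detector can be applied to spout-absent
    frames for inferred licking.
    """
    X = face_feature_matrix(face)
    y = (np.asarray(sensor_licks) > 0).astype(int)
    if train_mask is not None:
        X, y = X[train_mask], y[train_mask]
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    clf = LogisticRegression(max_iter=1000)
    pred = cross_val_predict(clf, X, y, cv=cv)
    acc = float((pred == y).mean())
    cm = confusion_matrix(y, pred, labels=[0, 1]).astype(float)
    cm /= cm.sum(axis=1, keepdims=True)
    return LickDetector(model=clf.fit(X, y), cv_accuracy=acc, confusion=cm)


def dlm_predict(target: np.ndarray, predictors: np.ndarray,
                max_lag_frames: int = 10, train_fraction: float = 0.8) -> dict:
    """Distributed-lag OLS of ``target`` on lagged copies of ``predictors``
    (lags -max_lag..+max_lag), evaluated on the held-out final segment.

    Returns lag coefficients and the out-of-sample R².
    """
    y = np.asarray(target, dtype=float)
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == y.shape[0] and X.ndim == 2 and X.shape[1] != y.shape[0]:
        X = X.T                       # accept frames x features
    n_pred, T = X.shape
    L = int(max_lag_frames)
    if L < 0:
        raise ValueError("max_lag_frames must be >= 0")
    if 2 * L + 1 >= T:
        raise ValueError("lag window exceeds series length")
    lags = np.arange(-L, L + 1)
    cols = [np.roll(X[p], lag) for p in range(n_pred) for lag in lags]
    D = np.column_stack(cols)[L:T - L] if L else np.column_stack(cols)
    yv = y[L:T - L] if L else y
    split = int(round(train_fraction * len(yv)))
    D_tr, D_te = D[:split], D[split:]
    y_tr, y_te = yv[:split], yv[split:]
    model = sm.OLS(y_tr, sm.add_constant(D_tr)).fit()
    pred = model.predict(sm.add_constant(D_te, has_constant="add"))
    ss_res = np.sum((y_te - pred) ** 2)
    ss_tot = np.sum((y_te - y_te.mean()) ** 2)
    coefs = model.params[1:].reshape(n_pred, len(lags))
    return {"lags": lags, "coefficients": coefs,
            "r2_out_of_sample": float(1 - ss_res / ss_tot),
            "r2_in_sample": float(model.rsquared)}


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.rsquared)


def omission_r2(responses: np.ndarray, contingency: np.ndarray,
                lick_rate: np.ndarray) -> pd.DataFrame:
    """Variance partitioning of per-trial responses between reward
    contingency and anticipatory licking.

    ``responses``: neurons x trials (or a single trial vector).  Three OLS
    fits per neuron — contingency only, licking only, both + interaction —
    give ΔR²_-valence = R²_full − R²_licking-only and ΔR²_-licking =
    R²_full − R²_contingency-only (non-negative for nested in-sample fits).
    """
    R = np.atleast_2d(np.asarray(responses, dtype=float))
    c = np.asarray(contingency, dtype=float)
    l = np.asarray(lick_rate, dtype=float)
    if R.shape[1] < 10:
        raise ValueError("need >=10 trials")
    c_const, l_const = np.ptp(c) == 0, np.ptp(l) == 0
    rows = []
    X_full = np.column_stack([c, l, c * l])
    for i, y in enumerate(R):
        r2_full = _ols_r2(y, X_full) if not (c_const or l_const) else np.nan
        r2_c = _ols_r2(y, c[:, None]) if not c_const else np.nan
        r2_l = _ols_r2(y, l[:, None]) if not l_const else np.nan
        rows.append(dict(
            neuron=i, r2_full=r2_full,
            dr2_valence=r2_full - r2_l if np.isfinite(r2_full) else np.nan,
            dr2_licking=r2_full - r2_c if np.isfinite(r2_full) else np.nan,
            flag_constant_contingency=c_const, flag_constant_licking=l_const))
    return pd.DataFrame(rows)


def accuracy_vs_behavior(accuracies: np.ndarray, d_lick: np.ndarray,
                         d_contingency: np.ndarray) -> dict:
    """Fit pairwise decoding accuracies to Δlick, ΔP(sucrose), and both
    (+ interaction); report coefficients, p-values and R² per model."""
    y = np.asarray(accuracies, dtype=float)
    dl = np.asarray(d_lick, dtype=float)
    dc = np.asarray(d_contingency, dtype=float)
    if len(y) < 10:
        raise ValueError("need >=10 observations")
    out = {}
    for name, X in [("lick", dl[:, None]), ("contingency", dc[:, None]),
                    ("combined", np.column_stack([dl, dc, dl * dc]))]:
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError(f"rank-deficient design for model {name!r}")
        m = sm.OLS(y, Xc).fit()
        out[name] = {"r2": float(m.rsquared),
                     "coefficients": m.params[1:].tolist(),
                     "p_values": m.pvalues[1:].tolist()}
    return out


def range_normalize(d_lick: np.ndarray) -> np.ndarray:
    """Normalize pairwise Δlick by the maximum pairwise Δlick (per animal)."""
    d = np.asarray(d_lick, dtype=float)
    m = np.nanmax(np.abs(d))
    return d / m if m > 0 else d
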