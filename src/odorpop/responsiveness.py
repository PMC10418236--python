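"""Framewise odor-responsiveness testing and ΔΔF/F similarity analyses.

For each (neuron, odor) family, the ΔF/F at each frame of the 2-s odor
period (per-trial values across that odor's trials) is compared against the
pooled pre-odor distribution (all pre-odor frames x trials of that odor)
with a two-sided Wilcoxon rank-sum test; the 10 framewise p-values are
Holm-Bonferroni corrected within the family (FWER 0.05).  A neuron is called
responsive to an odor when at least 4 corrected-significant frames share one
direction (excited/inhibited); mixed-sign significant frames are labeled by
the majority sign and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _windows
from .preprocess import TrialTensor, ResponseMagnitude

MIN_SIG_FRAMES = 4


@dataclass
class FramewiseTest:
    """Rank-sum p-values and directions for one (neuron, odor) family."""

    p_values: np.ndarray        # per odor frame
    significant: np.ndarray     # Holm-corrected rejections at alpha
    direction: np.ndarray       # +1 excited / -1 inhibited per frame
    alpha: float


def holm_bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down rejections for one family of p-values.

    Ordered p-values are rejected while p_(k) <= alpha/(m-k+1); the first
    failure stops the procedure.
    """
    return holm_bonferroni_matrix(np.atleast_2d(p_values), alpha)[0]


def holm_bonferroni_matrix(P: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm rejections applied independently to each row (family) of P."""
    P = np.asarray(P, dtype=float)
    n, m = P.shape
    order = np.argsort(P, axis=1)
    thresh = alpha / (m - np.arange(m))
    ok = np.take_along_axis(P, order, axis=1) <= thresh
    ok = np.logical_and.accumulate(ok, axis=1)      # stop at first failure
    reject = np.zeros_like(ok)
    np.put_along_axis(reject, order, ok, axis=1)
    return reject


def _ranksum_pvals(frames: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p of each odor frame against the pooled pre-odor
    distribution, vectorized over neurons.

    frames: neurons x trials x odor_frames; pool: neurons x pool_size.
    Continuous (tie-free) slices use the vectorized normal approximation
    with continuity correction (identical to scipy's asymptotic method);
    slices containing ties fall back to scipy for its tie correction.
    All-tied columns get p = 1 (degenerate data, warned).
    """
    n, t, n_f = frames.shape
    m = pool.shape[1]
    N = t + m
    # slices: (neuron, frame) -> concatenated sample of length N
    A = np.concatenate(
        [np.swapaxes(frames, 1, 2), np.repeat(pool[:, None, :], n_f, axis=1)],
        axis=2)                                       # n x n_f x N
    ranks = stats.rankdata(A, axis=2)
    U = ranks[:, :, :t].sum(axis=2) - t * (t + 1) / 2
    has_ties = (np.sort(A, axis=2)[:, :, 1:] == np.sort(A, axis=2)[:, :, :-1]
                ).any(axis=2)
    mu = t * m / 2.0
    sd = np.sqrt(t * m * (N + 1) / 12.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(U - mu) - 0.5) / sd
    p = 2.0 * stats.norm.sf(z)
    if has_ties.any():
        all_tied = np.zeros_like(has_ties)
        for i, j in zip(*np.nonzero(has_ties)):
            x, y = frames[i, :, j], pool[i]
            if np.ptp(A[i, j]) == 0:
                all_tied[i, j] = True
                p[i, j] = 1.0
            else:
                p[i, j] = stats.mannwhitneyu(
                    x, y, alternative="two-sided",
                    method="asymptotic").pvalue
        if all_tied.any():
            warnings.warn("all-tied degenerate data; p set to 1")
    return np.clip(p, np.finfo(float).tiny, 1.0)


def framewise_tests_for_odor(tensor: TrialTensor, odor: str,
                             alpha: float = 0.05,
                             odor_duration_s: float = 2.0) -> list[FramewiseTest]:
    """Framewise tests of every neuron for one odor (vectorized)."""
    mask = tensor.trial_mask(odor)
    if mask.sum() < 2:
        raise ValueError(f"need >=2 trials of odor {odor!r}")
    fs = tensor.frame_rate
    odor_idx = tensor.rel_index(_windows.odor_frames(fs, odor_duration_s))
    pre_idx = tensor.rel_index(_windows.pre_odor_window(fs, tensor.pre_s))
    vals = tensor.values[:, mask]                # neurons x trials x frames
    pool = vals[:, :, pre_idx].reshape(tensor.n_neurons, -1)
    frames = vals[:, :, odor_idx]
    p = _ranksum_pvals(frames, pool)
    sig = holm_bonferroni_matrix(p, alpha)
    med_pool = np.median(pool, axis=1)
    direction = np.where(np.median(frames, axis=1) >= med_pool[:, None], 1, -1)
    return [FramewiseTest(p_values=p[i], significant=sig[i],
                          direction=direction[i], alpha=alpha)
            for i in range(tensor.n_neurons)]


def framewise_response_test(tensor: TrialTensor, neuron: int, odor: str,
                            alpha: float = 0.05,
                            odor_duration_s: float = 2.0) -> FramewiseTest:
    """Test each odor frame of one neuron against the pre-odor pool."""
    mask = tensor.trial_mask(odor)
    if mask.sum() < 2:
        raise ValueError(f"need >=2 trials of odor {odor!r}")
    fs = tensor.frame_rate
    odor_idx = tensor.rel_index(_windows.odor_frames(fs, odor_duration_s))
    pre_idx = tensor.rel_index(_windows.pre_odor_window(fs, tensor.pre_s))
    vals = tensor.values[neuron][mask]           # trials x frames
    pool = vals[:, pre_idx].ravel()
    frames = vals[:, odor_idx]                   # trials x odor frames
    p = _ranksum_pvals(frames[None], pool[None])[0]
    direction = np.where(np.median(frames, axis=0) >= np.median(pool), 1, -1)
    return FramewiseTest(p_values=p, significant=holm_bonferroni(p, alpha),
                         direction=direction, alpha=alpha)


def _call_one(test: FramewiseTest) -> tuple[bool, int, int, bool]:
    """(responsive, direction, n significant frames, mixed-sign flag)."""
    sig = test.significant
    n_sig = int(sig.sum())
    if n_sig == 0:
        return False, 0, 0, False
    dirs = test.direction[sig]
    n_pos, n_neg = int((dirs > 0).sum()), int((dirs < 0).sum())
    mixed = n_pos > 0 and n_neg > 0
    major = 1 if n_pos >= n_neg else -1
    responsive = max(n_pos, n_neg) >= MIN_SIG_FRAMES
    return responsive, major, n_sig, mixed


def call_responsiveness(tensor: TrialTensor, alpha: float = 0.05,
                        odors: list[str] | None = None) -> pd.DataFrame:
    """Responsiveness calls for all neurons x odors.

    Returns a tidy table: neuron, odor, p_min, n_sig_frames, direction,
    responsive, mixed_sign.
    """
    odors = odors or sorted(tensor.labels["role"].unique())
    rows = []
    for odor in odors:
        for n, t in enumerate(framewise_tests_for_odor(tensor, odor, alpha)):
            resp, d, k, mixed = _call_one(t)
            rows.append(dict(neuron=n, odor=odor, p_min=float(t.p_values.min()),
                             n_sig_frames=k, direction=d, responsive=resp,
                             mixed_sign=mixed))
    return pd.DataFrame(rows)


def responsiveness_summary(calls: pd.DataFrame,
                           s_odors: tuple[str, str] = ("S_K", "S_T")) -> dict:
    """Population summary: percent responsive per odor, and the counts of
    neurons responsive to both sucrose odors in the same direction, to
    exactly one odor, and to three or more odors."""
    n_neurons = calls["neuron"].nunique()
    pct = (calls.groupby("odor")["responsive"].mean() * 100).to_dict()
    per_neuron = calls[calls["responsive"]].groupby("neuron")
    n_odors_resp = per_neuron["odor"].nunique()
    both_s = 0
    for neuron, grp in per_neuron:
        sub = grp[grp["odor"].isin(s_odors)]
        if set(sub["odor"]) == set(s_odors) and sub["direction"].nunique() == 1:
            both_s += 1
    return {
        "percent_responsive_per_odor": pct,
        "pct_both_s_same_direction": 100 * both_s / n_neurons,
        "pct_single_odor": 100 * (n_odors_resp == 1).sum() / n_neurons,
        "pct_three_plus_odors": 100 * (n_odors_resp >= 3).sum() / n_neurons,
    }


def responsiveness_timecourse(tensor: TrialTensor, alpha: float = 0.05,
                              odors: list[str] | None = None) -> pd.DataFrame:
    """Percent of neurons significant per odor frame (after Holm), per odor."""
    odors = odors or sorted(tensor.labels["role"].unique())
    rows = []
    for odor in odors:
        sig = np.zeros(len(_windows.odor_frames(tensor.frame_rate)))
        for t in framewise_tests_for_odor(tensor, odor, alpha):
            sig += t.significant
        for f, s in enumerate(sig):
            rows.append(dict(odor=odor, odor_frame=f,
                             percent_significant=100 * s / tensor.n_neurons))
    return pd.DataFrame(rows)


def us_response_test(tensor: TrialTensor, neuron: int, alpha: float = 0.05,
                     us_window_s: float = 2.0) -> FramewiseTest:
    """Framewise test of the post-US window (sucrose trials) against the
    pre-odor pool of the same trials."""
    mask = (tensor.labels["us_type"] == "sucrose").to_numpy()
    if mask.sum() < 2:
        raise ValueError("need >=2 sucrose trials")
    fs = tensor.frame_rate
    pre_idx = tensor.rel_index(_windows.pre_odor_window(fs, tensor.pre_s))
    vals = tensor.values[neuron][mask]
    pool = vals[:, pre_idx].ravel()
    onsets = tensor.labels.loc[mask, "onset_s"].to_numpy()
    us_times = tensor.labels.loc[mask, "us_time_s"].to_numpy()
    n_f = int(round(us_window_s * fs))
    rel_us = np.array([_windows.time_to_frame(u - o, fs)
                       for o, u in zip(onsets, us_times)])
    frames = np.stack([vals[i, tensor.pre_frames + rel_us[i]:
                            tensor.pre_frames + rel_us[i] + n_f]
                       for i in range(vals.shape[0])])
    p = np.empty(n_f)
    for j in range(n_f):
        x = frames[:, j]
        if np.ptp(np.concatenate([x, pool])) == 0:
            p[j] = 1.0
        else:
            p[j] = stats.mannwhitneyu(x, pool, alternative="two-sided",
                                      method="asymptotic").pvalue
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    direction = np.where(np.median(frames, axis=0) >= np.median(pool), 1, -1)
    return FramewiseTest(p, holm_bonferroni(p, alpha), direction, alpha)


def cross_day_transition(day1_tensor: TrialTensor, day3_tensor: TrialTensor,
                         matching: dict[int, int], alpha: float = 0.05,
                         s_odors: tuple[str, str] = ("S_K", "S_T")) -> dict:
    """US→CS transition analysis across days.

    Fraction of tracked neurons that are sucrose(US)-responsive on day 1 and
    S-odor responsive in the same direction on day 3, plus the per-neuron
    change in S-odor response magnitude between days.
    """
    if not matching:
        raise ValueError("empty day1→day3 neuron matching")
    from .preprocess import response_magnitude
    rm1 = response_magnitude(day1_tensor)
    rm3 = response_magnitude(day3_tensor)
    n_trans = 0
    rows = []
    for n1, n3 in matching.items():
        us = us_response_test(day1_tensor, n1, alpha)
        us_resp, us_dir, _, _ = _call_one(us)
        cs_resp, cs_dir = False, 0
        for odor in s_odors:
            t = framewise_response_test(day3_tensor, n3, odor, alpha)
            r, d, _, _ = _call_one(t)
            if r:
                cs_resp, cs_dir = True, d
                break
        transition = us_resp and cs_resp and us_dir == cs_dir
        n_trans += transition
        d_mag = float(rm3.ddff.loc[n3, list(s_odors)].mean()
                      - rm1.ddff.loc[n1, list(s_odors)].mean())
        rows.append(dict(neuron_day1=n1, neuron_day3=n3, us_responsive=us_resp,
                         cs_responsive=cs_resp, transition=transition,
                         delta_magnitude=d_mag))
    table = pd.DataFrame(rows)
    return {"fraction_transition": n_trans / len(matching), "table": table}


def ddff_similarity(rm: ResponseMagnitude, pair: tuple[str, str] = ("S_K", "S_T"),
                    reference_pair: tuple[str, str] = ("S_K", "X_K"),
                    use_scaled: bool = True,
                    thresholds: np.ndarray | None = None) -> dict:
    """Identity-line R² of the (ΔΔ_i, ΔΔ_j) scatter, and the fraction of
    neurons whose ΔΔ difference within ``pair`` is smaller than within
    ``reference_pair``.

    The null model is y = x (all neurons respond identically to both odors):
    R² = 1 - Σ(y-x)² / Σ(y-ȳ)².  This can be negative when the identity
    line describes the scatter worse than the mean of y.
    """
    table = rm.scaled if use_scaled else rm.ddff
    i, j = pair
    df = table[[i, j]].dropna()
    if len(df) < 3:
        raise ValueError("need >=3 neurons with defined values")
    x, y = df[i].to_numpy(), df[j].to_numpy()
    r2 = identity_line_r2(x, y)
    rk = table[list(set(pair) | set(reference_pair))].dropna()
    d_pair = (rk[pair[0]] - rk[pair[1]]).abs()
    d_ref = (rk[reference_pair[0]] - rk[reference_pair[1]]).abs()
    frac = float((d_pair < d_ref).mean())
    out = {"r2_identity_line": r2, "fraction_pair_closer": frac,
           "n_neurons": len(df)}
    if thresholds is not None:
        mags = rk[list(set(pair) | set(reference_pair))].abs().max(axis=1)
        out["fraction_by_threshold"] = {
            float(t): float((d_pair[mags >= t] < d_ref[mags >= t]).mean())
            if (mags >= t).any() else np.nan
            for t in thresholds}
    return out


def identity_line_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R² of the y = x null model: 1 - Σ(y-x)²/Σ(y-ȳ)²."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ss_res = np.sum((y - x) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)
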