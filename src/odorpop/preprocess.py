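"""Raw fluorescence → ΔF/F, trial epoching, and windowed response magnitudes.

The baseline of each neuron is estimated with a two-component Gaussian
mixture fit inside a moving window (default 2,500 frames = 500 s at 5 Hz):
the mean of the lower-mean component is taken as that window's baseline (the
upper component absorbs transient-contaminated samples), assigned to the
window's center frame, and linearly interpolated between centers with
constant extrapolation at the edges.  ΔF/F is then (F - baseline)/baseline.

The mixture is fit by a vectorized EM specialized to the 1-D two-component
case so that whole populations are baselined in one pass; it is checked
against ``sklearn.mixture.GaussianMixture`` in the test suite, and a
20th-percentile fallback handles degenerate (near-constant or collapsed)
windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _windows
from .schedule import TrialSchedule

_EPS = 1e-12


def _em_gmm_lower_mean(X: np.ndarray, max_iter: int = 50, tol: float = 1e-3,
                       min_weight: float = 0.25) -> np.ndarray:
    """Baseline-component mean of a 2-component 1-D GMM, fit per row of X.

    The baseline is the lowest-mean component that holds at least
    ``min_weight`` of the samples: a sparse low mode (activity *dips* of an
    inhibited neuron, or a collapsed component) is skipped in favor of the
    dominant mode.  Rows with (near-)constant values return their mean.
    Arithmetic runs in float32 (the tolerance is far coarser than the
    precision loss); results are returned as float64.
    """
    X64 = np.atleast_2d(np.asarray(X, dtype=float))
    X = X64.astype(np.float32)
    n, L = X.shape
    row_var = X.var(axis=1)
    degenerate = row_var < _EPS

    mu = np.stack([np.percentile(X, 20, axis=1), np.percentile(X, 80, axis=1)])
    var = np.maximum(np.stack([row_var / 4, row_var / 4]), _EPS)
    w1 = np.full(n, 0.5)
    for _ in range(max_iter):
        # E-step via the 2-component log-odds (single n x L temporary)
        d0 = X - mu[0][:, None]
        d1 = X - mu[1][:, None]
        logodds = d1 * d1 / (2 * var[1][:, None])
        logodds -= d0 * d0 / (2 * var[0][:, None])
        logodds += (np.log(np.maximum(w1, _EPS) / np.maximum(1 - w1, _EPS))
                    + 0.5 * np.log(var[1] / var[0]))[:, None]
        r1 = 1.0 / (1.0 + np.exp(np.clip(-logodds, -80, 80)))
        # M-step
        n1 = r1.sum(axis=1) + _EPS
        n2 = (L - n1) + 2 * _EPS
        new_mu0 = (r1 * X).sum(axis=1) / n1
        new_mu1 = ((1 - r1) * X).sum(axis=1) / n2
        d0 = X - new_mu0[:, None]
        d1 = X - new_mu1[:, None]
        var = np.stack([
            np.maximum((r1 * d0 * d0).sum(axis=1) / n1, _EPS),
            np.maximum(((1 - r1) * d1 * d1).sum(axis=1) / n2, _EPS)])
        w1 = n1 / L
        new_mu = np.stack([new_mu0, new_mu1])
        shift = np.abs(new_mu - mu).max()
        mu = new_mu
        if shift < tol:
            break
    w = np.stack([w1, 1 - w1])
    low = np.argmin(mu, axis=0)
    idx = np.arange(n)
    pick = np.where(w[low, idx] >= min_weight, low, 1 - low)
    baseline = mu[pick, idx].astype(float)
    baseline[degenerate] = X64[degenerate].mean(axis=1)
    return baseline


def _sklearn_gmm_lower_mean(x: np.ndarray, n_components: int,
                            seed: int) -> float:
    from sklearn.mixture import GaussianMixture
    if np.var(x) < _EPS:
        return float(np.mean(x))
    gm = GaussianMixture(n_components=n_components, random_state=seed,
                         n_init=1).fit(x.reshape(-1, 1))
    return float(gm.means_.min())


def estimate_moving_baseline(
    F: np.ndarray,
    window_frames: int = 2500,
    stride_frames: int = 500,
    n_components: int = 2,
    seed: int = 0,
    subsample: int = 4,
    method: str = "em",
) -> np.ndarray:
    """Moving-window GMM baseline for each neuron (row) of ``F``.

    Parameters
    ----------
    F : (neurons, frames) or (frames,) raw fluorescence.
    window_frames : moving-window length (clipped to the series at the edges).
    stride_frames : spacing of window starts; window baselines are assigned to
        center frames and linearly interpolated.
    n_components : mixture size.  The fast vectorized path requires 2;
        ``method="sklearn"`` supports any value.
    subsample : fit the mixture on every ``subsample``-th frame of the window
        (a numerical economy; the baseline is a distributional statistic).
    method : {"em", "sklearn", "percentile"}.
    """
    F = np.asarray(F, dtype=float)
    squeeze = F.ndim == 1
    F2 = np.atleast_2d(F)
    if not np.all(np.isfinite(F2)):
        raise ValueError("fluorescence contains non-finite values")
    n, T = F2.shape
    if T < 1:
        raise ValueError("empty series")
    if window_frames < n_components:
        raise ValueError("window_frames must be >= n_components")
    if method == "em" and n_components != 2:
        raise ValueError('method="em" supports exactly 2 components; '
                         'use method="sklearn"')

    win = min(window_frames, T)
    half = win // 2
    centers = list(range(0, T, stride_frames))
    if centers[-1] != T - 1:
        centers.append(T - 1)
    bounds = [(max(0, c - half), min(T, c + half + 1)) for c in centers]
    centers = np.asarray(centers, dtype=float)

    vals = np.empty((n, len(bounds)))
    for j, (s, e) in enumerate(bounds):
        X = F2[:, s:e:subsample]
        if method == "em":
            vals[:, j] = _em_gmm_lower_mean(X)
        elif method == "percentile":
            vals[:, j] = np.percentile(X, 20, axis=1)
        elif method == "sklearn":
            for i in range(n):
                vals[i, j] = _sklearn_gmm_lower_mean(X[i], n_components, seed)
        else:
            raise ValueError(f"unknown method {method!r}")

    frames = np.arange(T)
    baseline = np.empty_like(F2)
    for i in range(n):
        baseline[i] = np.interp(frames, centers, vals[i])
    return baseline[0] if squeeze else baseline


def compute_dff(F: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """ΔF/F = (F - baseline) / baseline, elementwise."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
    bad = np.flatnonzero((baseline <= 0).any(axis=1))
    if bad.size:
        raise ValueError(
            f"non-positive baseline for neuron(s) {bad.tolist()[:10]}")
    out = (F - baseline) / baseline
    return out[0] if out.shape[0] == 1 and F.shape[0] == 1 else out


@dataclass
class TrialTensor:
    """Epoched ΔF/F: neurons x trials x relative frames, plus trial labels."""

    values: np.ndarray
    labels: pd.DataFrame       # one row per retained trial (schedule columns)
    pre_s: float
    post_s: float
    frame_rate: float
    n_dropped: int = 0

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def pre_frames(self) -> int:
        return int(round(self.pre_s * self.frame_rate))

    def rel_index(self, rel_frames: np.ndarray) -> np.ndarray:
        """Tensor frame indices for onset-relative frame numbers."""
        return self.pre_frames + np.asarray(rel_frames)

    def window_mean(self, rel_frames: np.ndarray) -> np.ndarray:
        """Per-trial mean over an onset-relative frame window → (neurons, trials)."""
        return self.values[:, :, self.rel_index(rel_frames)].mean(axis=2)

    def trial_mask(self, role: str) -> np.ndarray:
        return (self.labels["role"] == role).to_numpy()

    def select_roles(self, roles) -> "TrialTensor":
        m = self.labels["role"].isin(roles).to_numpy()
        return TrialTensor(self.values[:, m], self.labels[m].reset_index(drop=True),
                           self.pre_s, self.post_s, self.frame_rate, self.n_dropped)


def epoch_trials(dff: np.ndarray, schedule: TrialSchedule, frame_rate: float,
                 pre_s: float = 2.0, post_s: float = 5.0) -> TrialTensor:
    """Slice ΔF/F around each odor onset.

    Relative frame 0 is the first frame whose start time is at or after the
    odor onset.  Trials whose window falls outside the recording are dropped
    with a warning.
    """
    dff = np.atleast_2d(np.asarray(dff))
    T = dff.shape[1]
    pre_f = int(round(pre_s * frame_rate))
    post_f = int(round(post_s * frame_rate))
    slices, kept = [], []
    for idx, tr in enumerate(schedule.trials.itertuples()):
        onset = _windows.time_to_frame(tr.onset_s, frame_rate)
        a, b = onset - pre_f, onset + post_f
        if a < 0 or b > T:
            continue
        slices.append(dff[:, a:b])
        kept.append(idx)
    n_dropped = len(schedule.trials) - len(kept)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} truncated trial(s)")
    if not kept:
        raise ValueError("no complete trials inside the recording")
    values = np.stack(slices, axis=1)
    labels = schedule.trials.iloc[kept].reset_index(drop=True)
    return TrialTensor(values=values, labels=labels, pre_s=pre_s,
                       post_s=post_s, frame_rate=frame_rate,
                       n_dropped=n_dropped)


@dataclass
class ResponseMagnitude:
    """Trial-averaged ΔΔF/F per neuron per odor, plus the scaled variant.

    ΔΔF/F = mean over trials of (last-odor-second mean − 2 s pre-odor mean).
    The scaled variant divides each neuron by its largest positive ΔΔF/F
    across odors; neurons with no positive value are NaN (flagged).
    """

    ddff: pd.DataFrame          # neurons x odor labels
    scaled: pd.DataFrame
    no_positive_max: np.ndarray  # boolean per neuron


def response_magnitude(tensor: TrialTensor, by: str = "role") -> ResponseMagnitude:
    fs = tensor.frame_rate
    last = tensor.rel_index(_windows.last_odor_second(fs))
    pre = tensor.rel_index(_windows.pre_odor_window(fs, tensor.pre_s))
    per_trial = (tensor.values[:, :, last].mean(axis=2)
                 - tensor.values[:, :, pre].mean(axis=2))  # neurons x trials
    groups = tensor.labels.groupby(by).indices
    cols = {}
    for label in sorted(groups):
        idx = groups[label]
        if len(idx) == 0:
            raise ValueError(f"odor {label!r} has zero trials")
        cols[label] = per_trial[:, idx].mean(axis=1)
    ddff = pd.DataFrame(cols)
    maxpos = ddff.where(ddff > 0).max(axis=1)
    no_pos = ~(ddff.to_numpy() > 0).any(axis=1)
    scaled = ddff.div(maxpos, axis=0)
    scaled[no_pos] = np.nan
    return ResponseMagnitude(ddff=ddff, scaled=scaled, no_positive_max=no_pos)


def preprocess_session(session, window_frames: int = 2500,
                       stride_frames: int = 500, pre_s: float = 2.0,
                       post_s: float = 5.0, method: str = "em",
                       seed: int = 0):
    """Convenience: baseline → ΔF/F → epoched tensor for one session."""
    baseline = estimate_moving_baseline(
        session.F, window_frames=window_frames, stride_frames=stride_frames,
        method=method, seed=seed)
    dff = compute_dff(session.F, baseline)
    tensor = epoch_trials(dff, session.schedule, session.frame_rate,
                          pre_s=pre_s, post_s=post_s)
    return dff, tensor
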