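"""Population geometry: distance trajectories, pooled hierarchical
clustering, and participation-ratio dimensionality.

The participation ratio PR = (Σλ_i)² / Σλ_i² over the eigenvalues λ_i of the
neuron-covariance matrix ranges from 1 (all variance on one axis) to the
number of neurons (isotropic variance).  It is computed on the full-session
ΔF/F time series by default and bootstrapped by subsampling a fixed number
of neurons to compare populations of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import _windows
from .preprocess import TrialTensor


def distance_trajectories(tensor: TrialTensor) -> pd.DataFrame:
    """Normalized pairwise Euclidean distance between odor trajectories.

    Per trial, the mean pre-odor ΔF/F (2 s) is subtracted from every frame;
    responses are averaged across trials per odor; at each relative frame the
    Euclidean distance across neurons is computed for every odor pair, then
    all distances are normalized by the maximum over pairs and frames (so the
    per-animal maximum is exactly 1).

    Returns a long table: pair, rel_frame, distance.
    """
    roles = sorted(tensor.labels["role"].unique())
    if len(roles) < 2:
        raise ValueError("need >=2 odors")
    pre = tensor.rel_index(_windows.pre_odor_window(tensor.frame_rate, tensor.pre_s))
    base = tensor.values[:, :, pre].mean(axis=2, keepdims=True)
    corrected = tensor.values - base
    means = {r: corrected[:, tensor.trial_mask(r)].mean(axis=1) for r in roles}
    rows = []
    for a, b in combinations(roles, 2):
        d = np.linalg.norm(means[a] - means[b], axis=0)
        for f, v in enumerate(d):
            rows.append(dict(pair=f"{a}|{b}", rel_frame=f - tensor.pre_frames,
                             distance=v))
    df = pd.DataFrame(rows)
    df["distance"] /= df["distance"].max()
    return df


@dataclass
class ClusterResult:
    labels: np.ndarray                 # cluster id per retained neuron
    features: np.ndarray               # retained neurons x 18
    retained: np.ndarray               # indices into the pooled input
    mean_traces: dict[int, np.ndarray]  # cluster -> odors x frames mean z-trace
    composition: pd.DataFrame          # cluster x region counts


def _cluster_features(tensor: TrialTensor, roles) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored trial-averaged responses binned into first-odor-second,
    last-odor-second, first-post-odor-second per odor → neurons x 18, plus
    the full z-scored trial-averaged traces (neurons x odors x frames)."""
    fs = tensor.frame_rate
    bins = [tensor.rel_index(_windows.first_odor_second(fs)),
            tensor.rel_index(_windows.last_odor_second(fs)),
            tensor.rel_index(_windows.first_post_odor_second(fs))]
    means = np.stack([tensor.values[:, tensor.trial_mask(r)].mean(axis=1)
                      for r in roles], axis=1)      # neurons x odors x frames
    n = means.shape[0]
    concat = means.reshape(n, -1)
    mu = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ((concat - mu) / sd).reshape(means.shape)
    feats = np.stack([z[:, :, b].mean(axis=2) for b in bins], axis=2)
    return feats.reshape(n, -1), z


def cluster_pooled_responses(tensors: list[TrialTensor], k: int = 6,
                             regions: list[str] | None = None) -> ClusterResult:
    """Ward clustering of pooled trial-averaged responses.

    Each tensor contributes its neurons (pooled across sessions/regions);
    features are the 18-element binned z-scored response vectors.  Neurons
    with zero-variance traces are dropped (logged in the result).  Cluster
    ids are relabeled 1..k by descending mean response to the S odors.
    """
    regions = regions or [f"pop{i}" for i in range(len(tensors))]
    roles = sorted(tensors[0].labels["role"].unique())
    feats, zs, region_tags = [], [], []
    for tensor, reg in zip(tensors, regions):
        f, z = _cluster_features(tensor, roles)
        feats.append(f)
        zs.append(z)
        region_tags += [reg] * f.shape[0]
    X = np.vstack(feats)
    Z = np.concatenate(zs, axis=0)
    region_tags = np.asarray(region_tags)
    ok = np.isfinite(X).all(axis=1)
    X, Z, region_tags = X[ok], Z[ok], region_tags[ok]
    if k == 1:
        labels = np.ones(X.shape[0], int)
    else:
        labels = fcluster(linkage(X, method="ward"), k, criterion="maxclust")
    # stable ordering: descending mean S-odor response
    s_cols = [i for i, r in enumerate(roles) if r.startswith("S")] or [0]
    s_resp = Z[:, s_cols].mean(axis=(1, 2))
    order = sorted(np.unique(labels),
                   key=lambda c: -np.nanmean(s_resp[labels == c]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels])
    mean_traces = {c: Z[labels == c].mean(axis=0) for c in np.unique(labels)}
    comp = pd.crosstab(pd.Series(labels, name="cluster"),
                       pd.Series(region_tags, name="region"))
    return ClusterResult(labels=labels, features=X,
                         retained=np.flatnonzero(ok),
                         mean_traces=mean_traces, composition=comp)


def participation_ratio(activity: np.ndarray) -> float:
    """PR = (Σλ)²/Σλ² of the neuron-covariance eigenvalues.

    ``activity`` is samples x neurons (e.g. the full ΔF/F series transposed).
    """
    X = np.asarray(activity, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a samples x neurons matrix with >=2 samples")
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s <= 0:
        raise ValueError("zero-variance activity")
    return float(s ** 2 / np.sum(lam ** 2))


def subsampled_pr(activity: np.ndarray, k: int = 15, n_repeats: int = 1000,
                  seed: int = 0) -> dict:
    """Mean PR over random k-neuron subsamples (without replacement)."""
    X = np.asarray(activity, dtype=float)
    n = X.shape[1]
    if k > n:
        raise ValueError("k exceeds population size")
    rng = np.random.default_rng(seed)
    cov = np.cov(X, rowvar=False)
    prs = np.empty(n_repeats)
    for r in range(n_repeats):
        cols = rng.choice(n, size=k, replace=False)
        lam = np.clip(np.linalg.eigvalsh(cov[np.ix_(cols, cols)]), 0, None)
        prs[r] = lam.sum() ** 2 / np.sum(lam ** 2)
    return {"mean_pr": float(prs.mean()), "sd_pr": float(prs.std()),
            "k": k, "n_repeats": n_repeats}


def pr_vs_n(activity: np.ndarray, ks: np.ndarray | None = None,
            n_repeats: int = 200, seed: int = 0,
            normalize: bool = True) -> pd.DataFrame:
    """Subsampled PR over a grid of subsample sizes (optionally PR/k)."""
    n = activity.shape[1]
    ks = ks if ks is not None else np.unique(
        np.linspace(2, n, min(10, n - 1)).astype(int))
    rows = []
    for k in ks:
        r = subsampled_pr(activity, k=int(k), n_repeats=n_repeats, seed=seed)
        val = r["mean_pr"] / k if normalize else r["mean_pr"]
        rows.append(dict(k=int(k), pr=r["mean_pr"], normalized_pr=val))
    return pd.DataFrame(rows)
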