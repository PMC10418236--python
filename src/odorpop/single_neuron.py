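"""Single-neuron pairwise odor discriminability and categorization.

The per-trial feature is the mean ΔF/F over the last second of the odor
(Z-scored over the pooled trials of the two odors).  A logistic model fit on
this 1-D feature produces scores that are a monotone function of the feature,
so the auROC of the model equals the rank (Mann-Whitney) auROC of the feature
up to orientation; the fitted coefficient's sign fixes the orientation.  The
rank computation with midrank tie handling is therefore the implementation,
and a permutation null of the same statistic yields an add-one p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from . import _windows
from .preprocess import TrialTensor

SIX_ODOR_ROLES = ("S_K", "S_T", "X_K", "X_T", "P_K", "P_T")


def canonical_pairs(roles=SIX_ODOR_ROLES) -> list[tuple[str, str]]:
    """The 15 unordered odor pairs, in canonical order."""
    return list(combinations(roles, 2))


def rank_auroc(x: np.ndarray, labels: np.ndarray) -> float:
    """auROC of feature x for labels (1 = positive class), midrank ties."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(x)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class NeuronPairScore:
    neuron: int
    pair: tuple[str, str]
    auroc: float
    zero_variance: bool = False
    null_mean: float | None = None
    null_sd: float | None = None
    n_shuffles: int = 0
    p_value: float | None = None


def _pair_feature(tensor: TrialTensor, neuron: int, pair: tuple[str, str],
                  window: np.ndarray | None = None):
    fs = tensor.frame_rate
    rel = window if window is not None else _windows.last_odor_second(fs)
    feat = tensor.window_mean(rel)[neuron]
    m0, m1 = tensor.trial_mask(pair[0]), tensor.trial_mask(pair[1])
    x = np.concatenate([feat[m0], feat[m1]])
    y = np.concatenate([np.zeros(m0.sum(), int), np.ones(m1.sum(), int)])
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    return x, y, sd


def single_neuron_auroc(tensor: TrialTensor, neuron: int,
                        pair: tuple[str, str],
                        window: np.ndarray | None = None,
                        seed: int = 0) -> NeuronPairScore:
    """auROC of a logistic classifier on the per-trial window-mean feature.

    Orientation follows the fitted coefficient sign, so values below 0.5 are
    possible in degenerate cases; zero-variance features return 0.5, flagged.
    """
    x, y, sd = _pair_feature(tensor, neuron, pair, window)
    if min((y == 0).sum(), (y == 1).sum()) < 5:
        raise ValueError("need >=5 trials of each odor")
    if sd == 0:
        return NeuronPairScore(neuron, pair, 0.5, zero_variance=True)
    a = rank_auroc(x, y)
    clf = LogisticRegression(C=1e6).fit(x[:, None], y)
    auroc = a if clf.coef_[0, 0] > 0 else 1.0 - a
    return NeuronPairScore(neuron, pair, auroc)


def _oriented_null_auroc(x: np.ndarray, y_shuffled: np.ndarray) -> float:
    # mean-difference sign stands in for the logistic coefficient sign
    a = rank_auroc(x, y_shuffled)
    sign = x[y_shuffled == 1].mean() - x[y_shuffled == 0].mean()
    return a if sign > 0 else 1.0 - a


def auroc_shuffle_null(tensor: TrialTensor, neuron: int,
                       pair: tuple[str, str], n_shuffles: int = 10000,
                       seed: int = 0,
                       window: np.ndarray | None = None) -> NeuronPairScore:
    """Label-permutation null for the oriented auROC; add-one p-value."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles < 100 gives unusable p resolution")
    score = single_neuron_auroc(tensor, neuron, pair, window=window)
    x, y, sd = _pair_feature(tensor, neuron, pair, window)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = _oriented_null_auroc(x, rng.permutation(y))
    p = (1 + (null >= score.auroc).sum()) / (1 + n_shuffles)
    score.null_mean = float(null.mean())
    score.null_sd = float(null.std())
    score.n_shuffles = n_shuffles
    score.p_value = float(p)
    return score


def score_all_pairs(tensor: TrialTensor, pairs=None,
                    window: np.ndarray | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """auROC for every neuron x odor pair (no permutation null)."""
    pairs = pairs or canonical_pairs(sorted(tensor.labels["role"].unique()))
    rows = []
    for pair in pairs:
        for n in range(tensor.n_neurons):
            s = single_neuron_auroc(tensor, n, pair, window=window, seed=seed)
            rows.append(dict(neuron=n, pair=f"{pair[0]}|{pair[1]}",
                             auroc=s.auroc, zero_variance=s.zero_variance))
    return pd.DataFrame(rows)


@dataclass
class QuadrantLabel:
    neuron: int
    label: str            # valence / identity / identity_S_only / uninformative
    intervalence_auroc: float
    intravalence_auroc: float
    threshold: float


def categorize_quadrants(intervalence: np.ndarray, intravalence: np.ndarray,
                         threshold: float = 0.75) -> pd.DataFrame:
    """Quadrant categorization from the two auROC axes.

    intervalence = auROC for a different-contingency pair (e.g. S_K vs X_K);
    intravalence = auROC for the same-contingency pair (S_K vs S_T).
    valence: intervalence > θ only; identity: both > θ;
    identity_S_only: intravalence > θ only; uninformative: neither.
    """
    inter = np.asarray(intervalence, dtype=float)
    intra = np.asarray(intravalence, dtype=float)
    labels = np.where(
        (inter > threshold) & (intra > threshold), "identity",
        np.where(inter > threshold, "valence",
                 np.where(intra > threshold, "identity_S_only",
                          "uninformative")))
    return pd.DataFrame({
        "neuron": np.arange(len(inter)), "label": labels,
        "intervalence_auroc": inter, "intravalence_auroc": intra,
        "threshold": threshold,
    })


def quadrant_composition(table: pd.DataFrame) -> dict[str, float]:
    frac = table["label"].value_counts(normalize=True)
    return {k: float(frac.get(k, 0.0)) for k in
            ("valence", "identity", "identity_S_only", "uninformative")}


def single_neuron_mnr_confusion(tensor: TrialTensor, neuron: int, k: int = 5,
                                seed: int = 0,
                                window: np.ndarray | None = None) -> pd.DataFrame:
    """Row-normalized 6x6 confusion of a cross-validated multinomial model on
    the single neuron's per-trial window feature."""
    fs = tensor.frame_rate
    rel = window if window is not None else _windows.last_odor_second(fs)
    roles = sorted(tensor.labels["role"].unique())
    if len(roles) < 6:
        raise ValueError("all 6 odors required")
    feat = tensor.window_mean(rel)[neuron][:, None]
    y = tensor.labels["role"].to_numpy()
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = cross_val_predict(LogisticRegression(max_iter=1000), feat, y, cv=cv)
    return _confusion_table(y, pred, roles)


def _confusion_table(y_true, y_pred, roles) -> pd.DataFrame:
    from sklearn.metrics import confusion_matrix
    cm = confusion_matrix(y_true, y_pred, labels=roles).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, row_sums, out=np.full_like(cm, np.nan),
                   where=row_sums > 0)
    return pd.DataFrame(cm, index=roles, columns=roles)


def confusion_summary(cm: pd.DataFrame,
                      s_pair: tuple[str, str] = ("S_K", "S_T"),
                      ketone_group: tuple[str, ...] = ("S_K", "X_K", "P_K")) -> dict:
    """Mean mutual confusion within the sucrose pair and the ketone group."""
    i, j = s_pair
    s_conf = (cm.loc[i, j] + cm.loc[j, i]) / 2
    offs = [cm.loc[a, b] for a in ketone_group for b in ketone_group if a != b]
    return {"s_pair_confusion": float(s_conf),
            "ketone_group_confusion": float(np.mean(offs))}
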