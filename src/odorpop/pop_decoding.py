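"""Population-level decoding: pairwise CV classifiers, permutation nulls,
cross-pair generalization, PC-restricted decoding, multinomial confusion.

Designs are built from simultaneously recorded neurons only (one session at
a time).  Features are per-trial window-averaged ΔF/F, Z-scored per neuron
with training-fold statistics (a ``StandardScaler`` inside the CV pipeline,
so no leakage into held-out folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _windows
from .preprocess import TrialTensor
from .single_neuron import canonical_pairs, _confusion_table

CONTINGENCY_RANK = {"S": 1.0, "X": 0.0, "P": -1.0}


@dataclass
class PopulationDesign:
    """Trials x neurons feature matrix with labels and session grouping."""

    X: np.ndarray
    labels: pd.DataFrame              # retained schedule rows
    animal_id: str = "sim0"
    day: int = 1

    def pair_subset(self, pair: tuple[str, str]):
        m = self.labels["role"].isin(pair).to_numpy()
        y = (self.labels.loc[m, "role"] == pair[1]).to_numpy().astype(int)
        return self.X[m], y, self.labels[m]


def build_design(tensor: TrialTensor, window: np.ndarray | None = None,
                 animal_id: str = "sim0", day: int | None = None,
                 paradigm: str = "six_odor") -> PopulationDesign:
    """Per-trial window-mean features for all trials of a session.

    Default window: last odor second (six-odor paradigm) or the anticipatory
    window, last 0.5 s odor + first 0.5 s delay (lick/no-lick paradigm).
    """
    fs = tensor.frame_rate
    if window is None:
        window = (_windows.anticipatory_window(fs) if paradigm == "lick_nolick"
                  else _windows.last_odor_second(fs))
    X = tensor.window_mean(window).T      # trials x neurons
    return PopulationDesign(X=X, labels=tensor.labels, animal_id=animal_id,
                            day=day if day is not None else 1)


def _learner(name: str, seed: int):
    if name == "logistic":
        clf = LogisticRegression(max_iter=1000)
    elif name == "svm_rbf":
        clf = SVC(C=1.0, gamma="scale")
    else:
        raise ValueError(f"unknown learner {name!r}")
    return make_pipeline(StandardScaler(), clf)


def population_pair_classifier(design: PopulationDesign, pair: tuple[str, str],
                               learner: str = "logistic", k: int = 5,
                               seed: int = 0) -> float:
    """Stratified k-fold CV accuracy for one odor pair."""
    X, y, _ = design.pair_subset(pair)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} trials")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return float(cross_val_score(_learner(learner, seed), X, y, cv=cv).mean())


def pair_accuracy_timecourse(tensor: TrialTensor, pair: tuple[str, str],
                             learner: str = "logistic", k: int = 5,
                             seed: int = 0) -> np.ndarray:
    """CV accuracy with the classifier retrained at each relative frame."""
    n_frames = tensor.values.shape[2]
    out = np.empty(n_frames)
    for f in range(n_frames):
        design = PopulationDesign(X=tensor.values[:, :, f].T,
                                  labels=tensor.labels)
        out[f] = population_pair_classifier(design, pair, learner, k, seed)
    return out


def population_shuffle_null(design: PopulationDesign, pair: tuple[str, str],
                            learner: str = "logistic", k: int = 5,
                            n_shuffles: int = 10000, seed: int = 0) -> dict:
    """Label-permutation null of the CV accuracy; add-one p-value."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles < 100 gives unusable p resolution")
    X, y, _ = design.pair_subset(pair)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    obs = float(cross_val_score(_learner(learner, seed), X, y, cv=cv).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = cross_val_score(_learner(learner, seed), X,
                                  rng.permutation(y), cv=cv).mean()
    p = (1 + (null >= obs).sum()) / (1 + n_shuffles)
    return {"accuracy": obs, "p_value": float(p), "null_mean": float(null.mean()),
            "null_sd": float(null.std()), "n_shuffles": n_shuffles}


@dataclass
class GeneralizationMatrix:
    """15x15 train-pair x test-pair accuracies.

    Diagonal entries are within-pair CV accuracies; off-diagonal entries come
    from a model trained on the full data of the training pair and tested on
    all trials of the test pair under the contingency-aligned label mapping.
    Entries whose label mapping is orientation-ambiguous (no contingency
    difference in train or test pair) take the maximum over both mappings and
    are flagged.
    """

    accuracies: pd.DataFrame
    ambiguous: pd.DataFrame
    pairs: list[tuple[str, str]] = field(default_factory=list)


def _pair_rank(pair: tuple[str, str], labels: pd.DataFrame) -> tuple[float, float]:
    by_role = labels.drop_duplicates("role").set_index("role")
    if "reward_probability" in by_role and labels["reward_probability"].nunique() > 1:
        key = by_role["reward_probability"]
    else:
        key = by_role["contingency"].map(CONTINGENCY_RANK)
    return float(key[pair[0]]), float(key[pair[1]])


def generalization_matrix(design: PopulationDesign, learner: str = "logistic",
                          k: int = 5, seed: int = 0) -> GeneralizationMatrix:
    """Train on each odor pair, test on every other pair.

    Label transfer: the higher-reward-contingency class of the training pair
    maps onto the higher-contingency class of the test pair.
    """
    roles = sorted(design.labels["role"].unique())
    if len(roles) < 6:
        raise ValueError("all 6 odors required")
    pairs = canonical_pairs(roles)
    names = [f"{a}|{b}" for a, b in pairs]
    acc = pd.DataFrame(np.nan, index=names, columns=names)
    amb = pd.DataFrame(False, index=names, columns=names)
    models = {}
    for pair in pairs:
        X, y, _ = design.pair_subset(pair)
        models[pair] = _learner(learner, seed).fit(X, y)
    for i, tr_pair in enumerate(pairs):
        r_tr = _pair_rank(tr_pair, design.labels)
        tr_tied = r_tr[0] == r_tr[1]
        for j, te_pair in enumerate(pairs):
            if i == j:
                acc.iloc[i, j] = population_pair_classifier(
                    design, tr_pair, learner, k, seed)
                continue
            X_te, y_te, _ = design.pair_subset(te_pair)
            r_te = _pair_rank(te_pair, design.labels)
            te_tied = r_te[0] == r_te[1]
            pred = models[tr_pair].predict(X_te)
            ambiguous = tr_tied or te_tied
            if ambiguous:
                a = max((pred == y_te).mean(), (pred == 1 - y_te).mean())
            else:
                # align by contingency: training class 1 corresponds to the
                # test class whose contingency ranks the same way
                same_orientation = ((r_tr[1] > r_tr[0]) == (r_te[1] > r_te[0]))
                a = (pred == y_te).mean() if same_orientation \
                    else (pred == 1 - y_te).mean()
            acc.iloc[i, j] = float(a)
            amb.iloc[i, j] = ambiguous
    return GeneralizationMatrix(accuracies=acc, ambiguous=amb, pairs=pairs)


def is_intervalence(pair: tuple[str, str], labels: pd.DataFrame) -> bool:
    """Pair with unequal sucrose contingency where exactly one odor is
    sucrose-predicting."""
    by_role = labels.drop_duplicates("role").set_index("role")["contingency"]
    return (by_role[pair[0]] == "S") != (by_role[pair[1]] == "S")


def generalized_valence_decoding(gm: GeneralizationMatrix,
                                 labels: pd.DataFrame) -> float:
    """Mean accuracy over the off-diagonal intervalence→intervalence block."""
    inter = [f"{a}|{b}" for a, b in gm.pairs if is_intervalence((a, b), labels)]
    block = gm.accuracies.loc[inter, inter].to_numpy().copy()
    np.fill_diagonal(block, np.nan)
    return float(np.nanmean(block))


def pca_restricted_decoding(design: PopulationDesign, pair: tuple[str, str],
                            k_neurons: int = 15,
                            n_components: np.ndarray | None = None,
                            n_subsamples: int = 20, k: int = 5,
                            seed: int = 0) -> pd.DataFrame:
    """CV accuracy of classifiers trained on the top-m PCs of a k-neuron
    subsample, as a function of m; averaged over subsamples.

    The PCA basis is fit on the *full* design (all odors), so the leading
    components capture the population's dominant response axes; whether the
    pair is decodable from few components then reflects how the pair's
    signal aligns with those axes.
    """
    pair_mask = design.labels["role"].isin(pair).to_numpy()
    y = (design.labels.loc[pair_mask, "role"] == pair[1]).to_numpy().astype(int)
    n_neurons = design.X.shape[1]
    if n_neurons < k_neurons:
        raise ValueError("population smaller than k_neurons")
    ms = (np.asarray(n_components) if n_components is not None
          else np.arange(1, k_neurons + 1))
    if ms.max() > k_neurons:
        raise ValueError("n_components exceeds k_neurons")
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc = np.zeros((n_subsamples, len(ms)))
    for s in range(n_subsamples):
        cols = rng.choice(n_neurons, size=k_neurons, replace=False)
        scaler = StandardScaler().fit(design.X[:, cols])
        Z_all = PCA(n_components=k_neurons).fit_transform(
            scaler.transform(design.X[:, cols]))
        Z = Z_all[pair_mask]
        for mi, m in enumerate(ms):
            clf = make_pipeline(StandardScaler(),
                                LogisticRegression(max_iter=1000))
            acc[s, mi] = cross_val_score(clf, Z[:, :m], y, cv=cv).mean()
    return pd.DataFrame({"n_components": ms, "accuracy": acc.mean(axis=0),
                         "accuracy_sd": acc.std(axis=0)})


def population_mnr_confusion(design: PopulationDesign, k: int = 5,
                             seed: int = 0) -> pd.DataFrame:
    """Row-normalized 6x6 confusion of a cross-validated multinomial model."""
    roles = sorted(design.labels["role"].unique())
    y = design.labels["role"].to_numpy()
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    pred = cross_val_predict(clf, design.X, y, cv=cv)
    return _confusion_table(y, pred, roles)


def enumerate_cohort_tasks(n_animals: int, days: list[int],
                           roles=None) -> pd.DataFrame:
    """All (animal, day, pair) classifier tasks for a cohort; one pairwise
    classifier is trained per row."""
    pairs = canonical_pairs(roles or
                            ("S_K", "S_T", "X_K", "X_T", "P_K", "P_T"))
    rows = [dict(animal=a, day=d, pair=f"{p[0]}|{p[1]}")
            for a in range(n_animals) for d in days for p in pairs]
    return pd.DataFrame(rows)
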