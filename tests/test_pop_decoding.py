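import numpy as np
import pandas as pd
import pytest

import odorpop as op
from odorpop.pop_decoding import (PopulationDesign, build_design,
                                  enumerate_cohort_tasks,
                                  generalization_matrix,
                                  generalized_valence_decoding,
                                  pca_restricted_decoding,
                                  population_mnr_confusion,
                                  population_pair_classifier,
                                  population_shuffle_null)


def _gaussian_design(n_per_class=30, n_neurons=10, sep=10.0, seed=0,
                     roles=("A", "B")):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per_class, n_neurons)) +
                   (0 if i == 0 else sep) for i in range(len(roles))])
    labels = pd.DataFrame({"role": np.repeat(roles, n_per_class),
                           "contingency": np.repeat(["S", "X"], n_per_class)
                           if len(roles) == 2 else "X"})
    return PopulationDesign(X=X, labels=labels)


def test_separable_classes_perfect_accuracy():
    d = _gaussian_design(sep=10.0)
    assert population_pair_classifier(d, ("A", "B")) == 1.0


def test_random_labels_chance_accuracy():
    rng = np.random.default_rng(1)
    accs = []
    for s in range(40):
        d = _gaussian_design(sep=0.0, seed=s)
        accs.append(population_pair_classifier(d, ("A", "B"), seed=s))
    assert 0.45 < np.mean(accs) < 0.55


def test_too_few_trials_per_class_raises():
    d = _gaussian_design(n_per_class=4)
    with pytest.raises(ValueError):
        population_pair_classifier(d, ("A", "B"))


def test_svm_learner_supported():
    d = _gaussian_design(sep=5.0)
    acc = population_pair_classifier(d, ("A", "B"), learner="svm_rbf")
    assert acc > 0.9
    with pytest.raises(ValueError):
        population_pair_classifier(d, ("A", "B"), learner="forest")


def test_shuffle_null_p_values():
    d = _gaussian_design(sep=8.0, n_per_class=15)
    res = population_shuffle_null(d, ("A", "B"), n_shuffles=200, seed=2)
    assert res["accuracy"] == 1.0
    assert res["p_value"] < 0.01
    res2 = population_shuffle_null(d, ("A", "B"), n_shuffles=200, seed=2)
    assert res2["p_value"] == res["p_value"]
    with pytest.raises(ValueError):
        population_shuffle_null(d, ("A", "B"), n_shuffles=50)


def test_cohort_task_enumeration():
    tasks = enumerate_cohort_tasks(17, [1, 3, 6])
    assert len(tasks) == 765
    assert tasks.groupby(["animal", "day"]).size().eq(15).all()


def test_generalization_matrix_valence_population(vp_tensor):
    """Valence-coding population: decoders trained on one S-vs-nonS pair
    transfer to the other S-vs-nonS pairs."""
    design = build_design(vp_tensor)
    gm = generalization_matrix(design)
    assert gm.accuracies.shape == (15, 15)
    gvd = generalized_valence_decoding(gm, design.labels)
    assert gvd >= 0.85
    # diagonal is within-pair CV accuracy, high for intervalence pairs
    assert gm.accuracies.loc["S_K|X_K", "S_K|X_K"] > 0.9
    # train on itself (full data) >= CV accuracy, statistically
    assert not gm.ambiguous.loc["S_K|X_K", "P_K|S_K"]
    assert gm.ambiguous.loc["S_K|X_K", "X_K|X_T"]


def test_generalization_matrix_identity_population(vp_tensor, identity_tensor):
    """Identity-coding population: valence decoding generalizes much less
    than for a valence-coding population of the same size."""
    d_vp = build_design(vp_tensor)
    d_id = build_design(identity_tensor)
    gvd_vp = generalized_valence_decoding(generalization_matrix(d_vp),
                                          d_vp.labels)
    gvd_id = generalized_valence_decoding(generalization_matrix(d_id),
                                          d_id.labels)
    assert gvd_vp > gvd_id + 0.1


def test_pca_restricted_low_rank_signal(vp_tensor):
    """Rank-1 valence signal: one PC suffices for S-vs-P decoding."""
    design = build_design(vp_tensor)
    curve = pca_restricted_decoding(design, ("S_K", "P_K"), k_neurons=15,
                                    n_components=np.array([1, 15]),
                                    n_subsamples=10, seed=0)
    a1 = curve.loc[curve["n_components"] == 1, "accuracy"].item()
    a15 = curve.loc[curve["n_components"] == 15, "accuracy"].item()
    assert a1 >= a15 - 0.05


def test_pca_restricted_high_rank_signal(identity_tensor):
    """Full-rank identity tuning: S_K vs S_T decoding needs many PCs."""
    design = build_design(identity_tensor)
    curve = pca_restricted_decoding(design, ("S_K", "S_T"), k_neurons=15,
                                    n_components=np.array([1, 15]),
                                    n_subsamples=10, seed=0)
    a1 = curve.loc[curve["n_components"] == 1, "accuracy"].item()
    a15 = curve.loc[curve["n_components"] == 15, "accuracy"].item()
    assert a15 > a1 + 0.05
    with pytest.raises(ValueError):
        pca_restricted_decoding(design, ("S_K", "S_T"), k_neurons=15,
                                n_components=np.array([16]))


def test_full_basis_equals_unprojected(vp_tensor):
    design = build_design(vp_tensor)
    curve = pca_restricted_decoding(design, ("S_K", "X_K"), k_neurons=15,
                                    n_components=np.array([15]),
                                    n_subsamples=5, seed=3)
    # rotation invariance: full-basis projection ~ unprojected learner
    full = curve["accuracy"].item()
    assert full > 0.9


def test_population_mnr_confusion_structure(vp_tensor, identity_tensor):
    from odorpop.single_neuron import confusion_summary
    cm_vp = population_mnr_confusion(build_design(vp_tensor))
    cm_id = population_mnr_confusion(build_design(identity_tensor))
    s_vp = confusion_summary(cm_vp)
    s_id = confusion_summary(cm_id)
    # valence population confuses the two sucrose cues; identity does not
    assert s_vp["s_pair_confusion"] > s_id["s_pair_confusion"]
    # identity population: high diagonal
    assert np.mean(np.diag(cm_id.to_numpy())) > 0.5


def test_pair_accuracy_timecourse():
    """Per-frame classifier accuracy: chance before odor onset, perfect
    during the odor for a constructed response."""
    from odorpop.pop_decoding import pair_accuracy_timecourse
    from odorpop.preprocess import TrialTensor
    rng = np.random.default_rng(11)
    vals, labels = [], []
    for role, resp in (("A", 1.0), ("B", -1.0)):
        for _ in range(15):
            f = 0.3 * rng.standard_normal((4, 35))
            f[:, 10:20] += resp
            vals.append(f)
            labels.append(role)
    t = TrialTensor(np.stack(vals, axis=1), pd.DataFrame({"role": labels}),
                    2.0, 5.0, 5.0)
    tc = pair_accuracy_timecourse(t, ("A", "B"), k=3)
    assert tc.shape == (35,)
    assert tc[:10].mean() < 0.7       # pre-odor: near chance
    assert tc[12:20].min() > 0.9      # odor period: separable


def test_noise_neurons_do_not_help():
    rng = np.random.default_rng(9)
    accs0, accs1 = [], []
    for s in range(10):
        d = _gaussian_design(sep=0.35, n_per_class=30, n_neurons=5, seed=s)
        accs0.append(population_pair_classifier(d, ("A", "B"), seed=s))
        Xn = np.hstack([d.X, rng.standard_normal((d.X.shape[0], 50))])
        dn = PopulationDesign(X=Xn, labels=d.labels)
        accs1.append(population_pair_classifier(dn, ("A", "B"), seed=s))
    assert np.mean(accs1) <= np.mean(accs0) + 0.05
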