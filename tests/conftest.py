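import numpy as np
import pytest

import odorpop as op


@pytest.fixture(scope="session")
def day3_schedule():
    return op.build_conditioning_schedule("six_odor", 30, day=3, seed=11)


@pytest.fixture(scope="session")
def vp_session(day3_schedule):
    """Valence-dominated 60-neuron session, day 3 (trained)."""
    pop = op.sample_ground_truth_population(op.vp_like_config(60), seed=21)
    return op.synthesize_session(day3_schedule, pop, seed=22)


@pytest.fixture(scope="session")
def vp_tensor(vp_session):
    _, tensor = op.preprocess_session(vp_session)
    return tensor


@pytest.fixture(scope="session")
def identity_session(day3_schedule):
    pop = op.sample_ground_truth_population(op.identity_only_config(60), seed=31)
    return op.synthesize_session(day3_schedule, pop, seed=32)


@pytest.fixture(scope="session")
def identity_tensor(identity_session):
    _, tensor = op.preprocess_session(identity_session)
    return tensor


@pytest.fixture(scope="session")
def lick_nolick_session():
    sch = op.build_conditioning_schedule("lick_nolick", 30, day=1, seed=41)
    cfg = op.PopulationConfig(
        n_neurons=40, region="VP",
        class_fractions={"valence_pos": 0.4, "valence_neg": 0.0,
                         "identity": 0.0, "lick": 0.3, "us_sucrose": 0.1,
                         "salience": 0.0, "silent": 0.2})
    pop = op.sample_ground_truth_population(cfg, seed=42)
    return op.synthesize_session(sch, pop, seed=43)
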