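"""Ground-truth neuron populations for synthetic sessions.

Each neuron belongs to one encoding class:

- ``valence_pos`` / ``valence_neg``: driven by the *current* reward
  contingency of the presented odor (shared low-rank template across odors;
  near-equal weights on both same-contingency odors up to a configurable
  per-odor jitter).  In the lick/no-lick paradigm the drive scales with the
  odor's reward probability.
- ``identity``: odor tuning drawn independently per chemical, giving
  full-rank population tuning.
- ``lick``: driven by lick events, not odors.
- ``us_sucrose``: driven by sucrose delivery.
- ``salience``: driven equally by every odor and by the airpuff.
- ``silent``: baseline + drift + noise only.

The per-neuron kinetic, amplitude, baseline, drift, and noise parameters are
the recovery target for downstream parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENCODING_CLASSES = (
    "valence_pos", "valence_neg", "identity", "lick",
    "us_sucrose", "salience", "silent",
)


@dataclass
class PopulationConfig:
    """Sampling configuration for a ground-truth population.

    ``class_fractions`` must sum to 1.  Amplitudes are ΔF/F-scale response
    amplitudes (unitless, relative to baseline F0); kinetics are seconds.
    """

    n_neurons: int = 130
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"valence_pos": 0.5, "valence_neg": 0.1,
                                 "us_sucrose": 0.15, "lick": 0.05,
                                 "salience": 0.0, "identity": 0.0,
                                 "silent": 0.2})
    exact_fractions: bool = False
    amplitude_mean: float = 0.8          # lognormal mean of peak ΔF/F drive
    amplitude_sigma: float = 0.4         # lognormal sigma (log scale)
    valence_jitter: float = 0.1          # sd of per-odor multiplicative jitter
    trial_gain_sd: float = 0.35          # per-trial multiplicative response gain sd
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.7
    f0_mean: float = 100.0
    f0_sigma: float = 0.3                # lognormal sigma of baseline F0
    drift_amplitude: float = 0.05        # OU stationary sd, fraction of F0
    drift_timescale_s: float = 100.0
    noise_sd: float = 0.05               # additive noise sd, fraction of F0
    region: str = "VP"


def vp_like_config(n_neurons: int = 130, **kw) -> PopulationConfig:
    """Valence-dominated, low-rank population (ventral-pallidum-like)."""
    return PopulationConfig(n_neurons=n_neurons, region="VP", **kw)


def ot_like_config(n_neurons: int = 250, region: str = "OT_D2", **kw) -> PopulationConfig:
    """Identity-dominated, full-rank-tuning population (tubercle-like)."""
    return PopulationConfig(
        n_neurons=n_neurons, region=region,
        class_fractions={"valence_pos": 0.0, "valence_neg": 0.0,
                         "us_sucrose": 0.05, "lick": 0.05, "salience": 0.0,
                         "identity": 0.7, "silent": 0.2},
        **kw,
    )


def identity_only_config(n_neurons: int = 250, **kw) -> PopulationConfig:
    return PopulationConfig(
        n_neurons=n_neurons, region="OT_D2",
        class_fractions={c: 0.0 for c in ENCODING_CLASSES} | {"identity": 1.0},
        **kw,
    )


@dataclass
class GroundTruthPopulation:
    """Per-neuron encoding classes and generative parameters."""

    neurons: pd.DataFrame          # class + scalar parameters, one row/neuron
    odor_weights: np.ndarray       # (n, 6) identity tuning per chemical
    odor_jitter: np.ndarray        # (n, 6) multiplicative jitter for valence drive
    config: PopulationConfig

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def classes(self) -> np.ndarray:
        return self.neurons["encoding_class"].to_numpy()

    def to_csv(self, path) -> None:
        df = self.neurons.copy()
        for j in range(6):
            df[f"odor_weight_{j}"] = self.odor_weights[:, j]
        df.to_csv(path, index=False)


def sample_ground_truth_population(
    config: PopulationConfig, seed: int | np.random.Generator = 0
) -> GroundTruthPopulation:
    """Draw a population deterministically under ``seed``.

    Class counts follow a multinomial over ``class_fractions`` unless
    ``exact_fractions`` is set, in which case largest-remainder rounding of
    n * fraction is used.
    """
    fr = {c: config.class_fractions.get(c, 0.0) for c in ENCODING_CLASSES}
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_neurons
    names = list(ENCODING_CLASSES)
    probs = np.array([fr[c] for c in names])
    if config.exact_fractions:
        raw = probs * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - np.floor(raw)))
        counts[order[:rem]] += 1
    else:
        counts = rng.multinomial(n, probs)
    classes = np.repeat(names, counts)
    rng.shuffle(classes)

    amp = rng.lognormal(np.log(config.amplitude_mean), config.amplitude_sigma, n)
    f0 = rng.lognormal(np.log(config.f0_mean), config.f0_sigma, n)
    neurons = pd.DataFrame({
        "neuron": np.arange(n),
        "encoding_class": classes,
        "amplitude": amp,
        "tau_rise_s": np.full(n, config.tau_rise_s),
        "tau_decay_s": np.full(n, config.tau_decay_s),
        "f0": f0,
        "drift_amplitude": np.full(n, config.drift_amplitude),
        "drift_timescale_s": np.full(n, config.drift_timescale_s),
        "noise_sd": np.full(n, config.noise_sd),
        "region": config.region,
    })
    # identity tuning: independent per odor, sparse-ish exponential weights,
    # normalized so the preferred odor has weight 1
    w = rng.exponential(1.0, (n, 6))
    w /= w.max(axis=1, keepdims=True)
    odor_weights = np.where(
        (classes == "identity")[:, None], w, 0.0)
    odor_jitter = 1.0 + config.valence_jitter * rng.standard_normal((n, 6))
    return GroundTruthPopulation(
        neurons=neurons, odor_weights=odor_weights,
        odor_jitter=np.clip(odor_jitter, 0.0, None), config=config,
    )
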