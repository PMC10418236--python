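"""Synthesis of full recording sessions (fluorescence + behavior streams).

The generative model per neuron is

    F(t) = F0 * (1 + drift(t) + r(t)) + noise(t),   truncated at 0,

where ``drift`` is an Ornstein-Uhlenbeck process (slow baseline wander),
``r`` is the event drive convolved with a difference-of-exponentials calcium
kernel (jGCaMP7s-like: 0.2 s rise, 1.7 s decay by default, peak-normalized),
and ``noise`` is white Gaussian.  Event drives depend on the neuron's
encoding class (see :mod:`odorpop.ground_truth`).

Licking is an inhomogeneous Poisson process: a low spontaneous rate, an
anticipatory ramp over the final odor second of reward-predicting odors that
persists through the trace-reward delay (scaled by a per-day learning factor
and by reward probability), and a consummatory bout after sucrose delivery.
The capacitive lick sensor only registers licks while the spout is present;
face features (tongue/mouth-corner tracking confidences and lip coordinates)
are noisy deterministic functions of the true lick state and therefore carry
lick information even on spout-retracted trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ._windows import time_to_frame
from .ground_truth import GroundTruthPopulation
from .schedule import TrialSchedule

# learning factor by day within a contingency phase: how strongly anticipatory
# licking tracks the current reward contingencies
LEARNING_BY_PHASE_DAY = (0.15, 0.6, 0.95)

LICK_BASELINE_HZ = 0.2
LICK_ANTICIPATORY_PEAK_HZ = 7.0
LICK_CONSUMMATORY_HZ = 7.0
LICK_CONSUMMATORY_DUR_S = 2.5


@dataclass
class RecordingSession:
    """One simulated (or loaded) imaging session with aligned behavior."""

    F: np.ndarray                    # neurons x frames, raw fluorescence, >= 0
    frame_rate: float
    schedule: TrialSchedule
    licks: np.ndarray                # sensor lick counts per frame
    locomotion: np.ndarray           # placeholder speed stream, per frame
    face: np.ndarray                 # frames x 6 tracked face features
    region: str = "VP"
    animal_id: str = "sim0"
    day: int = 1
    licks_true: np.ndarray | None = None     # ground-truth lick counts
    ground_truth: GroundTruthPopulation | None = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


def learning_factor(paradigm: str, day: int) -> float:
    """Anticipatory-licking learning factor for a session day.

    Six-odor days restart learning after the day-3/day-4 contingency switch;
    lick/no-lick sessions are modeled as already trained.
    """
    if paradigm == "lick_nolick":
        return LEARNING_BY_PHASE_DAY[-1]
    d = (day - 1) % 3
    return LEARNING_BY_PHASE_DAY[d]


def calcium_kernel(tau_rise_s: float, tau_decay_s: float, frame_rate: float,
                   duration_s: float = 10.0) -> np.ndarray:
    """Difference-of-exponentials kernel, normalized to unit peak."""
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("kernel time constants must be positive")
    t = np.arange(int(round(duration_s * frame_rate))) / frame_rate
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (decay must exceed rise)")
    return k / peak


def lick_rate(schedule: TrialSchedule, frame_rate: float, n_frames: int,
              learning: float | None = None) -> np.ndarray:
    """Per-frame lick rate (Hz) implied by the schedule and learning state."""
    if learning is None:
        learning = learning_factor(schedule.paradigm, schedule.day)
    rate = np.full(n_frames, LICK_BASELINE_HZ)
    t_frame = np.arange(n_frames) / frame_rate
    for tr in schedule.trials.itertuples():
        if tr.reward_probability > 0:
            drive = learning * (tr.reward_probability
                                if schedule.paradigm == "lick_nolick" else 1.0)
        else:
            # weak generalized anticipation early in learning
            drive = 0.15 * (1.0 - learning)
        peak = LICK_ANTICIPATORY_PEAK_HZ * drive
        ramp0, ramp1 = tr.offset_s - 1.0, tr.offset_s
        hold1 = tr.us_time_s if np.isfinite(tr.us_time_s) else tr.offset_s + 0.3
        i0, i1 = time_to_frame(ramp0, frame_rate), time_to_frame(ramp1, frame_rate)
        i2 = min(time_to_frame(hold1, frame_rate), n_frames)
        if i1 > i0:
            rate[i0:i1] += peak * (t_frame[i0:i1] - ramp0) / 1.0
        rate[i1:i2] += peak
        if tr.us_type == "sucrose" and np.isfinite(tr.us_time_s):
            j0 = time_to_frame(tr.us_time_s, frame_rate)
            j1 = min(time_to_frame(tr.us_time_s + LICK_CONSUMMATORY_DUR_S,
                                   frame_rate), n_frames)
            rate[j0:j1] += LICK_CONSUMMATORY_HZ
    return rate


def generate_licks(schedule: TrialSchedule, frame_rate: float, n_frames: int,
                   rng: np.random.Generator,
                   learning: float | None = None) -> np.ndarray:
    """Sample per-frame lick counts from the inhomogeneous Poisson rate."""
    return rng.poisson(lick_rate(schedule, frame_rate, n_frames, learning)
                       / frame_rate)


def spout_present_mask(schedule: TrialSchedule, frame_rate: float,
                       n_frames: int) -> np.ndarray:
    """Boolean mask of frames during which the lick spout is in place."""
    mask = np.ones(n_frames, dtype=bool)
    for tr in schedule.trials.itertuples():
        if np.isfinite(tr.spout_retract_s):
            a = time_to_frame(tr.spout_retract_s, frame_rate)
            b = min(time_to_frame(tr.spout_return_s, frame_rate), n_frames)
            mask[a:b] = False
    return mask


def lick_bout_onsets(licks: np.ndarray, frame_rate: float,
                     min_gap_s: float = 1.0) -> np.ndarray:
    """Frames starting a lick bout (first lick after >= min_gap lick-free)."""
    lick_frames = np.flatnonzero(licks > 0)
    if lick_frames.size == 0:
        return lick_frames
    gap = int(round(min_gap_s * frame_rate))
    onsets = [lick_frames[0]]
    for f_prev, f in zip(lick_frames[:-1], lick_frames[1:]):
        if f - f_prev >= gap:
            onsets.append(f)
    return np.asarray(onsets)


def make_face_features(licks_true: np.ndarray, rng: np.random.Generator,
                       noise_sd: float = 0.05) -> np.ndarray:
    """Frames x 6: tongue conf, mouth-corner conf, upper-lip xy, lower-lip xy.

    Lip distance grows and tracking confidences rise while the animal licks;
    Gaussian noise on top.  Minimal structure sufficient to train and test a
    face-based lick detector.
    """
    n = licks_true.shape[0]
    lick_state = (licks_true > 0).astype(float)
    face = np.empty((n, 6))
    face[:, 0] = np.clip(0.05 + 0.9 * lick_state + noise_sd * rng.standard_normal(n), 0, 1)
    face[:, 1] = np.clip(0.3 + 0.4 * lick_state + noise_sd * rng.standard_normal(n), 0, 1)
    face[:, 2] = noise_sd * rng.standard_normal(n)            # upper lip x
    face[:, 3] = noise_sd * rng.standard_normal(n)            # upper lip y
    face[:, 4] = noise_sd * rng.standard_normal(n)            # lower lip x
    face[:, 5] = 2.0 + 3.0 * lick_state + 2 * noise_sd * rng.standard_normal(n)
    return face


def _event_drive(schedule: TrialSchedule, population: GroundTruthPopulation,
                 frame_rate: float, n_frames: int, licks_true: np.ndarray,
                 kernel_odor_gain: float, rng: np.random.Generator) -> np.ndarray:
    """Spike-drive matrix (neurons x frames) in peak-ΔF/F units."""
    n = population.n_neurons
    drive = np.zeros((n, n_frames))
    cls = population.classes
    amp = population.neurons["amplitude"].to_numpy()
    trials = schedule.trials
    is_ln = schedule.paradigm == "lick_nolick"

    # per-(neuron, trial) odor weight
    odor_ids = trials["odor_id"].to_numpy()
    p_reward = trials["reward_probability"].to_numpy()
    is_s = (trials["contingency"] == "S").to_numpy()
    v_scale = p_reward if is_ln else is_s.astype(float)

    w = np.zeros((n, len(trials)))
    val_pos = cls == "valence_pos"
    val_neg = cls == "valence_neg"
    ident = cls == "identity"
    sal = cls == "salience"
    jit = population.odor_jitter[:, odor_ids]
    w[val_pos] = (amp[val_pos, None] * v_scale[None, :]) * jit[val_pos]
    w[val_neg] = -(amp[val_neg, None] * v_scale[None, :]) * jit[val_neg]
    w[ident] = amp[ident, None] * population.odor_weights[ident][:, odor_ids]
    w[sal] = amp[sal, None]
    # trial-to-trial multiplicative response variability (biological gain noise)
    gain = np.clip(1.0 + population.config.trial_gain_sd
                   * rng.standard_normal(w.shape), 0.0, None)
    w *= gain

    odor_len = None
    for j, tr in enumerate(trials.itertuples()):
        a = time_to_frame(tr.onset_s, frame_rate)
        b = min(time_to_frame(tr.offset_s, frame_rate), n_frames)
        if odor_len is None:
            odor_len = b - a
        drive[:, a:b] += w[:, j, None] * kernel_odor_gain
        if np.isfinite(tr.us_time_s):
            f_us = time_to_frame(tr.us_time_s, frame_rate)
            if f_us < n_frames:
                if tr.us_type == "sucrose":
                    us_cells = cls == "us_sucrose"
                    drive[us_cells, f_us] += 1.5 * amp[us_cells] * gain[us_cells, j]
                elif tr.us_type == "airpuff":
                    drive[sal, f_us] += 1.5 * amp[sal] * gain[sal, j]
    lick_cells = cls == "lick"
    if lick_cells.any():
        # bout-onset-locked drive scaled by the bout's vigor (licks in the
        # first second), so lick-neuron fluorescence tracks lick rate
        span = int(round(frame_rate))
        for f in lick_bout_onsets(licks_true, frame_rate):
            vigor = licks_true[f:f + span].sum() / (0.5 * LICK_ANTICIPATORY_PEAK_HZ)
            drive[lick_cells, f] += amp[lick_cells] * vigor
    return drive


def _ou_drift(n: int, n_frames: int, amplitude: np.ndarray, tau_s: np.ndarray,
              frame_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU process per neuron (AR(1) exact discretization)."""
    a = np.exp(-1.0 / (tau_s * frame_rate))
    innov_sd = amplitude * np.sqrt(1.0 - a ** 2)
    eps = rng.standard_normal((n, n_frames)) * innov_sd[:, None]
    eps[:, 0] = amplitude * rng.standard_normal(n)  # stationary start
    out = np.empty((n, n_frames))
    for i in range(n):
        out[i] = lfilter([1.0], [1.0, -a[i]], eps[i])
    return out


def synthesize_session(
    schedule: TrialSchedule,
    population: GroundTruthPopulation,
    seed: int | np.random.Generator = 0,
    frame_rate: float = 5.0,
    animal_id: str = "sim0",
) -> RecordingSession:
    """Build a full synthetic session; bit-reproducible under a fixed seed."""
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = population.config
    n_frames = int(np.ceil(schedule.duration_s * frame_rate))
    n = population.n_neurons

    licks_true = generate_licks(schedule, frame_rate, n_frames, rng)
    spout = spout_present_mask(schedule, frame_rate, n_frames)
    licks_sensor = np.where(spout, licks_true, 0)

    kernel = calcium_kernel(cfg.tau_rise_s, cfg.tau_decay_s, frame_rate)
    # gain so a unit-weight 2-s boxcar drive peaks at ~1 ΔF/F
    odor_frames = int(round(2.0 * frame_rate))
    gain = 1.0 / np.convolve(np.ones(odor_frames), kernel).max()
    drive = _event_drive(schedule, population, frame_rate, n_frames,
                         licks_true, gain, rng)
    # FIR filtering == causal convolution truncated to the recording length
    resp = lfilter(kernel, [1.0], drive, axis=1)

    f0 = population.neurons["f0"].to_numpy()
    F = _ou_drift(n, n_frames,
                  population.neurons["drift_amplitude"].to_numpy(),
                  population.neurons["drift_timescale_s"].to_numpy(),
                  frame_rate, rng)
    F += resp
    F += 1.0
    F *= f0[:, None]
    noise = rng.standard_normal((n, n_frames))
    noise *= (population.neurons["noise_sd"].to_numpy() * f0)[:, None]
    F += noise
    np.clip(F, 0.0, None, out=F)

    locomotion = np.abs(lfilter([1.0], [1.0, -0.98],
                                rng.standard_normal(n_frames)))
    face = make_face_features(licks_true, rng)
    return RecordingSession(
        F=F, frame_rate=frame_rate, schedule=schedule, licks=licks_sensor,
        locomotion=locomotion, face=face, region=cfg.region,
        animal_id=animal_id, day=schedule.day, licks_true=licks_true,
        ground_truth=population,
    )
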