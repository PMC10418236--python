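"""Frame/time conventions shared by every stage.

Frames are 0-based; frame ``i`` covers the half-open interval
``[i/fs, (i+1)/fs)`` seconds.  A time window ``[t0, t1)`` therefore contains
every frame whose *start* time falls inside it.  All window bookkeeping in the
package funnels through these helpers so that, e.g., the anticipatory-licking
window used by the behavior module and the decoding window used by the
population module are provably the same frames.
"""

from __future__ import annotations

import math

import numpy as np


def time_to_frame(t_s: float, frame_rate: float) -> int:
    """First frame whose start time is >= ``t_s`` (exact boundary maps to itself)."""
    return int(math.ceil(t_s * frame_rate - 1e-9))


def frames_in_window(t0_s: float, t1_s: float, frame_rate: float) -> np.ndarray:
    """Indices of frames whose start time lies in the half-open window [t0, t1)."""
    first = time_to_frame(t0_s, frame_rate)
    last = time_to_frame(t1_s, frame_rate)  # exclusive
    return np.arange(first, last)


# Relative-frame windows around odor onset (onset = relative frame 0).
def odor_frames(frame_rate: float, odor_duration_s: float = 2.0) -> np.ndarray:
    """All frames during the odor period."""
    return frames_in_window(0.0, odor_duration_s, frame_rate)


def first_odor_second(frame_rate: float) -> np.ndarray:
    return frames_in_window(0.0, 1.0, frame_rate)


def last_odor_second(frame_rate: float, odor_duration_s: float = 2.0) -> np.ndarray:
    return frames_in_window(odor_duration_s - 1.0, odor_duration_s, frame_rate)


def pre_odor_window(frame_rate: float, pre_s: float = 2.0) -> np.ndarray:
    return frames_in_window(-pre_s, 0.0, frame_rate)


def first_post_odor_second(frame_rate: float, odor_duration_s: float = 2.0) -> np.ndarray:
    return frames_in_window(odor_duration_s, odor_duration_s + 1.0, frame_rate)


def anticipatory_window(frame_rate: float, odor_duration_s: float = 2.0) -> np.ndarray:
    """Last 0.5 s of odor + first 0.5 s of the trace-reward delay.

    This is the analysis window for the lick/no-lick paradigm, shared between
    anticipatory-lick quantification and the scalar decoding summaries.
    """
    return frames_in_window(odor_duration_s - 0.5, odor_duration_s + 0.5, frame_rate)
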