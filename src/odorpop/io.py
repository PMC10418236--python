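"""HDF5 / CSV persistence for sessions, schedules and derived tables.

Session layout::

    /F                    neurons x frames raw fluorescence
    /dff                  (optional) neurons x frames ΔF/F
    /behavior/licks       per-frame sensor lick counts
    /behavior/licks_true  (synthetic only) ground-truth lick counts
    /behavior/locomotion  per-frame speed
    /behavior/face        frames x 6 tracked face features
    /schedule/<column>    one dataset per schedule column
    attrs: frame_rate_hz, region, animal_id, day, paradigm

The schedule is mirrored to a sidecar CSV next to the HDF5 file.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .schedule import TrialSchedule
from .simulate import RecordingSession

_SCHEDULE_COLUMNS = [
    "trial", "block", "odor_id", "odor_name", "odor_class", "contingency",
    "role", "reward_probability", "spout_present", "onset_s", "offset_s",
    "us_type", "us_time_s", "spout_retract_s", "spout_return_s", "iti_s",
]


def save_session(session: RecordingSession, path: str | Path,
                 sidecar_csv: bool = True) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=session.F)
        beh = f.create_group("behavior")
        beh.create_dataset("licks", data=session.licks)
        beh.create_dataset("locomotion", data=session.locomotion)
        beh.create_dataset("face", data=session.face)
        if session.licks_true is not None:
            beh.create_dataset("licks_true", data=session.licks_true)
        sch = f.create_group("schedule")
        for col in _SCHEDULE_COLUMNS:
            vals = session.schedule.trials[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            sch.create_dataset(col, data=vals)
        f.attrs["frame_rate_hz"] = session.frame_rate
        f.attrs["region"] = session.region
        f.attrs["animal_id"] = session.animal_id
        f.attrs["day"] = session.day
        f.attrs["paradigm"] = session.schedule.paradigm
        f.attrs["duration_s"] = session.schedule.duration_s
    if sidecar_csv:
        session.schedule.trials[_SCHEDULE_COLUMNS].to_csv(
            path.with_suffix(".schedule.csv"), index=False)
    if session.ground_truth is not None:
        session.ground_truth.to_csv(path.with_suffix(".ground_truth.csv"))


def load_session(path: str | Path) -> RecordingSession:
    with h5py.File(path, "r") as f:
        cols = {}
        for col in _SCHEDULE_COLUMNS:
            v = f["schedule"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        trials = pd.DataFrame(cols)
        trials["spout_present"] = trials["spout_present"].astype(bool)
        schedule = TrialSchedule(
            trials=trials, paradigm=str(f.attrs["paradigm"]),
            day=int(f.attrs["day"]), duration_s=float(f.attrs["duration_s"]))
        licks_true = (f["behavior/licks_true"][()]
                      if "licks_true" in f["behavior"] else None)
        session = RecordingSession(
            F=f["F"][()], frame_rate=float(f.attrs["frame_rate_hz"]),
            schedule=schedule, licks=f["behavior/licks"][()],
            locomotion=f["behavior/locomotion"][()],
            face=f["behavior/face"][()], region=str(f.attrs["region"]),
            animal_id=str(f.attrs["animal_id"]), day=int(f.attrs["day"]),
            licks_true=licks_true)
    return session


def save_dff(path: str | Path, dff: np.ndarray) -> None:
    with h5py.File(path, "a") as f:
        if "dff" in f:
            del f["dff"]
        f.create_dataset("dff", data=dff)


def load_dff(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["dff"][()]


def save_tensor(tensor, path: str | Path) -> None:
    """Serialize a TrialTensor to HDF5 (values + window metadata) with the
    trial labels mirrored to a sidecar CSV."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values)
        f.attrs["pre_s"] = tensor.pre_s
        f.attrs["post_s"] = tensor.post_s
        f.attrs["frame_rate"] = tensor.frame_rate
        f.attrs["n_dropped"] = tensor.n_dropped
    tensor.labels.to_csv(path.with_suffix(".labels.csv"), index=False)


def load_tensor(path: str | Path):
    from .preprocess import TrialTensor
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        meta = dict(f.attrs)
    labels = pd.read_csv(path.with_suffix(".labels.csv"))
    return TrialTensor(values=values, labels=labels,
                       pre_s=float(meta["pre_s"]), post_s=float(meta["post_s"]),
                       frame_rate=float(meta["frame_rate"]),
                       n_dropped=int(meta["n_dropped"]))


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output (fixed float format) for reproducible runs."""
    df.to_csv(path, index=False, float_format="%.10g")
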