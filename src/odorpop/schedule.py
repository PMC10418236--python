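"""Conditioning-paradigm trial schedules.

Two paradigms are modeled:

``six_odor``
    Classical conditioning with six odors (three 2-ketones, three terpenes),
    two odors per contingency group: sucrose (S), nothing (X), airpuff (P).
    On days 1-3 the original contingency map applies; on days 4-6 the map is
    switched so that every contingency group keeps one ketone and one terpene
    but the chemical assignments change.

``lick_nolick``
    Reward probability (0 / 50 / 100 % sucrose) crossed with lick-spout
    availability: for three odors the spout stays in place (L_X, L_lo, L_hi),
    for the other three it is retracted 0.2 s before odor onset and returns
    0.1 s before the earliest possible reward time (N_X, N_lo, N_hi).

Trials are organized into blocks, each containing every odor exactly once in
random order, with a uniform 12-18 s inter-trial interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ODOR_CHEMICALS = ["hexanone", "heptanone", "octanone", "terpinene", "pinene", "limonene"]
ODOR_CLASS = {
    "hexanone": "ketone",
    "heptanone": "ketone",
    "octanone": "ketone",
    "terpinene": "terpene",
    "pinene": "terpene",
    "limonene": "terpene",
}

ODOR_DURATION_S = 2.0
ITI_RANGE_S = (12.0, 18.0)
US_DELAY_SIX_ODOR_S = (0.1, 0.3)
US_DELAY_LICK_NOLICK_S = (1.1, 1.3)
SPOUT_RETRACT_BEFORE_ONSET_S = 0.2
SPOUT_RETURN_BEFORE_US_S = 0.1

# days 1-3 (phase 1) and days 4-6 (phase 2) contingency maps: chemical -> S/X/P
SIX_ODOR_CONTINGENCY = {
    1: {"hexanone": "X", "terpinene": "X",
        "heptanone": "S", "pinene": "S",
        "octanone": "P", "limonene": "P"},
    2: {"heptanone": "X", "limonene": "X",
        "octanone": "S", "terpinene": "S",
        "hexanone": "P", "pinene": "P"},
}

# lick/no-lick: reward probability and spout availability per chemical.
# Spout stays for hexanone/heptanone/pinene; retracted for the other three.
LICK_NOLICK_DESIGN = {
    "hexanone": (0.0, True), "heptanone": (0.5, True), "pinene": (1.0, True),
    "terpinene": (0.0, False), "octanone": (0.5, False), "limonene": (1.0, False),
}

_PROB_TAG = {0.0: "X", 0.5: "lo", 1.0: "hi"}


def six_odor_phase(day: int) -> int:
    return 1 if day <= 3 else 2


def six_odor_roles(day: int) -> dict[str, str]:
    """Map chemical -> role label (S_K, S_T, X_K, X_T, P_K, P_T) for a day."""
    cmap = SIX_ODOR_CONTINGENCY[six_odor_phase(day)]
    return {chem: f"{cont}_{'K' if ODOR_CLASS[chem] == 'ketone' else 'T'}"
            for chem, cont in cmap.items()}


def lick_nolick_roles() -> dict[str, str]:
    """Map chemical -> role label (L_hi, L_lo, L_X, N_hi, N_lo, N_X)."""
    out = {}
    for chem, (p, spout) in LICK_NOLICK_DESIGN.items():
        tag = _PROB_TAG[p]
        out[chem] = f"{'L' if spout else 'N'}_{tag}"
    return out


@dataclass
class TrialSchedule:
    """Trial-structured event metadata for one session.

    ``trials`` has one row per trial with columns: trial, block, odor_id,
    odor_name, odor_class, contingency, role, reward_probability,
    spout_present, onset_s, offset_s, us_type, us_time_s, spout_retract_s,
    spout_return_s, iti_s.
    """

    trials: pd.DataFrame
    paradigm: str
    day: int
    duration_s: float = field(default=0.0)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def roles(self) -> list[str]:
        return sorted(self.trials["role"].unique())

    def trials_for_role(self, role: str) -> pd.DataFrame:
        return self.trials[self.trials["role"] == role]


def _block_orders(n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random within-block odor orders, rejecting any order in which
    an odor repeats more than twice in a row across block boundaries."""
    while True:
        orders = np.stack([rng.permutation(6) for _ in range(n_blocks)])
        flat = orders.ravel()
        run, bad = 1, False
        for a, b in zip(flat[:-1], flat[1:]):
            run = run + 1 if a == b else 1
            if run > 2:
                bad = True
                break
        if not bad:
            return orders


def build_conditioning_schedule(
    paradigm: str,
    n_blocks: int = 30,
    day: int = 1,
    seed: int | np.random.Generator = 0,
    start_s: float = 15.0,
) -> TrialSchedule:
    """Generate a trial schedule for one session.

    Parameters
    ----------
    paradigm : {"six_odor", "lick_nolick"}
    n_blocks : number of blocks; each block presents every odor once.
    day : session day (for ``six_odor``, days 1-3 use the original contingency
        map and days 4-6 the switched map).
    seed : int seed or Generator; the schedule is deterministic given it.
    start_s : onset time of the first trial.
    """
    if paradigm not in ("six_odor", "lick_nolick"):
        raise ValueError(f"unknown paradigm: {paradigm!r}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if paradigm == "six_odor":
        cont_map = SIX_ODOR_CONTINGENCY[six_odor_phase(day)]
        roles = six_odor_roles(day)
        us_delay = US_DELAY_SIX_ODOR_S
    else:
        roles = lick_nolick_roles()
        us_delay = US_DELAY_LICK_NOLICK_S

    orders = _block_orders(n_blocks, rng)
    rows = []
    t = start_s
    trial = 0
    for block in range(n_blocks):
        for odor_id in orders[block]:
            chem = ODOR_CHEMICALS[odor_id]
            onset, offset = t, t + ODOR_DURATION_S
            delay = rng.uniform(*us_delay)
            iti = rng.uniform(*ITI_RANGE_S)
            if paradigm == "six_odor":
                cont = cont_map[chem]
                p_reward = 1.0 if cont == "S" else 0.0
                us_type = {"S": "sucrose", "P": "airpuff", "X": "none"}[cont]
                us_time = offset + delay if us_type != "none" else np.nan
                spout_present = True
                retract = ret = np.nan
            else:
                p_reward, spout_present = LICK_NOLICK_DESIGN[chem]
                cont = "S" if p_reward > 0 else "X"
                rewarded = rng.random() < p_reward
                us_type = "sucrose" if rewarded else "none"
                us_time = offset + delay if rewarded else np.nan
                if spout_present:
                    retract = ret = np.nan
                else:
                    retract = onset - SPOUT_RETRACT_BEFORE_ONSET_S
                    ret = offset + us_delay[0] - SPOUT_RETURN_BEFORE_US_S
            rows.append(dict(
                trial=trial, block=block, odor_id=int(odor_id), odor_name=chem,
                odor_class=ODOR_CLASS[chem], contingency=cont, role=roles[chem],
                reward_probability=p_reward, spout_present=spout_present,
                onset_s=onset, offset_s=offset, us_type=us_type,
                us_time_s=us_time, spout_retract_s=retract, spout_return_s=ret,
                iti_s=iti,
            ))
            t = offset + iti
            trial += 1
    df = pd.DataFrame(rows)
    duration = float(df["offset_s"].iloc[-1] + 20.0)
    return TrialSchedule(trials=df, paradigm=paradigm, day=day, duration_s=duration)
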