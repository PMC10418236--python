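"""End-to-end orchestration: simulate → preprocess → analyze → report.

Each (population, day) cohort member produces a fixed bundle of tidy CSV
tables under the output directory; a manifest records the config hash and
derived seeds so any table can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import _windows, behavior, geometry, pop_decoding, single_neuron
from .config import RunConfig
from .ground_truth import (PopulationConfig, identity_only_config,
                           ot_like_config, sample_ground_truth_population,
                           vp_like_config)
from .io import write_csv
from .preprocess import preprocess_session
from .responsiveness import call_responsiveness
from .schedule import build_conditioning_schedule
from .simulate import synthesize_session

log = logging.getLogger("odorpop.pipeline")

_PRESETS = {
    "vp_like": vp_like_config,
    "ot_like": ot_like_config,
    "identity_only": identity_only_config,
}


def population_from_block(block, seed: int):
    if block.preset == "custom":
        cfg = PopulationConfig(n_neurons=block.n_neurons, region=block.region,
                               class_fractions=block.class_fractions)
    elif block.preset in _PRESETS:
        cfg = _PRESETS[block.preset](n_neurons=block.n_neurons)
        cfg.region = block.region
    else:
        raise ValueError(f"unknown population preset {block.preset!r}")
    return sample_ground_truth_population(cfg, seed)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis for every (population, day) in the config.

    Returns a manifest dict; writes, per cohort member, seven tables:
    responsiveness, quadrants, generalization, pr_summary, distances,
    behavior, clusters (plus a quadrant-composition JSON and manifest.json).
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    an = config.analysis
    ss = np.random.SeedSequence(config.seed)
    manifest = {"config_hash": _config_hash(config), "seed": config.seed,
                "members": []}
    for p_i, block in enumerate(config.populations):
        for day in config.paradigm.days:
            child = ss.spawn(1)[0]
            seeds = child.generate_state(3) % (2 ** 31)
            tag = f"{block.region}_day{day}"
            stage = "simulate"
            try:
                pop = population_from_block(block, int(seeds[0]))
                sch = build_conditioning_schedule(
                    config.paradigm.name, config.paradigm.n_blocks, day=day,
                    seed=int(seeds[1]))
                ses = synthesize_session(sch, pop, int(seeds[2]),
                                         frame_rate=config.frame_rate_hz)
                stage = "preprocess"
                dff, tensor = preprocess_session(
                    ses, window_frames=an.baseline_window_frames,
                    stride_frames=an.baseline_stride_frames,
                    pre_s=an.pre_s, post_s=an.post_s)
                stage = "analyze"
                _analyze_member(ses, dff, tensor, an, out, tag)
            except Exception as e:
                raise RuntimeError(f"pipeline failed at stage {stage!r} "
                                   f"for {tag}: {e}") from e
            manifest["members"].append(
                {"region": block.region, "day": day,
                 "seeds": [int(s) for s in seeds]})
            log.info("finished %s", tag)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _analyze_member(ses, dff, tensor, an, out: Path, tag: str) -> None:
    roles = sorted(tensor.labels["role"].unique())
    fs = tensor.frame_rate
    is_ln = ses.schedule.paradigm == "lick_nolick"
    window = (_windows.anticipatory_window(fs) if is_ln
              else _windows.last_odor_second(fs))

    calls = call_responsiveness(tensor, alpha=an.alpha)
    write_csv(calls, out / f"responsiveness_{tag}.csv")

    scores = single_neuron.score_all_pairs(tensor, window=window)
    inter_pair = ("N_hi", "N_X") if is_ln else ("S_K", "X_K")
    intra_pair = ("L_hi", "N_hi") if is_ln else ("S_K", "S_T")
    inter = scores[scores["pair"] == f"{inter_pair[0]}|{inter_pair[1]}"] \
        .sort_values("neuron")["auroc"].to_numpy()
    intra = scores[scores["pair"] == f"{intra_pair[0]}|{intra_pair[1]}"] \
        .sort_values("neuron")["auroc"].to_numpy()
    quad = single_neuron.categorize_quadrants(inter, intra,
                                              threshold=an.auroc_threshold)
    write_csv(quad, out / f"quadrants_{tag}.csv")
    (out / f"quadrant_composition_{tag}.json").write_text(
        json.dumps(single_neuron.quadrant_composition(quad), indent=2))

    design = pop_decoding.build_design(
        tensor, window=window, animal_id=ses.animal_id, day=ses.day,
        paradigm=ses.schedule.paradigm)
    gm = pop_decoding.generalization_matrix(design, k=an.k_folds)
    gm.accuracies.to_csv(out / f"generalization_{tag}.csv",
                         float_format="%.10g")

    pr_full = geometry.participation_ratio(dff.T)
    sub = geometry.subsampled_pr(dff.T, k=min(an.k_subsample, dff.shape[0]),
                                 n_repeats=an.n_pr_repeats, seed=0)
    write_csv(pd.DataFrame([{"pr_full": pr_full, **sub}]),
              out / f"pr_summary_{tag}.csv")

    write_csv(geometry.distance_trajectories(tensor),
              out / f"distances_{tag}.csv")

    licks = behavior.lick_selectivity(ses.schedule, ses.licks, fs)
    write_csv(licks.per_trial, out / f"behavior_{tag}.csv")

    clus = geometry.cluster_pooled_responses([tensor], k=3 if is_ln else 6)
    write_csv(pd.DataFrame({"neuron": clus.retained, "cluster": clus.labels}),
              out / f"clusters_{tag}.csv")
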