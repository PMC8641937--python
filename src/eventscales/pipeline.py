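"""End-to-end orchestration of the fMRI and reading pipelines.

``run_pipeline`` wires the stages together on synthetic data: corpus
generation, (optionally) scaled-down language-model training and feature
extraction, design assembly, vertex-wise encoding, intersubject
correlation and ROI selection, gradient fitting, surprisal-gated
connectivity, and the reading branch.  Every stage is seeded from the
single pipeline seed, so a run is reproducible from config alone.
"""

from __future__ import annotations

import json
import logging
import time
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import gradient as grad
from . import isc as isc_mod
from . import reading as reading_mod
from .design import ScrambleSet, assemble_design, hrf_convolve
from .features import feature_table
from .lm import LMConfig, train
from .ridge import CVScheme, fit_cv, null_calibrate, lambda_grid
from .synthetic import (
    SPILLOVER_LAGS,
    default_ground_truth,
    generate_cohort,
    generate_corpus,
    generate_reading_logs,
    synthetic_feature_table,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "tr": 0.947,
    "run_length": 96,
    "n_runs": 8,
    "n_participants": 6,
    "sheet_shape": (24, 48),
    "corpus": {"vocab_size": 24, "n_levels": 3, "mean_event_lengths": [4, 16, 64], "length": 2600},
    "train_lm": False,  # True: tiny HM-LSTM features; False: planted features
    "lm": {"n_layers": 5, "units": 16, "embed_dim": 8, "context_len": 48},
    "planted_slope_mm": 8.0,
    "noise_sd": 0.9,
    "gain": 1.5,
    # profile smoothing scaled to the sheet (the 70 mm full-scale default
    # would span the whole 48 mm demo axis)
    "smooth_window_mm": 12.0,
    "coupling": [(s, s + 1, 1.5) for s in range(1, 5)]
    + [(s + 1, s, 1.5) for s in range(1, 5)],
    "spillover": [0.0, 0.0, 0.3, 0.15, 0.05, 0.0, 0.0, 0.0],
    "n_scrambles": 40,
    "n_boot": 400,
    "n_shuffle": 1000,
    "n_null_ppi": 60,
    "lambda_points": 30,
    "constrained": True,
}


def run_pipeline(config: Optional[Dict] = None) -> Dict:
    """Run the full synthetic-data analysis and return a JSON-ready report."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    t0 = time.time()
    report: Dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}}

    # --- simulate ---------------------------------------------------------
    corpus = generate_corpus(seed=seed, **cfg["corpus"])
    n_words = len(corpus.tokens)
    if cfg["train_lm"]:
        lmcfg = LMConfig(
            vocab_size=cfg["corpus"]["vocab_size"], variant="hmlstm", **cfg["lm"]
        )
        res = train(corpus.tokens, lmcfg, seed=seed, max_epochs=3, seq_len=48)
        features = feature_table(res.model, corpus.tokens)
        features = features.fillna(features.mean())
        report["stages"]["train"] = {"log": res.log}
    else:
        features = synthetic_feature_table(n_words, seed=seed + 1)

    truth = default_ground_truth(
        slope_mm=cfg["planted_slope_mm"],
        sheet_shape=tuple(cfg["sheet_shape"]),
        is_origin=4.0,
        seed_coupling=[tuple(c) for c in cfg["coupling"]],
        spillover_weights=cfg["spillover"],
    )
    cohort = generate_cohort(
        corpus,
        features,
        truth,
        n_participants=int(cfg["n_participants"]),
        n_runs=int(cfg["n_runs"]),
        noise_sd=float(cfg["noise_sd"]),
        gain=float(cfg["gain"]),
        seed=seed + 2,
        sheet_shape=tuple(cfg["sheet_shape"]),
        tr=float(cfg["tr"]),
        run_length=int(cfg["run_length"]),
    )
    report["stages"]["simulate"] = {
        "n_words": int(n_words),
        "n_vertices": int(cohort.participants[0].n_vertices),
    }

    # --- design -----------------------------------------------------------
    design = assemble_design(
        features,
        cohort.word_onsets,
        cohort.word_runs,
        cohort.run_length,
        cohort.tr,
        annotations=corpus.annotations,
        acoustic=rng.normal(0, 1, (cohort.n_runs * cohort.run_length, 9)),
    )
    grid = lambda_grid(int(cfg["lambda_points"]))
    scrambles = ScrambleSet(design, n=int(cfg["n_scrambles"]), seed=seed + 3)

    # --- isc / roi --------------------------------------------------------
    iscres = isc_mod.pairwise_isc(cohort.participants)
    iscres = isc_mod.bootstrap_test(iscres, n=int(cfg["n_boot"]), seed=seed + 4)
    roi = isc_mod.select_roi(iscres.q, cohort.participants[0].parcel)
    report["stages"]["isc"] = {
        "median_isc_max": float(np.nanmax(iscres.group_map)),
        "roi_vertices": int(roi.sum()),
    }

    # --- encoding ---------------------------------------------------------
    scale_cols = [f"surprisal_s{s}" for s in range(1, 6)]
    weight_maps = []  # [participant][scale] WeightMap over ROI vertices
    zmaps = []
    roi_idx = np.flatnonzero(roi) if roi.any() else np.arange(cohort.participants[0].n_vertices)
    coords_roi = cohort.participants[0].coords[roi_idx]
    for part in cohort.participants:
        Y = np.concatenate(part.runs, axis=1).T[:, roi_idx]
        enc = fit_cv(design, Y)
        enc = null_calibrate(design, scrambles, Y, enc)
        maps = [
            grad.WeightMap(weights=enc.weights[design.columns.index(c)], coords=coords_roi)
            for c in scale_cols
        ]
        weight_maps.append(maps)
        zmaps.append(enc.z_accuracy)
    zstack = np.stack(zmaps)
    planted = truth.vertex_scale[roi_idx] > 0
    report["stages"]["encode"] = {
        "mean_z_accuracy": float(zstack.mean()),
        "mean_z_accuracy_planted_vertices": float(zstack[:, planted].mean())
        if planted.any()
        else None,
    }

    # --- gradient ---------------------------------------------------------
    mode = "constrained" if cfg["constrained"] else "unconstrained"
    smooth = float(cfg.get("smooth_window_mm", 70.0))
    peaksets = []
    for maps in weight_maps:
        profiles, positions = [], None
        for wm in maps:
            positions, prof = grad.weight_profile(wm, smooth_window=smooth)
            profiles.append(prof)
        peaksets.append(grad.find_peaks(profiles, positions, mode))
    slope = grad.fit_gradient(peaksets, n_shuffle=int(cfg["n_shuffle"]), seed=seed + 5)
    report["stages"]["gradient"] = {
        "grand_average_slope_mm": slope.grand_average,
        "p": slope.p,
        "planted_slope_mm": float(cfg["planted_slope_mm"]),
    }

    # --- connectivity -----------------------------------------------------
    grand_median = np.median(np.stack([ps.coordinates for ps in peaksets]), axis=0)
    n_scales = 5
    regs = np.zeros((n_scales, cohort.n_runs, cohort.run_length))
    for r in range(cohort.n_runs):
        w = cohort.word_runs == r
        for s in range(n_scales):
            x = hrf_convolve(
                list(zip(cohort.word_onsets[r], features.loc[w, scale_cols[s]])),
                cohort.run_length,
                cohort.tr,
            )
            sd = x.std()
            regs[s, r] = (x - x.mean()) / sd if sd > 0 else 0.0
    seeds = [
        conn.define_seeds(
            maps, grand_median, [run[roi_idx] for run in part.runs]
        )
        for maps, part in zip(weight_maps, cohort.participants)
    ]
    ppi = conn.hypothesis_distance(
        seeds, regs, n_null=int(cfg["n_null_ppi"]), seed=seed + 6, grid=grid
    )
    mats = [conn.fit_ppi(s, regs, grid=grid) for s in seeds]
    direction = conn.directionality(mats, n_perm=int(cfg["n_shuffle"]), seed=seed + 7)
    report["stages"]["ppi"] = {
        "mean_distance": ppi["mean_distance"],
        "p": ppi["p"],
        "directionality": direction,
    }

    # --- reading ----------------------------------------------------------
    logs = generate_reading_logs(
        features,
        truth,
        n_participants=1,
        noise_sd=0.15,
        seed=seed + 8,
        annotations=corpus.annotations,
    )
    rec, prestats = reading_mod.preprocess_reading(logs, seed=seed + 9)
    nuis = pd.DataFrame(
        {
            "word_length": corpus.annotations["length"],
            "word_frequency": corpus.annotations["zipf"],
            "content_flag": corpus.annotations["content"],
        }
    )
    rdesign = reading_mod.build_lagged_design(
        features[["surprisal_full"]], rec, nuisance=nuis
    )
    rres = reading_mod.fit_reading(
        rdesign,
        rec.loc[rdesign.rows, "z_speed"].to_numpy(),
        n_scrambles=int(cfg["n_scrambles"]),
        seed=seed + 10,
        grid=grid,
    )
    report["stages"]["reading"] = {
        "accuracy": float(rres.accuracy[0]),
        "z_accuracy": float(rres.z_accuracy[0]),
        "run_slope_p": prestats.get("run_slope_p"),
    }

    report["elapsed_s"] = time.time() - t0
    return report


def report_to_json(report: Dict) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    return json.dumps(report, indent=2, default=default)
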