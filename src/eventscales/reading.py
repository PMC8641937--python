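"""Self-paced-reading pipeline: exclusions, speed transform, lagged
design and the cross-validated ridge reading model.

Reading times are bounded to (0.001 s, 6 s), inverted into speed,
cleaned of within-run outliers (3 SD) and z-scored per run.  Features of
predictiveness and nuisance covariates enter the design at word-position
lags -2..5 to capture spill-over effects; the model reuses the shared
ridge engine with one run per cross-validation fold, and the unique
contribution of predictiveness is the observed encoding accuracy
z-scored against refits with scrambled predictiveness columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import phase_scramble
from .ridge import CVScheme, EncodingResult, fit_cv, _ridge_solve, _colwise_corr

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_reading",
    "build_lagged_design",
    "fit_reading",
    "ReadingDesign",
]

LAGS = np.arange(-2, 6)


def preprocess_reading(
    logs: pd.DataFrame,
    *,
    min_rt: float = 0.001,
    max_rt: float = 6.0,
    sd_criterion: float = 3.0,
    run_slope_perms: int = 10000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Exclusion, speed transform and per-run z-scoring of reading logs.

    Order of operations: (1) reading times outside [min_rt, max_rt] are
    excluded; (2) remaining times are inverted into speed (1/s); (3)
    trials exceeding ``sd_criterion`` standard deviations within a run
    are excluded; (4) retained speeds are z-scored per run.  Runs with
    fewer than three retained trials are dropped.  Also reports a
    permutation test of the across-run speed slope (practice effect),
    built from linear fits to shuffled run-mean speeds.
    """
    if logs.empty:
        raise ValueError("empty reading logs")
    df = logs.copy()
    df["exclusion"] = ""
    bad = (df["rt_s"] < min_rt) | (df["rt_s"] > max_rt)
    df.loc[bad, "exclusion"] = "bounds"
    df["speed"] = np.where(bad, np.nan, 1.0 / df["rt_s"])

    for run, sub in df.groupby("run"):
        ok = sub["exclusion"] == ""
        s = sub.loc[ok, "speed"]
        if len(s) < 3:
            df.loc[sub.index, "exclusion"] = np.where(
                ok, "run_dropped", df.loc[sub.index, "exclusion"]
            )
            logger.warning("run %s dropped: fewer than 3 retained trials", run)
            continue
        # applied to a fixpoint so that rerunning the preprocessing on its
        # own output changes nothing
        while True:
            mu, sd = s.mean(), s.std(ddof=0)
            if sd <= 0:
                break
            out = np.abs(s - mu) > sd_criterion * sd
            if not out.any():
                break
            df.loc[s.index[out], "exclusion"] = "sd"
            s = s[~out]

    df["z_speed"] = np.nan
    for run, sub in df.groupby("run"):
        ok = sub["exclusion"] == ""
        s = sub.loc[ok, "speed"]
        if len(s) < 3:
            continue
        sd = s.std(ddof=0)
        if sd < 1e-12:
            df.loc[s.index, "z_speed"] = 0.0
            logger.warning("degenerate (constant) speeds in run %s; z set to 0", run)
        else:
            df.loc[s.index, "z_speed"] = (s - s.mean()) / sd

    # practice effect: slope of mean speed across runs vs shuffled-run null
    means = df[df["exclusion"] == ""].groupby("run")["speed"].mean()
    runs = np.arange(len(means), dtype=float)
    stats: dict = {"run_means": means.to_dict()}
    if len(means) >= 2:
        X = np.column_stack([np.ones_like(runs), runs])
        obs = np.linalg.lstsq(X, means.to_numpy(), rcond=None)[0][1]
        rng = np.random.default_rng(seed)
        null = np.empty(run_slope_perms)
        vals = means.to_numpy()
        for i in range(run_slope_perms):
            null[i] = np.linalg.lstsq(X, rng.permutation(vals), rcond=None)[0][1]
        stats["run_slope"] = float(obs)
        stats["run_slope_p"] = float((1 + np.sum(np.abs(null) >= abs(obs))) / (run_slope_perms + 1))
    return df, stats


@dataclass
class ReadingDesign:
    X: np.ndarray
    columns: List[str]
    run_of_row: np.ndarray
    predictiveness_columns: List[str]
    rows: np.ndarray  # indices into the trial frame
    word_index: Optional[np.ndarray] = None
    base_features: Optional[Dict[str, np.ndarray]] = None  # word series pre-lagging
    lags: np.ndarray = field(default_factory=lambda: LAGS.copy())


def build_lagged_design(
    features: pd.DataFrame,
    records: pd.DataFrame,
    *,
    nuisance: Optional[pd.DataFrame] = None,
    lags: np.ndarray = LAGS,
    add_missing_indicator: bool = True,
) -> ReadingDesign:
    """Trial-wise design with lagged copies of every feature column.

    Lag ``k`` of a column at trial ``t`` holds the feature of the word
    ``k`` positions earlier (negative lags look ahead); edge trials
    lacking a lag get 0, with an optional shared missing-lag indicator
    column.  Nuisance covariates (length, frequency, content flag) are
    lagged the same way; the trial-number covariate is appended unlagged.
    Only retained (non-excluded) trials enter the design.
    """
    keep = records["exclusion"] == "" if "exclusion" in records else np.ones(len(records), bool)
    rec = records[keep]
    word_idx = rec["word_index"].to_numpy()
    n_words = len(features)

    base = features.copy()
    if nuisance is not None:
        for col in nuisance.columns:
            base[col] = nuisance[col].to_numpy()
    cols: List[np.ndarray] = []
    names: List[str] = []
    missing_any = np.zeros(len(rec), dtype=bool)
    for col in base.columns:
        series = base[col].to_numpy(dtype=float)
        series = np.nan_to_num(series, nan=np.nanmean(series))
        lagged, miss = _lag_columns(series, word_idx, lags)
        missing_any |= miss
        cols.extend(lagged)
        names.extend(f"{col}_lag{lag}" for lag in lags)
    cols.append(rec["trial"].to_numpy(dtype=float))
    names.append("trial_number")
    if add_missing_indicator:
        cols.append(missing_any.astype(float))
        names.append("missing_lag")
    X = np.column_stack(cols)
    pred_cols = [
        n for n in names if n.startswith(("surprisal", "entropy", "dissimilarity"))
    ]
    return ReadingDesign(
        X=X,
        columns=names,
        run_of_row=rec["run"].to_numpy(),
        predictiveness_columns=pred_cols,
        rows=rec.index.to_numpy(),
        word_index=word_idx,
        base_features={
            c: np.nan_to_num(features[c].to_numpy(dtype=float),
                             nan=float(np.nanmean(features[c])))
            for c in features.columns
        },
        lags=np.asarray(lags),
    )


def _lag_columns(series: np.ndarray, word_idx: np.ndarray, lags: np.ndarray):
    out, missing = [], np.zeros(len(word_idx), dtype=bool)
    for lag in lags:
        src = word_idx - lag
        valid = (src >= 0) & (src < len(series))
        vals = np.zeros(len(word_idx))
        vals[valid] = series[src[valid]]
        missing |= ~valid
        out.append(vals)
    return out, missing


def fit_reading(
    design: ReadingDesign,
    z_speed: np.ndarray,
    *,
    n_scrambles: int = 500,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
) -> EncodingResult:
    """Cross-validated ridge fit of z-scored reading speed with a
    scrambled-predictiveness null.

    Folds are single runs.  The null refits the model ``n_scrambles``
    times with phase-scrambled predictiveness columns (nuisance intact)
    using the frozen per-fold penalties, and the observed accuracy is
    z-scored against the null accuracies.
    """
    run_ids = np.unique(design.run_of_row)
    remap = {r: i for i, r in enumerate(run_ids)}
    run_of_row = np.array([remap[r] for r in design.run_of_row])
    scheme = CVScheme.single_runs(len(run_ids))

    # z-score columns within run; constant columns left centred
    X = design.X.astype(float).copy()
    for r in range(len(run_ids)):
        m = run_of_row == r
        seg = X[m]
        sd = seg.std(axis=0)
        X[m] = np.where(sd > 1e-12, (seg - seg.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)

    res = fit_cv(X, np.asarray(z_speed, float), run_of_row=run_of_row, scheme=scheme, grid=grid)
    res.columns = design.columns

    # the null scrambles each base predictiveness word series once and
    # rebuilds its lagged copies, preserving the lag-correlation structure
    # of the observed design
    pred_stems = {c.rsplit("_lag", 1)[0] for c in design.predictiveness_columns}
    rng = np.random.default_rng(seed)
    masks = scheme.row_masks(run_of_row)
    lambdas = np.atleast_2d(res.lambdas)
    y = np.asarray(z_speed, float)[:, None]
    null_acc = np.empty(n_scrambles)
    for i in range(n_scrambles):
        Xs = X.copy()
        for stem in pred_stems:
            s = int(rng.integers(0, 2**31))
            surr = phase_scramble(design.base_features[stem], 1, s)[0]
            lagged, _ = _lag_columns(surr, design.word_index, design.lags)
            for lag, vals in zip(design.lags, lagged):
                j = design.columns.index(f"{stem}_lag{lag}")
                for r in range(len(run_ids)):
                    m = run_of_row == r
                    sd = vals[m].std()
                    Xs[m, j] = (vals[m] - vals[m].mean()) / sd if sd > 1e-12 else 0.0
        fold_r = np.empty(len(masks))
        for k, test in enumerate(masks):
            train = ~test
            mu = y[train].mean(axis=0)
            W = _ridge_solve(Xs[train], y[train] - mu, lambdas[k])
            fold_r[k] = _colwise_corr(Xs[test] @ W, y[test] - mu)[0]
        null_acc[i] = np.arctanh(np.clip(fold_r.mean(), -0.999999, 0.999999))
    sd = null_acc.std()
    res.null_accuracy = null_acc
    res.z_accuracy = np.array([
        0.0 if sd < 1e-12 else (res.accuracy[0] - null_acc.mean()) / sd
    ])
    if sd < 1e-12:
        logger.warning("degenerate reading null spread; z set to 0")
    return res


def recover_lag_profile(
    design: ReadingDesign, z_speed: np.ndarray, column_stem: str = "surprisal_full"
) -> Dict[int, float]:
    """Ordinary least squares refit returning the lag profile of one
    feature (used as an oracle for spill-over recovery)."""
    X = design.X
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xn = np.where(sd > 1e-12, Xc / np.where(sd > 0, sd, 1.0), 0.0)
    y = np.asarray(z_speed, float)
    beta, *_ = np.linalg.lstsq(Xn, y - y.mean(), rcond=None)
    out = {}
    for j, name in enumerate(design.columns):
        if name.startswith(column_stem + "_lag"):
            out[int(name.rsplit("lag", 1)[1])] = float(beta[j])
    return out
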