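"""Surprisal-gated effective connectivity between time-scale seeds.

Seeds are spheres placed at the peak location of each time scale of
surprisal; the activity of each (target) seed is regressed onto the
physiological, psychological and psychophysiological-interaction (PPI)
regressors of all other (predictor) time scales within the same
cross-validated ridge scheme used for the encoding models.  The
resulting 5x5 predictor-weight matrix (empty main diagonal; upper
triangle top-down, lower triangle bottom-up) is compared to a hypothesis
matrix that predicts increased coupling between neighbouring time scales
when surprisal is high, using Euclidean distance and a circular-shift
null that preserves autocorrelation while destroying stimulus alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .gradient import WeightMap, weight_profile, _local_maxima
from .ridge import CVScheme, fit_cv

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "hypothesis_matrix",
    "define_seeds",
    "build_ppi_design",
    "fit_ppi",
    "hypothesis_distance",
    "directionality",
]


@dataclass
class SeedSet:
    centers: np.ndarray  # (n_scales, 2) mm (anterior-posterior, inferior-superior)
    radius: float
    members: List[np.ndarray]  # vertex indices per seed
    series: List[List[np.ndarray]]  # [scale][run] mean activity
    fallback: np.ndarray  # per-scale flag: empty sphere, nearest vertex used


def hypothesis_matrix(n_scales: int = 5) -> np.ndarray:
    """The hypothesized PPI pattern: first off-diagonals +1 (neighbouring
    time scales couple when surprisal is high), all other off-diagonal
    entries -1, main diagonal NaN."""
    H = -np.ones((n_scales, n_scales))
    for i in range(n_scales - 1):
        H[i, i + 1] = 1.0
        H[i + 1, i] = 1.0
    np.fill_diagonal(H, np.nan)
    return H


def define_seeds(
    maps: Sequence[WeightMap],
    grand_median_is: np.ndarray,
    runs: List[np.ndarray],
    *,
    radius: float = 5.0,
    ap_window: Tuple[float, float] = (2.0, 5.0),
) -> SeedSet:
    """Place one spherical seed per time scale on a participant's sheet.

    The inferior-superior coordinate of scale s is the grand-median
    constrained peak ``grand_median_is[s]``; the anterior-posterior
    coordinate is found by shifting a moving-average window (width
    ``ap_window[0]`` mm along the anterior-posterior axis, height
    ``ap_window[1]`` mm centred on the inferior-superior coordinate)
    along the anterior-posterior axis of that scale's weight map and
    taking the highest local maximum of the smoothed profile.  The seed
    series is the mean activity of vertices within ``radius`` mm; an
    empty sphere falls back to the nearest vertex and is flagged.
    """
    n_scales = len(maps)
    coords = maps[0].coords
    width, height = ap_window
    centers = np.empty((n_scales, 2))
    members: List[np.ndarray] = []
    fallback = np.zeros(n_scales, dtype=bool)
    series: List[List[np.ndarray]] = []
    for s in range(n_scales):
        is_c = grand_median_is[s]
        band = np.abs(coords[:, 1] - is_c) <= height / 2.0
        ap_vals = np.unique(coords[band, 0]) if band.any() else np.unique(coords[:, 0])
        prof = np.full(ap_vals.size, np.nan)
        for i, ap in enumerate(ap_vals):
            sel = band & (np.abs(coords[:, 0] - ap) <= width / 2.0)
            if sel.any():
                prof[i] = maps[s].weights[sel].mean()
        ok = ~np.isnan(prof)
        prof = np.interp(ap_vals, ap_vals[ok], prof[ok]) if ok.any() else np.zeros_like(prof)
        cand = _local_maxima(prof)
        cand = cand[prof[cand] > 0]
        ap_c = ap_vals[cand[np.argmax(prof[cand])]] if cand.size else ap_vals[np.argmax(prof)]
        centers[s] = (ap_c, is_c)
        d = np.linalg.norm(coords - centers[s], axis=1)
        mem = np.flatnonzero(d <= radius)
        if mem.size == 0:
            mem = np.array([int(np.argmin(d))])
            fallback[s] = True
            logger.warning("empty seed sphere for scale %d; nearest vertex used", s + 1)
        members.append(mem)
        series.append([run[mem].mean(axis=0) for run in runs])
    return SeedSet(centers=centers, radius=radius, members=members, series=series, fallback=fallback)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 1e-12 else x - x.mean()


def build_ppi_design(
    target_scale: int,
    seeds: SeedSet,
    surprisal_regs: np.ndarray,
) -> Tuple[np.ndarray, List[str]]:
    """Regressors for one target seed: for every other (predictor) scale,
    the physiological seed series, the psychological HRF-convolved
    surprisal series of that scale, and their pointwise product, all
    z-scored per run.

    ``surprisal_regs`` is (n_scales, n_runs, run_length), already
    HRF-convolved and sample-aligned.  Returns the stacked (samples,
    3 * (n_scales - 1)) design and the column names; PPI columns are named
    ``ppi_s{k}``.
    """
    n_scales = len(seeds.series)
    n_runs = len(seeds.series[0])
    if surprisal_regs.shape[0] != n_scales:
        raise ValueError("one surprisal series per scale required")
    cols: List[np.ndarray] = []
    names: List[str] = []
    for s in range(n_scales):
        if s == target_scale:
            continue
        phys_runs, psych_runs, ppi_runs = [], [], []
        for r in range(n_runs):
            phys = np.asarray(seeds.series[s][r], dtype=float)
            psych = np.asarray(surprisal_regs[s, r], dtype=float)
            if phys.shape != psych.shape:
                raise ValueError("misaligned seed and surprisal series")
            zphys, zpsych = _zscore(phys), _zscore(psych)
            phys_runs.append(zphys)
            psych_runs.append(zpsych)
            ppi_runs.append(_zscore(zphys * zpsych))
        cols += [np.concatenate(phys_runs), np.concatenate(psych_runs), np.concatenate(ppi_runs)]
        names += [f"phys_s{s + 1}", f"psych_s{s + 1}", f"ppi_s{s + 1}"]
    return np.column_stack(cols), names


def fit_ppi(
    seeds: SeedSet,
    surprisal_regs: np.ndarray,
    *,
    scheme: Optional[CVScheme] = None,
    grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """The PPI weight matrix for one participant.

    Each seed is selected as target once; its series is regressed onto
    the joint 12-column design of all predictor scales within the paired
    cross-validation scheme, and the fold-averaged PPI weights fill the
    target's matrix row (off-diagonal).  Returns an (n_scales, n_scales)
    matrix with NaN on the main diagonal.
    """
    n_scales = len(seeds.series)
    n_runs = len(seeds.series[0])
    run_len = len(seeds.series[0][0])
    run_of_row = np.repeat(np.arange(n_runs), run_len)
    if scheme is None:
        scheme = CVScheme.paired_runs(n_runs)
    M = np.full((n_scales, n_scales), np.nan)
    for tgt in range(n_scales):
        X, names = build_ppi_design(tgt, seeds, surprisal_regs)
        y = np.concatenate([_zscore(np.asarray(seeds.series[tgt][r])) for r in range(n_runs)])
        res = fit_cv(X, y, run_of_row=run_of_row, scheme=scheme, grid=grid)
        for j, name in enumerate(names):
            if name.startswith("ppi_s"):
                src = int(name[5:]) - 1
                M[tgt, src] = res.weights[j]
    return M


def hypothesis_distance_of(matrix: np.ndarray) -> float:
    """Euclidean distance of the 20 off-diagonal entries to the
    hypothesis matrix."""
    n = matrix.shape[0]
    H = hypothesis_matrix(n)
    off = ~np.eye(n, dtype=bool)
    if np.isnan(matrix[off]).any():
        raise ValueError("incomplete PPI matrix")
    return float(np.linalg.norm(matrix[off] - H[off]))


def hypothesis_distance(
    participant_seeds: Sequence[SeedSet],
    surprisal_regs: np.ndarray,
    *,
    n_null: int = 10000,
    seed: int = 0,
    scheme: Optional[CVScheme] = None,
    grid: Optional[np.ndarray] = None,
    matrices: Optional[Sequence[np.ndarray]] = None,
) -> dict:
    """Group-mean Euclidean distance to the hypothesis matrix, ranked
    against a circular-shift null.

    For each null iteration, every participant's target seed series are
    circularly shifted by a uniformly drawn whole number of runs (1..7,
    in samples) before refitting the PPI models, which preserves
    autocorrelation but destroys stimulus alignment.  ``matrices`` may
    supply precomputed observed PPI matrices to avoid refitting.
    """
    rng = np.random.default_rng(seed)
    if matrices is None:
        matrices = [fit_ppi(s, surprisal_regs, scheme=scheme, grid=grid) for s in participant_seeds]
    obs_d = np.array([hypothesis_distance_of(M) for M in matrices])
    obs = float(obs_d.mean())

    n_runs = len(participant_seeds[0].series[0])
    run_len = len(participant_seeds[0].series[0][0])
    null = np.empty(n_null)
    for b in range(n_null):
        dists = []
        for seeds in participant_seeds:
            shift = int(rng.integers(1, 8)) * run_len
            shifted = _shift_seeds(seeds, shift)
            M = fit_ppi(shifted, surprisal_regs, scheme=scheme, grid=grid)
            dists.append(hypothesis_distance_of(M))
        null[b] = np.mean(dists)
    p = float((1 + np.sum(null <= obs)) / (n_null + 1))
    return {"distances": obs_d, "mean_distance": obs, "null": null, "p": p}


def _shift_seeds(seeds: SeedSet, shift: int) -> SeedSet:
    """Circularly shift every seed's concatenated series by ``shift``
    samples (targets only; the predictor design is rebuilt from the same
    shifted physiological series, matching a whole-session rotation)."""
    n_runs = len(seeds.series[0])
    run_len = len(seeds.series[0][0])
    new_series = []
    for s in range(len(seeds.series)):
        cat = np.concatenate(seeds.series[s])
        cat = np.roll(cat, shift)
        new_series.append([cat[r * run_len : (r + 1) * run_len] for r in range(n_runs)])
    return SeedSet(
        centers=seeds.centers,
        radius=seeds.radius,
        members=seeds.members,
        series=new_series,
        fallback=seeds.fallback,
    )


def compare_distances_between_models(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permutation test on the difference of mean hypothesis distances."""
    a, b = np.asarray(dist_a, float), np.asarray(dist_b, float)
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(a.size) < 0.5
        null[i] = np.where(swap, b, a).mean() - np.where(swap, a, b).mean()
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return float(obs), p


def directionality(
    matrices: Sequence[np.ndarray],
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Mean top-down (upper triangle) vs bottom-up (lower triangle) PPI
    weight, with a paired sign-flip permutation test across participants."""
    tops, bottoms = [], []
    for M in matrices:
        n = M.shape[0]
        iu = np.triu_indices(n, 1)
        il = np.tril_indices(n, -1)
        tops.append(float(np.nanmean(M[iu])))
        bottoms.append(float(np.nanmean(M[il])))
    tops, bottoms = np.array(tops), np.array(bottoms)
    diff = tops - bottoms
    rng = np.random.default_rng(seed)
    obs = diff.mean()
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = (diff * rng.choice([-1, 1], diff.size)).mean()
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return {
        "top_down": float(tops.mean()),
        "bottom_up": float(bottoms.mean()),
        "difference": float(obs),
        "p": p,
    }
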