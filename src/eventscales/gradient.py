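"""From vertex-wise surprisal weights to the time-scale gradient.

The weight map of each time scale is collapsed across the
anterior-posterior axis into a 1-D profile along the inferior-superior
axis (2 mm windows in 1 mm steps, robust-linear smoothing over 70 mm),
peaks are selected per time scale (unconstrained, or constrained to the
dorsal stream), and a linear gradient is fit to the peak coordinates
across time scales with a coordinate-shuffle permutation null.  The
module also provides cluster-based permutation tests on the sheet, the
rotation (spatial-specificity) analysis, and the paired encoding-accuracy
contrast between language models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMap",
    "PeakSet",
    "SlopeResult",
    "weight_profile",
    "find_peaks",
    "fit_gradient",
    "cluster_permutation_map",
    "rotation_analysis",
    "compare_accuracy_maps",
]


@dataclass
class WeightMap:
    """Per-vertex weights for one (model, scale, participant) with sheet
    coordinates (anterior-posterior, inferior-superior) in mm."""

    weights: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.coords.shape != (self.weights.size, 2):
            raise ValueError("coords must be (n_vertices, 2)")


@dataclass
class PeakSet:
    coordinates: np.ndarray  # (n_scales,) inferior-superior mm
    mode: str  # "unconstrained" | "constrained"
    fallback: np.ndarray  # per-scale flag: no local maximum available


@dataclass
class SlopeResult:
    slopes: np.ndarray  # per participant, mm per scale step
    grand_average: float
    null: np.ndarray
    p: float
    r_squared: np.ndarray  # per participant


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _robust_local_linear(x: np.ndarray, y: np.ndarray, window: float, iters: int = 2) -> np.ndarray:
    """Iteratively reweighted local linear smoother (bisquare) evaluated
    at every x over a sliding window of total width ``window``."""
    out = np.empty_like(y, dtype=float)
    half = window / 2.0
    for i, x0 in enumerate(x):
        sel = np.abs(x - x0) <= half
        xs, ys = x[sel], y[sel]
        ok = np.isfinite(ys)
        xs, ys = xs[ok], ys[ok]
        if xs.size == 0:
            out[i] = np.nan
            continue
        if xs.size < 3 or np.ptp(xs) == 0:
            out[i] = np.nanmean(ys)
            continue
        w = np.ones_like(ys)
        X = np.column_stack([np.ones_like(xs), xs - x0])
        beta = None
        for _ in range(iters + 1):
            WX = X * w[:, None]
            beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ ys, rcond=None)
            resid = ys - X @ beta
            s = np.median(np.abs(resid)) * 1.4826
            if s < 1e-12:
                break
            u = np.clip(resid / (4.685 * s), -1, 1)
            w = (1 - u**2) ** 2
        out[i] = beta[0]
    return out


def weight_profile(
    wmap: WeightMap,
    *,
    window_height: float = 2.0,
    step: float = 1.0,
    smooth_window: float = 70.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Collapse a weight map into a smoothed 1-D profile.

    A window of the given height is shifted along the inferior-superior
    axis in the given steps; all weights falling into the window are
    averaged (collapsing the anterior-posterior axis), and the resulting
    profile is smoothed with a robust local linear fit over
    ``smooth_window`` mm.  Returns (positions, profile).  Empty windows
    are interpolated from their neighbours and flagged in the log.
    """
    if wmap.weights.size == 0:
        raise ValueError("empty weight map")
    y = wmap.coords[:, 1]
    lo, hi = y.min(), y.max()
    n_steps = int(np.floor((hi - lo - window_height) / step)) + 1
    positions = lo + window_height / 2.0 + step * np.arange(max(n_steps, 1))
    raw = np.full(positions.size, np.nan)
    for i, c in enumerate(positions):
        sel = np.abs(y - c) <= window_height / 2.0
        if sel.any():
            raw[i] = wmap.weights[sel].mean()
    if np.isnan(raw).any():
        logger.warning("%d empty profile windows interpolated", int(np.isnan(raw).sum()))
        ok = ~np.isnan(raw)
        raw = np.interp(positions, positions[ok], raw[ok])
    smooth = _robust_local_linear(positions, raw, smooth_window)
    return positions, smooth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def _local_maxima(profile: np.ndarray) -> np.ndarray:
    """Indices of samples strictly larger than both neighbours."""
    if profile.size < 3:
        return np.array([], dtype=int)
    inner = (profile[1:-1] > profile[:-2]) & (profile[1:-1] > profile[2:])
    return np.flatnonzero(inner) + 1


def find_peaks(
    profiles: Sequence[np.ndarray],
    positions: np.ndarray,
    mode: str = "unconstrained",
) -> PeakSet:
    """One peak coordinate per time scale from its 1-D weight profile.

    Unconstrained: the local maximum with the highest positive value.
    Constrained: scale 1 must peak in the inferior half of the occupied
    axis, scales 2..n strictly superior to scale 1's peak.  Whenever no
    admissible positive local maximum exists, the largest positive value
    (or, failing that, the overall largest value) in the admissible
    region is selected and flagged.
    """
    if mode not in ("unconstrained", "constrained"):
        raise ValueError(f"unknown mode {mode!r}")
    n_scales = len(profiles)
    coords = np.empty(n_scales)
    fallback = np.zeros(n_scales, dtype=bool)
    midpoint = (positions[0] + positions[-1]) / 2.0

    def pick(profile: np.ndarray, allowed: np.ndarray) -> Tuple[float, bool]:
        cand = _local_maxima(profile)
        cand = cand[allowed[cand] & (profile[cand] > 0)]
        if cand.size:
            return positions[cand[np.argmax(profile[cand])]], False
        idx_allowed = np.flatnonzero(allowed)
        if idx_allowed.size == 0:
            idx_allowed = np.arange(profile.size)
        best = idx_allowed[np.argmax(profile[idx_allowed])]
        return positions[best], True

    for s in range(n_scales):
        profile = np.asarray(profiles[s], dtype=float)
        if mode == "constrained":
            if s == 0:
                allowed = positions <= midpoint
            else:
                allowed = positions > coords[0]
        else:
            allowed = np.ones(positions.size, dtype=bool)
        coords[s], fallback[s] = pick(profile, allowed)
    return PeakSet(coordinates=coords, mode=mode, fallback=fallback)


# ---------------------------------------------------------------------------
# gradient fit
# ---------------------------------------------------------------------------


def _slope_r2(scales: np.ndarray, coords: np.ndarray) -> Tuple[float, float]:
    X = np.column_stack([np.ones_like(scales, dtype=float), scales])
    beta, *_ = np.linalg.lstsq(X, coords, rcond=None)
    pred = X @ beta
    ss_res = float(np.sum((coords - pred) ** 2))
    ss_tot = float(np.sum((coords - coords.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(beta[1]), r2


def fit_gradient(
    peaksets: Sequence[PeakSet],
    *,
    n_shuffle: int = 10000,
    seed: int = 0,
) -> SlopeResult:
    """Least-squares slope of peak coordinates across time scales, per
    participant, with a coordinate-shuffle permutation null.

    The grand-average slope is ranked (one-sided, positive gradient
    hypothesized) against slopes recomputed after shuffling each
    participant's coordinates across time scales.  In constrained mode
    the scale-1 coordinate is preset and therefore held fixed in the
    shuffle.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two participants")
    n_scales = len(peaksets[0].coordinates)
    scales = np.arange(1, n_scales + 1, dtype=float)
    coords = np.stack([ps.coordinates for ps in peaksets])  # (P, S)
    if not np.all(np.isfinite(coords)):
        keep = np.all(np.isfinite(coords), axis=1)
        logger.warning("excluding %d participants with missing peaks", int((~keep).sum()))
        coords = coords[keep]
    constrained = peaksets[0].mode == "constrained"

    fits = [_slope_r2(scales, c) for c in coords]
    slopes = np.array([f[0] for f in fits])
    r2 = np.array([f[1] for f in fits])
    grand = float(slopes.mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        acc = 0.0
        for c in coords:
            if constrained:
                perm = c.copy()
                perm[1:] = rng.permutation(c[1:])
            else:
                perm = rng.permutation(c)
            acc += _slope_r2(scales, perm)[0]
        null[i] = acc / coords.shape[0]
    p = float((1 + np.sum(null >= grand)) / (n_shuffle + 1))
    return SlopeResult(slopes=slopes, grand_average=grand, null=null, p=p, r_squared=r2)


def compare_slopes_between_models(
    slopes_a: np.ndarray,
    slopes_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permutation test (model labels swapped within participant) on the
    difference of mean slopes."""
    a, b = np.asarray(slopes_a, float), np.asarray(slopes_b, float)
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(a.size) < 0.5
        null[i] = np.where(swap, b, a).mean() - np.where(swap, a, b).mean()
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return float(obs), p


# ---------------------------------------------------------------------------
# cluster-based permutation tests on the sheet
# ---------------------------------------------------------------------------


def _grid_neighbors(coords: np.ndarray) -> List[np.ndarray]:
    """8-connectivity neighbour lists for vertices on a unit grid."""
    index: Dict[Tuple[int, int], int] = {
        (int(round(x)), int(round(y))): i for i, (x, y) in enumerate(coords)
    }
    neigh: List[np.ndarray] = []
    for x, y in coords:
        xi, yi = int(round(x)), int(round(y))
        ids = [
            index[(xi + dx, yi + dy)]
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx or dy) and (xi + dx, yi + dy) in index
        ]
        neigh.append(np.array(ids, dtype=int))
    return neigh


def _clusters_from_t(
    t: np.ndarray,
    sig: np.ndarray,
    neighbors: List[np.ndarray],
    min_neighbors: int = 2,
) -> List[Tuple[np.ndarray, float]]:
    """Connected components of significant vertices that have at least
    ``min_neighbors`` significant neighbours; returns (members, summed t)."""
    core = sig.copy()
    for i in np.flatnonzero(sig):
        if np.sum(sig[neighbors[i]]) < min_neighbors:
            core[i] = False
    clusters = []
    seen = np.zeros_like(core)
    for i in np.flatnonzero(core):
        if seen[i]:
            continue
        stack, members = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            members.append(j)
            for k in neighbors[j]:
                if core[k] and not seen[k]:
                    seen[k] = True
                    stack.append(k)
        members = np.array(members, dtype=int)
        clusters.append((members, float(t[members].sum())))
    return clusters


def cluster_permutation_map(
    maps: np.ndarray,
    scrambled_maps: np.ndarray,
    coords: np.ndarray,
    *,
    alpha_vertex: float = 0.05,
    min_neighbors: int = 2,
    alpha_cluster: float = 0.05,
) -> List[dict]:
    """Cluster-based permutation test of weight maps against zero.

    ``maps`` is (participants, vertices); ``scrambled_maps`` is
    (partitions, participants, vertices) built from scrambled features.
    Positive and negative clusters are formed separately from vertex-wise
    one-sample t tests; an observed cluster is significant when its
    summed t is exceeded by at most ``alpha_cluster / 2`` of the
    max-cluster null per sign.
    """
    if scrambled_maps.ndim != 3 or scrambled_maps.shape[0] < 1:
        raise ValueError("scrambled partitions required")
    neighbors = _grid_neighbors(coords)

    def tmap(m):
        t, p = stats.ttest_1samp(m, 0.0, axis=0)
        return np.nan_to_num(t), np.nan_to_num(p, nan=1.0)

    t_obs, p_obs = tmap(maps)
    out = []
    null_max = {1: [], -1: []}
    for b in range(scrambled_maps.shape[0]):
        t_b, p_b = tmap(scrambled_maps[b])
        for sign in (1, -1):
            sig = (p_b < alpha_vertex) & (np.sign(t_b) == sign)
            cl = _clusters_from_t(t_b, sig, neighbors, min_neighbors)
            null_max[sign].append(
                max((abs(s) for _, s in cl), default=0.0)
            )
    for sign in (1, -1):
        sig = (p_obs < alpha_vertex) & (np.sign(t_obs) == sign)
        for members, summed in _clusters_from_t(t_obs, sig, neighbors, min_neighbors):
            null = np.asarray(null_max[sign])
            p_cl = float((1 + np.sum(null >= abs(summed))) / (null.size + 1))
            out.append(
                {
                    "members": members,
                    "summed_t": summed,
                    "sign": sign,
                    "p": p_cl,
                    # exceeded by no more than alpha/2 of the null per sign
                    "significant": bool(np.mean(null >= abs(summed)) <= alpha_cluster / 2.0),
                }
            )
    return out


def compare_accuracy_maps(
    zmaps_a: np.ndarray,
    zmaps_b: np.ndarray,
    coords: np.ndarray,
    *,
    n_perm: int = 1000,
    alpha_vertex: float = 0.05,
    min_neighbors: int = 2,
    alpha_cluster: float = 0.05,
    seed: int = 0,
) -> List[dict]:
    """Cluster-based permutation paired-sample t test between two
    accuracy maps; the null shuffles model labels within participants
    (sign flips of the paired differences)."""
    A = np.asarray(zmaps_a, float)
    B = np.asarray(zmaps_b, float)
    if A.shape != B.shape:
        raise ValueError("mismatched geometry between accuracy maps")
    D = A - B
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, D.shape[0]))
    scrambled = flips[:, :, None] * D[None, :, :]
    return cluster_permutation_map(
        D,
        scrambled,
        coords,
        alpha_vertex=alpha_vertex,
        min_neighbors=min_neighbors,
        alpha_cluster=alpha_cluster,
    )


# ---------------------------------------------------------------------------
# rotation analysis
# ---------------------------------------------------------------------------


def rotation_analysis(
    maps: Sequence[Sequence[WeightMap]],
    *,
    step_deg: float = 5.0,
    n_shuffle: int = 1000,
    seed: int = 0,
    profile_kwargs: Optional[dict] = None,
) -> dict:
    """Slope statistic around the full circle of sheet rotations.

    ``maps`` is indexed [participant][scale].  For each rotation the sheet
    coordinates are rotated about their centroid, unconstrained profiles
    and peaks are recomputed along the post-rotation second axis, and the
    gradient slope statistic is evaluated with a reduced shuffle null.
    Contiguous significant rotations (circular adjacency) form clusters
    whose summed statistic is ranked against a max-cluster shuffle null.
    """
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 360.0, step_deg)
    pk = profile_kwargs or {}
    n_sub = len(maps)
    n_scales = len(maps[0])
    coords0 = maps[0][0].coords
    centroid = coords0.mean(axis=0)

    grand = np.empty(angles.size)
    zstat = np.empty(angles.size)
    null_slopes = np.empty((angles.size, n_shuffle))
    for ai, ang in enumerate(angles):
        th = np.deg2rad(ang)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rc = (coords0 - centroid) @ R.T + centroid
        peaksets = []
        for p in range(n_sub):
            profiles = []
            positions = None
            for s in range(n_scales):
                wm = WeightMap(weights=maps[p][s].weights, coords=rc)
                positions, prof = weight_profile(wm, **pk)
                profiles.append(prof)
            peaksets.append(find_peaks(profiles, positions, "unconstrained"))
        res = fit_gradient(peaksets, n_shuffle=n_shuffle, seed=int(rng.integers(2**31)))
        grand[ai] = res.grand_average
        null_slopes[ai] = res.null
        sd = res.null.std()
        zstat[ai] = (res.grand_average - res.null.mean()) / sd if sd > 0 else 0.0

    # cluster the per-rotation statistic in the (circular) rotation domain
    p_rot = (1 + np.sum(null_slopes >= grand[:, None], axis=1)) / (n_shuffle + 1)
    sig = p_rot < 0.05
    clusters = _circular_clusters(sig, zstat)
    null_max = np.empty(n_shuffle)
    for b in range(n_shuffle):
        stat_b = null_slopes[:, b]
        z_b = (stat_b - null_slopes.mean(axis=1)) / np.where(
            null_slopes.std(axis=1) > 0, null_slopes.std(axis=1), 1.0
        )
        p_b = (1 + np.sum(null_slopes >= stat_b[:, None], axis=1)) / (n_shuffle + 1)
        cl_b = _circular_clusters(p_b < 0.05, z_b)
        null_max[b] = max((abs(s) for _, s in cl_b), default=0.0)
    results = []
    for members, summed in clusters:
        p_cl = float((1 + np.sum(null_max >= abs(summed))) / (n_shuffle + 1))
        results.append({"rotations": angles[members], "summed_stat": summed, "p": p_cl})
    return {"angles": angles, "slope": grand, "z": zstat, "p": p_rot, "clusters": results}


def _circular_clusters(sig: np.ndarray, stat: np.ndarray) -> List[Tuple[np.ndarray, float]]:
    n = sig.size
    if not sig.any():
        return []
    if sig.all():
        return [(np.arange(n), float(stat.sum()))]
    clusters = []
    # start after a gap so wrap-around clusters are contiguous
    start = int(np.flatnonzero(~sig)[0])
    members: List[int] = []
    for k in range(1, n + 1):
        i = (start + k) % n
        if sig[i]:
            members.append(i)
        elif members:
            idx = np.array(members, dtype=int)
            clusters.append((idx, float(stat[idx].sum())))
            members = []
    if members:
        idx = np.array(members, dtype=int)
        clusters.append((idx, float(stat[idx].sum())))
    return clusters
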