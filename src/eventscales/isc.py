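"""Intersubject correlation, bootstrap inference and ROI selection.

Vertex-wise time courses (concatenated across runs) are correlated
between every pair of participants; the group map is the median over
pairs.  Significance comes from a participant-resampling bootstrap that
excludes self-pairs, with Benjamini-Hochberg FDR adjustment, and parcels
enter the region of interest when at least 80% of their vertices are
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["ISCResult", "pairwise_isc", "bootstrap_test", "select_roi"]


@dataclass
class ISCResult:
    pair_maps: np.ndarray  # (n_pairs, n_vertices)
    pairs: List[Tuple[int, int]]
    group_map: np.ndarray  # median over pairs per vertex
    p: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    roi_mask: Optional[np.ndarray] = None


def _concat(participant) -> np.ndarray:
    if hasattr(participant, "concatenated"):
        return participant.concatenated()
    return np.asarray(participant)


def pairwise_isc(participants: Sequence) -> ISCResult:
    """Vertex-wise Pearson correlation for every unordered participant
    pair, and the median group map.

    Zero-variance vertex series make the correlation undefined; those
    entries are set to NaN and excluded from the median.
    """
    data = [_concat(p) for p in participants]
    if len(data) < 2:
        raise ValueError("need at least two participants")
    shape = data[0].shape
    if any(d.shape != shape for d in data):
        raise ValueError("participants must share vertex geometry and run lengths")
    Z = []
    for d in data:
        c = d - d.mean(axis=1, keepdims=True)
        sd = c.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = c / sd[:, None]
        c[sd == 0] = np.nan
        Z.append(c / np.sqrt(d.shape[1]))
    pairs = [(i, j) for i in range(len(data)) for j in range(i + 1, len(data))]
    maps = np.empty((len(pairs), shape[0]))
    for k, (i, j) in enumerate(pairs):
        maps[k] = np.sum(Z[i] * Z[j], axis=1)
    group = np.nanmedian(maps, axis=0)
    return ISCResult(pair_maps=maps, pairs=pairs, group_map=group)


def bootstrap_test(
    result: ISCResult,
    n: int = 10000,
    seed: int = 0,
    fdr_alpha: float = 0.01,
) -> ISCResult:
    """Bootstrap hypothesis test on the median intersubject correlation.

    Participants are resampled with replacement; the median group map of
    each bootstrap sample excludes pairs of a participant with herself.
    The observed median is ranked against the z-normalized null per
    vertex, and p-values are Benjamini-Hochberg adjusted.
    """
    if n < 100:
        logger.warning("bootstrap with n=%d iterations is unreliable", n)
    rng = np.random.default_rng(seed)
    n_sub = int(max(max(p) for p in result.pairs)) + 1
    pair_index: Dict[Tuple[int, int], int] = {p: k for k, p in enumerate(result.pairs)}
    null = np.empty((n, result.pair_maps.shape[1]))
    for b in range(n):
        sample = rng.integers(0, n_sub, n_sub)
        rows = []
        for ii in range(n_sub):
            for jj in range(ii + 1, n_sub):
                a, c = sample[ii], sample[jj]
                if a == c:
                    continue  # self-pair excluded
                rows.append(pair_index[(min(a, c), max(a, c))])
        null[b] = (
            np.nanmedian(result.pair_maps[rows], axis=0)
            if rows
            else np.zeros(result.pair_maps.shape[1])
        )
    mu = null.mean(axis=0)
    sd = null.std(axis=0)
    sd[sd < 1e-12] = 1e-12
    # Hall-Wilson style: shift the bootstrap distribution to the null
    # hypothesis (median 0), normalize, and rank the observed median on
    # that scale
    null_z = (null - mu) / sd
    obs_z = result.group_map / sd
    p = (1 + np.sum(null_z >= obs_z[None, :], axis=0)) / (n + 1)
    rej, q, *_ = multipletests(p, alpha=fdr_alpha, method="fdr_bh")
    result.p = p
    result.q = q
    return result


def select_roi(
    q: np.ndarray,
    parcel: np.ndarray,
    *,
    threshold: float = 0.80,
    q_alpha: float = 0.01,
    eligible_parcels: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Parcels with at least ``threshold`` of vertices significant.

    ``eligible_parcels`` restricts candidacy (the stand-in for the
    temporal/parietal parcel families); the returned boolean mask flags
    every vertex of every selected parcel.
    """
    parcel = np.asarray(parcel)
    mask = np.zeros(parcel.shape[0], dtype=bool)
    labels = np.unique(parcel)
    for lab in labels:
        if eligible_parcels is not None and lab not in eligible_parcels:
            continue
        members = parcel == lab
        if members.sum() == 0:
            logger.warning("empty parcel %s excluded", lab)
            continue
        frac = np.mean(q[members] < q_alpha)
        if frac >= threshold:
            mask[members] = True
    return mask
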