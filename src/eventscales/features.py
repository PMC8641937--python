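"""Word-level predictiveness metrics from full and layer-masked models.

Three metrics are derived from a model's next-word distribution:
surprisal (negative log probability of the actual next word), entropy of
the distribution (ascribed to the preceding word, since everything needed
to compute it is available before the word arrives), and the embedding
dissimilarity of the predicted and the actual word.  Each is computed
once from the full model and once per layer-masked model, giving 18
feature columns per language model.  The module also provides the
contextual-incongruence control and the temporal-integration-window
analysis based on context scrambling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lm import SequenceModel

logger = logging.getLogger(__name__)

__all__ = [
    "surprisal",
    "entropy",
    "dissimilarity",
    "feature_table",
    "contextual_incongruence",
    "IntegrationWindowResult",
    "integration_windows",
    "compare_second_level_slopes",
]

PROB_FLOOR = 1e-10


def surprisal(d: np.ndarray, actual: int, base: str = "e") -> float:
    """Negative log probability assigned to the actual next word.

    Zero probabilities are clipped at a floor of 1e-10 and flagged in the
    log.  ``base`` may be "e" (natural log, default) or "2".
    """
    p = float(d[actual])
    if p <= 0:
        logger.warning("zero probability for token %d clipped at %.0e", actual, PROB_FLOOR)
        p = PROB_FLOOR
    s = -np.log(p)
    return float(s / np.log(2.0)) if base == "2" else float(s)


def entropy(d: np.ndarray) -> float:
    """Shannon entropy -sum p ln p with 0 ln 0 := 0 (natural log)."""
    d = np.asarray(d, dtype=float)
    nz = d > 0
    return float(-(d[nz] * np.log(d[nz])).sum())


def dissimilarity(predicted: int, actual: int, embeddings: np.ndarray) -> float:
    """1 minus the Pearson correlation of the two word embeddings.

    A zero-variance embedding makes the correlation undefined; the value
    is set to 1 and flagged.
    """
    a = embeddings[predicted].astype(float)
    b = embeddings[actual].astype(float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("zero-variance embedding in dissimilarity; value set to 1")
        return 1.0
    return float(1.0 - (a @ b) / (na * nb))


# ---------------------------------------------------------------------------
# story scoring
# ---------------------------------------------------------------------------


def _window_distributions(
    model: SequenceModel,
    tokens: np.ndarray,
    positions: np.ndarray,
    masks: Dict[str, np.ndarray],
    context_len: int,
    batch_size: int = 64,
) -> Dict[str, np.ndarray]:
    """Next-word distributions at given story positions for several masks.

    For each target position p the preceding ``min(p, context_len)`` words
    are fed through the recurrent stack once; every mask then reads the
    final hidden states out through its own readout combination, so the
    stack cost is shared across masks.  Returns, per mask name, an array
    of shape (len(positions), vocab).
    """
    v = model.config.vocab_size
    out = {name: np.empty((len(positions), v)) for name in masks}
    order = np.argsort([min(p, context_len) for p in positions])
    k = 0
    while k < len(order):
        # group positions with equal effective context length into a batch
        batch_idx = [order[k]]
        clen = min(positions[order[k]], context_len)
        while (
            len(batch_idx) < batch_size
            and k + len(batch_idx) < len(order)
            and min(positions[order[k + len(batch_idx)]], context_len) == clen
        ):
            batch_idx.append(order[k + len(batch_idx)])
        k += len(batch_idx)
        windows = np.stack([tokens[positions[i] - clen : positions[i]] for i in batch_idx])
        cache = model._run_stack(windows)
        h_last = cache["h"][:, -1]  # (L, B, u)
        for name, mask in masks.items():
            probs = model._readout(h_last[:, None], np.asarray(mask, bool))  # (B,1,V)
            out[name][batch_idx] = probs[:, 0]
    return out


def feature_table(
    model: SequenceModel,
    tokens: Sequence[int],
    embeddings: Optional[np.ndarray] = None,
    *,
    context_len: Optional[int] = None,
    batch_size: int = 64,
) -> pd.DataFrame:
    """Per-word surprisal, entropy and dissimilarity from the full model
    and from every single-layer masked model.

    Word 0 has no context and carries no values (NaN); the entropy of the
    distribution predicting word p is stored at word p - 1.  Column names
    follow ``{metric}_{full|s1..sL}``.
    """
    tokens = np.asarray(tokens, dtype=int)
    ctx = context_len or model.config.context_len
    emb = embeddings if embeddings is not None else model.embeddings
    L = model.config.n_layers
    masks = {"full": np.ones(L, bool)}
    for l in range(L):
        m = np.zeros(L, bool)
        m[l] = True
        masks[f"s{l + 1}"] = m
    positions = np.arange(1, len(tokens))
    dists = _window_distributions(model, tokens, positions, masks, ctx, batch_size)

    n = len(tokens)
    df = pd.DataFrame(index=pd.RangeIndex(n, name="word_index"))
    for name, D in dists.items():
        surp = np.full(n, np.nan)
        ent = np.full(n, np.nan)
        diss = np.full(n, np.nan)
        p_actual = D[np.arange(len(positions)), tokens[positions]]
        clipped = p_actual <= 0
        if clipped.any():
            logger.warning("%d zero probabilities clipped", int(clipped.sum()))
        surp[positions] = -np.log(np.maximum(p_actual, PROB_FLOOR))
        ent_vals = -np.sum(np.where(D > 0, D * np.log(np.where(D > 0, D, 1.0)), 0.0), axis=1)
        ent[positions - 1] = ent_vals  # ascribed to the previous word
        pred = D.argmax(axis=1)
        diss[positions] = [
            dissimilarity(int(pr), int(ac), emb)
            for pr, ac in zip(pred, tokens[positions])
        ]
        df[f"surprisal_{name}"] = surp
        df[f"entropy_{name}"] = ent
        df[f"dissimilarity_{name}"] = diss
    return df


# ---------------------------------------------------------------------------
# contextual incongruence
# ---------------------------------------------------------------------------


def contextual_incongruence(
    tokens: Sequence[int],
    embeddings: np.ndarray,
    windows: Sequence[int] = (2, 4, 8, 16, 32),
    *,
    content_flags: Optional[np.ndarray] = None,
    function_words_only: bool = False,
) -> pd.DataFrame:
    """1 minus the correlation of a word's embedding with the mean
    embedding of its preceding context window, per window length.

    Windows truncate at the text start.  By default every word is scored;
    ``function_words_only`` restricts the computation to words flagged -1
    in ``content_flags`` (others NaN).
    """
    tokens = np.asarray(tokens, dtype=int)
    if any(w < 1 for w in windows):
        raise ValueError("window lengths must be positive")
    E = embeddings[tokens]  # (w, dim)
    n = len(tokens)
    out = pd.DataFrame(index=pd.RangeIndex(n, name="word_index"))
    csum = np.vstack([np.zeros(E.shape[1]), np.cumsum(E, axis=0)])
    for w in windows:
        vals = np.full(n, np.nan)
        for p in range(1, n):
            lo = max(0, p - w)
            mean_ctx = (csum[p] - csum[lo]) / (p - lo)
            a = E[p] - E[p].mean()
            b = mean_ctx - mean_ctx.mean()
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            vals[p] = 1.0 if na == 0 or nb == 0 else 1.0 - (a @ b) / (na * nb)
        if function_words_only:
            if content_flags is None:
                raise ValueError("content_flags required for function_words_only")
            vals[np.asarray(content_flags) != -1] = np.nan
        out[f"incongruence_w{w}"] = vals
    return out


# ---------------------------------------------------------------------------
# temporal integration windows
# ---------------------------------------------------------------------------


@dataclass
class IntegrationWindowResult:
    granularities: np.ndarray
    mean_surprisal: np.ndarray  # (layers, granularities)
    layer_slopes: np.ndarray  # first-level slope per layer (vs log2 granularity)
    second_level_slope: float  # slope of layer slopes across layers
    null_slopes: np.ndarray  # layer-shuffle null of the second-level slope
    p: float


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def integration_windows(
    model: SequenceModel,
    tokens: Sequence[int],
    granularities: Sequence[int] = (1, 2, 4, 8, 16, 32, 64, 128, 256),
    *,
    n_shuffle: int = 10000,
    seed: int = 0,
    positions: Optional[np.ndarray] = None,
    context_len: Optional[int] = None,
    batch_size: int = 64,
) -> IntegrationWindowResult:
    """Context benefit of each layer, probed by input scrambling.

    For each granularity g, the context beyond the most recent g words is
    word-scrambled (seeded uniform permutation) before scoring, so only g
    words of intact context remain.  Per layer, a linear function is fit
    to mean masked surprisal across log2 granularity; the first-level
    slope measures how much that layer benefits from longer intact
    context.  A second-level slope across layers tests whether deeper
    layers benefit more; its null distribution is built by shuffling the
    first-level slopes across layers.
    """
    granularities = np.asarray(granularities, dtype=int)
    if granularities.size < 2:
        raise ValueError("need at least two granularities")
    if np.any(np.diff(granularities) <= 0):
        raise ValueError("granularities must be strictly increasing")
    tokens = np.asarray(tokens, dtype=int)
    ctx = context_len or model.config.context_len
    L = model.config.n_layers
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = np.arange(ctx, len(tokens))
    positions = np.asarray(positions)

    masks = {}
    for l in range(L):
        m = np.zeros(L, bool)
        m[l] = True
        masks[f"s{l + 1}"] = m

    mean_surp = np.empty((L, granularities.size))
    for gi, g in enumerate(granularities):
        # scramble context beyond the last g words, per evaluation position
        surps = np.zeros((L, len(positions)))
        for bi in range(0, len(positions), batch_size):
            chunk = positions[bi : bi + batch_size]
            windows = []
            for p in chunk:
                lo = max(0, p - ctx)
                win = tokens[lo:p].copy()
                if len(win) > g:
                    head = win[: len(win) - g]
                    rng.shuffle(head)
                    win[: len(win) - g] = head
                windows.append(win)
            wlen = min(len(w) for w in windows)
            windows = np.stack([w[-wlen:] for w in windows])
            cache = model._run_stack(windows)
            h_last = cache["h"][:, -1]
            for l, (name, mask) in enumerate(masks.items()):
                probs = model._readout(h_last[:, None], np.asarray(mask, bool))[:, 0]
                pa = probs[np.arange(len(chunk)), tokens[chunk]]
                surps[l, bi : bi + len(chunk)] = -np.log(np.maximum(pa, PROB_FLOOR))
        mean_surp[:, gi] = surps.mean(axis=1)

    logg = np.log2(granularities).astype(float)
    layer_slopes = np.array([_ols_slope(logg, mean_surp[l]) for l in range(L)])
    layers = np.arange(1, L + 1, dtype=float)
    obs = _ols_slope(layers, layer_slopes)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        null[i] = _ols_slope(layers, rng.permutation(layer_slopes))
    # one-sided: do deeper layers benefit more (more negative slopes)?
    p = float((1 + np.sum(null <= obs)) / (n_shuffle + 1))
    return IntegrationWindowResult(
        granularities=granularities,
        mean_surprisal=mean_surp,
        layer_slopes=layer_slopes,
        second_level_slope=obs,
        null_slopes=null,
        p=p,
    )


def compare_second_level_slopes(
    slopes_a: np.ndarray,
    slopes_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Monte Carlo permutation test on the difference of mean first-level
    slopes between two models (labels swapped per layer)."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("slope vectors must have equal length")
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(a.size) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        null[i] = aa.mean() - bb.mean()
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return float(obs), p
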