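"""Seeded generators for corpora, brain-activity cohorts and reading logs.

Every downstream stage of the package (language modelling, encoding,
gradient fitting, connectivity, reading regression) can be exercised on
data from this module, with the planted structure returned as ground
truth:

* :func:`generate_corpus` draws token sequences from a nested hierarchy of
  latent topic states, so that context carries information at several
  event time scales and longer intact context genuinely lowers surprisal
  at the deeper scales;
* :func:`generate_cohort` paints a time-scale map onto a flattened
  cortical sheet and synthesises vertex-wise activity as HRF-convolved
  surprisal plus shared stimulus-locked signal and noise, including
  surprisal-gated coupling between time-scale seeds;
* :func:`generate_reading_logs` produces self-paced-reading times with a
  planted spill-over profile of surprisal across word lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import hrf_convolve

__all__ = [
    "SyntheticCorpus",
    "GroundTruth",
    "SheetSeries",
    "SyntheticCohort",
    "generate_corpus",
    "default_ground_truth",
    "generate_cohort",
    "generate_reading_logs",
    "synthetic_feature_table",
]

TR_DEFAULT = 0.947  # BOLD sampling interval, seconds
RUN_LENGTH_DEFAULT = 519  # samples per functional run
SHEET_SHAPE = (40, 60)  # (anterior-posterior, inferior-superior) mm grid


@dataclass
class SyntheticCorpus:
    """Token sequence with nested event boundaries and word annotations."""

    tokens: np.ndarray  # (w,) int
    boundaries: List[np.ndarray]  # per level, binary (w,); level L = coarsest
    embeddings: np.ndarray  # (vocab, dim)
    annotations: pd.DataFrame  # onset_s, content, zipf, length per token

    def __post_init__(self) -> None:
        w = len(self.tokens)
        for b in self.boundaries:
            if len(b) != w:
                raise ValueError("boundary sequence length mismatch")
        for coarse, fine in zip(self.boundaries[1:], self.boundaries[:-1]):
            if np.any(coarse & ~fine):
                raise ValueError("boundary levels are not nested")
        on = self.annotations["onset_s"].to_numpy()
        if np.any(np.diff(on) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def vocab_size(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class GroundTruth:
    """What was planted into a synthetic cohort."""

    vertex_scale: np.ndarray  # (n_vertices,) 0 = unassigned, 1..5 = scale
    true_gradient_slope: float  # mm of inferior-superior shift per scale step
    seed_coupling: List[Tuple[int, int, float]] = field(default_factory=list)
    spillover_weights: Optional[np.ndarray] = None  # lags -2..5

    def __post_init__(self) -> None:
        scales = set(np.unique(self.vertex_scale)) - {0}
        if scales and scales != set(range(1, max(scales) + 1)):
            raise ValueError("vertex_scale must cover each scale at least once")
        for _, _, a in self.seed_coupling:
            if not np.isfinite(a):
                raise ValueError("coupling amplitude must be finite")


@dataclass
class SheetSeries:
    """Per-run vertex-by-time activity on a flattened 2-D sheet."""

    runs: List[np.ndarray]  # each (n_vertices, n_samples)
    coords: np.ndarray  # (n_vertices, 2) mm, columns (anterior-posterior, inferior-superior)
    parcel: np.ndarray  # (n_vertices,) int labels

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.runs, axis=1)


@dataclass
class SyntheticCohort:
    participants: List[SheetSeries]
    word_onsets: List[np.ndarray]  # per run, onsets in run time (s)
    word_runs: np.ndarray  # (w,) run index per word
    truth: GroundTruth
    tr: float = TR_DEFAULT
    run_length: int = RUN_LENGTH_DEFAULT
    reading_logs: Optional[pd.DataFrame] = None

    @property
    def n_runs(self) -> int:
        return len(self.word_onsets)


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------


def generate_corpus(
    vocab_size: int,
    n_levels: int,
    mean_event_lengths: Sequence[float],
    length: int,
    seed: int,
    *,
    n_topics: int = 6,
    topic_concentration: float = 0.25,
    emission: str = "sequences",
    lexicon_size: int = 12,
    word_interval: float = 0.40,
    tr: float = TR_DEFAULT,
) -> SyntheticCorpus:
    """Sample a token sequence from a nested hierarchy of latent topics.

    Level ``k`` (1-based; level ``n_levels`` is the coarsest) carries a
    latent topic state that is resampled at that level's event boundaries,
    and boundary sequences are nested by construction (a coarse boundary
    is also a boundary at every finer level).

    Two emission regimes are available.  ``"sequences"`` (default) treats
    level-1 events as fixed token sequences ("words" from a small
    lexicon); which word comes next is drawn from the active level-2
    topic, which is itself resampled from the active coarser topics at
    level-2 boundaries, and so on up the hierarchy.  Within an event the
    next token is predictable from short context, while across boundaries
    prediction requires the coarse topic inferred from long context — the
    regime a sparsely updating hierarchy is designed for.  ``"mixture"``
    emits every token independently from the topic-specific categorical
    distribution of one uniformly chosen level.  In both regimes longer
    intact context lowers surprisal at the deeper levels.
    """
    if vocab_size < 8:
        raise ValueError("vocab_size must be at least 8")
    if len(mean_event_lengths) != n_levels:
        raise ValueError("need one mean event length per level")
    mel = np.asarray(mean_event_lengths, dtype=float)
    if np.any(np.diff(mel) <= 0):
        raise ValueError("mean_event_lengths must be strictly increasing across levels")
    if emission not in ("sequences", "mixture"):
        raise ValueError(f"unknown emission regime {emission!r}")
    rng = np.random.default_rng(seed)

    boundaries = [np.zeros(length, dtype=bool) for _ in range(n_levels)]
    tokens = np.empty(length, dtype=int)

    if emission == "mixture":
        # nested Bernoulli boundaries, coarse to fine
        for k in range(n_levels - 1, -1, -1):
            draw = rng.random(length) < 1.0 / mel[k]
            b = draw.copy()
            if k < n_levels - 1:
                b |= boundaries[k + 1]
            boundaries[k] = b
        emit = [
            rng.dirichlet(np.full(vocab_size, topic_concentration), size=n_topics)
            for _ in range(n_levels)
        ]
        states = rng.integers(0, n_topics, n_levels)
        for t in range(length):
            for k in range(n_levels):
                if t > 0 and boundaries[k][t - 1]:
                    states[k] = rng.integers(0, n_topics)
            lvl = rng.integers(0, n_levels)
            tokens[t] = rng.choice(vocab_size, p=emit[lvl][states[lvl]])
    else:
        # lexicon of level-1 event sequences with mean length ~ mel[0]
        lex: List[np.ndarray] = [
            rng.integers(0, vocab_size, max(2, 1 + rng.geometric(1.0 / max(mel[0] - 1, 1.0))))
            for _ in range(lexicon_size)
        ]
        # level-2 topics are sparse distributions over lexicon entries;
        # every deeper level's topics are distributions over the topics of
        # the level below
        topic_over_word = rng.dirichlet(
            np.full(lexicon_size, topic_concentration), size=n_topics
        )
        topic_over_topic = {
            k: rng.dirichlet(np.full(n_topics, topic_concentration), size=n_topics)
            for k in range(2, n_levels)  # level k+1 -> level k
        }
        # children per parent event reproduce the requested mean lengths
        ratio = {k: mel[k - 1] / mel[k - 2] for k in range(2, n_levels + 1)}

        state = {k: 0 for k in range(2, n_levels + 1)}
        count = {k: 0 for k in range(2, n_levels + 1)}

        def resample_from(level: int) -> None:
            # resample topics/counters for `level` and everything below it
            for k in range(level, 1, -1):
                if k == n_levels:
                    state[k] = int(rng.integers(0, n_topics))
                else:
                    state[k] = int(rng.choice(n_topics, p=topic_over_topic[k][state[k + 1]]))
                count[k] = max(1, int(rng.geometric(1.0 / ratio[k])))

        if n_levels >= 2:
            resample_from(n_levels)
        t = 0
        while t < length:
            if n_levels >= 2:
                word = lex[int(rng.choice(lexicon_size, p=topic_over_word[state[2]]))]
            else:
                word = lex[int(rng.integers(0, lexicon_size))]
            end = min(t + len(word), length)
            tokens[t:end] = word[: end - t]
            boundaries[0][end - 1] = True
            exhausted = 0
            for k in range(2, n_levels + 1):
                count[k] -= 1
                if count[k] <= 0:
                    boundaries[k - 1][end - 1] = True
                    exhausted = k
                else:
                    break
            if exhausted:
                resample_from(exhausted)
            t = end
        # nesting: a coarse boundary is a boundary at every finer level
        for k in range(n_levels - 1, 0, -1):
            boundaries[k - 1] |= boundaries[k]

    embeddings = rng.normal(0.0, 1.0, (vocab_size, 16))
    onsets = np.cumsum(word_interval * (0.7 + 0.6 * rng.random(length)))
    counts = np.bincount(tokens, minlength=vocab_size).astype(float)
    # Zipf-like standardized frequency value per word type, range roughly 1..7
    zipf = 1.0 + 6.0 * (np.log1p(counts) / np.log1p(counts.max()))
    ann = pd.DataFrame(
        {
            "onset_s": onsets,
            "content": rng.choice([-1, 1], length),
            "zipf": zipf[tokens],
            "length": rng.poisson(4.0, length) + 1,
        }
    )
    return SyntheticCorpus(
        tokens=tokens,
        boundaries=[b.astype(int) for b in boundaries],
        embeddings=embeddings,
        annotations=ann,
    )


# ---------------------------------------------------------------------------
# planted feature table (LM-free stand-in for encoding/reading tests)
# ---------------------------------------------------------------------------


def synthetic_feature_table(n_words: int, seed: int, n_scales: int = 5) -> pd.DataFrame:
    """Plausible per-word predictiveness values without a language model.

    Surprisal columns at the five time scales are mutually weakly
    correlated lognormal-ish series; entropy and dissimilarity are filled
    with matching ranges.  Used to exercise the encoding, gradient,
    connectivity and reading machinery with a known signal.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, n_words)
    cols: Dict[str, np.ndarray] = {}
    for s in range(1, n_scales + 1):
        x = 0.3 * base + rng.normal(0, 1, n_words)
        cols[f"surprisal_s{s}"] = np.log1p(np.exp(x)) * 2.0
    cols["surprisal_full"] = np.log1p(np.exp(0.5 * base + rng.normal(0, 1, n_words))) * 2.0
    for name in list(cols):
        metric_base = cols[name]
        s = name.split("_")[1]
        cols[f"entropy_{s}"] = np.abs(0.5 * metric_base + rng.normal(0, 0.5, n_words))
        cols[f"dissimilarity_{s}"] = np.clip(
            1.0 + 0.2 * rng.normal(0, 1, n_words), 0.0, 2.0
        )
    df = pd.DataFrame(cols)
    df.index.name = "word_index"
    return df


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def default_ground_truth(
    slope_mm: float = 10.0,
    *,
    sheet_shape: Tuple[int, int] = SHEET_SHAPE,
    n_scales: int = 5,
    blob_radius: float = 3.0,
    ap_center: Optional[float] = None,
    is_origin: float = 5.0,
    seed_coupling: Optional[List[Tuple[int, int, float]]] = None,
    spillover_weights: Optional[Sequence[float]] = None,
) -> GroundTruth:
    """A time-scale map with scale ``s`` centred ``slope_mm`` superior to
    scale ``s - 1`` along the inferior-superior axis."""
    ap, isax = np.meshgrid(
        np.arange(sheet_shape[0], dtype=float),
        np.arange(sheet_shape[1], dtype=float),
        indexing="ij",
    )
    coords = np.column_stack([ap.ravel(), isax.ravel()])
    vertex_scale = np.zeros(coords.shape[0], dtype=int)
    apc = ap_center if ap_center is not None else sheet_shape[0] / 2.0
    for s in range(1, n_scales + 1):
        center = np.array([apc, is_origin + slope_mm * (s - 1)])
        d = np.linalg.norm(coords - center, axis=1)
        vertex_scale[d <= blob_radius] = s
    return GroundTruth(
        vertex_scale=vertex_scale,
        true_gradient_slope=slope_mm,
        seed_coupling=list(seed_coupling or []),
        spillover_weights=None
        if spillover_weights is None
        else np.asarray(spillover_weights, dtype=float),
    )


def sheet_coords(sheet_shape: Tuple[int, int] = SHEET_SHAPE) -> np.ndarray:
    ap, isax = np.meshgrid(
        np.arange(sheet_shape[0], dtype=float),
        np.arange(sheet_shape[1], dtype=float),
        indexing="ij",
    )
    return np.column_stack([ap.ravel(), isax.ravel()])


def sheet_parcels(
    sheet_shape: Tuple[int, int] = SHEET_SHAPE, n_parcels: int = 6
) -> np.ndarray:
    """Parcel labels 1..n as bands along the inferior-superior axis."""
    coords = sheet_coords(sheet_shape)
    edges = np.linspace(0, sheet_shape[1], n_parcels + 1)
    return np.clip(np.digitize(coords[:, 1], edges[1:-1]) + 1, 1, n_parcels)


def _split_words_into_runs(
    onsets: np.ndarray, n_runs: int, run_duration: float
) -> Tuple[List[np.ndarray], np.ndarray]:
    words_per_run = len(onsets) // n_runs
    run_onsets: List[np.ndarray] = []
    word_runs = np.empty(len(onsets), dtype=int)
    for r in range(n_runs):
        lo = r * words_per_run
        hi = (r + 1) * words_per_run if r < n_runs - 1 else len(onsets)
        seg = onsets[lo:hi] - onsets[lo] + 2.0  # 2 s lead-in
        # squeeze into the run if the raw pacing overruns it
        if seg[-1] > run_duration - 8.0:
            seg = seg * (run_duration - 8.0) / seg[-1]
        run_onsets.append(seg)
        word_runs[lo:hi] = r
    return run_onsets, word_runs


def generate_cohort(
    corpus: SyntheticCorpus,
    features: pd.DataFrame,
    truth: GroundTruth,
    n_participants: int,
    n_runs: int,
    noise_sd: float,
    seed: int,
    *,
    gain: float = 1.0,
    shared_gain: float = 0.5,
    sheet_shape: Tuple[int, int] = SHEET_SHAPE,
    tr: float = TR_DEFAULT,
    run_length: int = RUN_LENGTH_DEFAULT,
) -> SyntheticCohort:
    """Synthesise a cohort of sheet time series with planted structure.

    Vertex activity is ``gain`` times the HRF-convolved surprisal
    regressor of the vertex's assigned time scale, plus a stimulus-locked
    component shared by all participants (drives intersubject correlation),
    plus independent Gaussian noise.  For every planted coupling
    ``(source, target, amplitude)`` the target blob additionally receives
    ``amplitude * z(source activity) * z(source-scale surprisal)``,
    realising a psychophysiological interaction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    coords = sheet_coords(sheet_shape)
    if len(truth.vertex_scale) != coords.shape[0]:
        raise ValueError("vertex_scale length does not match sheet geometry")
    if len(features) < len(corpus.tokens):
        raise ValueError("features must cover every token")
    parcel = sheet_parcels(sheet_shape)
    rng = np.random.default_rng(seed)

    onsets = corpus.annotations["onset_s"].to_numpy()
    run_onsets, word_runs = _split_words_into_runs(onsets, n_runs, run_length * tr)

    n_scales = int(truth.vertex_scale.max())
    scale_cols = [f"surprisal_s{s}" for s in range(1, n_scales + 1)]
    # per-run, per-scale convolved + z-scored regressors
    regs = np.zeros((n_runs, n_scales, run_length))
    for r in range(n_runs):
        w = word_runs == r
        for si, col in enumerate(scale_cols):
            x = hrf_convolve(
                list(zip(run_onsets[r], features.loc[w, col].to_numpy())),
                run_length,
                tr,
            )
            sd = x.std()
            regs[r, si] = (x - x.mean()) / sd if sd > 0 else 0.0

    # stimulus-locked shared component: smooth noise common to all participants
    shared = rng.normal(0, 1, (n_runs, run_length))
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    kernel /= kernel.sum()
    for r in range(n_runs):
        s = np.convolve(shared[r], kernel, mode="same")
        shared[r] = (s - s.mean()) / s.std()

    sig_parcels = np.unique(parcel[truth.vertex_scale > 0])
    in_sig_parcel = np.isin(parcel, sig_parcels)
    blobs = [np.flatnonzero(truth.vertex_scale == s) for s in range(1, n_scales + 1)]

    participants: List[SheetSeries] = []
    for p in range(n_participants):
        prng = np.random.default_rng(rng.integers(0, 2**31))
        runs: List[np.ndarray] = []
        for r in range(n_runs):
            act = np.zeros((coords.shape[0], run_length))
            act[in_sig_parcel] += shared_gain * shared[r]
            for s in range(1, n_scales + 1):
                act[truth.vertex_scale == s] += gain * regs[r, s - 1]
            for src, tgt, amp in truth.seed_coupling:
                src_act = act[blobs[src - 1]].mean(axis=0)
                sd = src_act.std()
                z_src = (src_act - src_act.mean()) / sd if sd > 0 else src_act
                ppi = z_src * regs[r, src - 1]
                sd = ppi.std()
                if sd > 0:
                    ppi = (ppi - ppi.mean()) / sd
                act[blobs[tgt - 1]] += amp * ppi
            act += prng.normal(0, noise_sd, act.shape)
            runs.append(act)
        participants.append(SheetSeries(runs=runs, coords=coords, parcel=parcel))

    cohort = SyntheticCohort(
        participants=participants,
        word_onsets=run_onsets,
        word_runs=word_runs,
        truth=truth,
        tr=tr,
        run_length=run_length,
    )
    if truth.spillover_weights is not None:
        cohort.reading_logs = generate_reading_logs(
            features, truth, n_participants, noise_sd=0.1, seed=seed + 1,
            annotations=corpus.annotations, word_runs=word_runs,
        )
    return cohort


# ---------------------------------------------------------------------------
# reading logs
# ---------------------------------------------------------------------------

SPILLOVER_LAGS = np.arange(-2, 6)  # word-position lags -2..5


def generate_reading_logs(
    features: pd.DataFrame,
    truth: GroundTruth,
    n_participants: int,
    noise_sd: float,
    seed: int,
    *,
    annotations: Optional[pd.DataFrame] = None,
    word_runs: Optional[np.ndarray] = None,
    n_runs: int = 4,
    baseline_s: float = 0.22,
    length_effect: float = 0.05,
    freq_effect: float = -0.04,
) -> pd.DataFrame:
    """Self-paced-reading logs with a planted spill-over profile.

    Log reading time is a baseline plus the lagged surprisal effects given
    by ``truth.spillover_weights`` (lags -2..5), plus word-length and
    word-frequency effects, plus log-normal noise; reading times are
    clipped to (0, 6] seconds.
    """
    w = truth.spillover_weights
    if w is None or len(w) != len(SPILLOVER_LAGS):
        raise ValueError("spillover_weights must be defined for lags -2..5")
    n_words = len(features)
    rng = np.random.default_rng(seed)
    surp = features["surprisal_full"].to_numpy()
    zsurp = (surp - surp.mean()) / surp.std()
    if word_runs is None:
        word_runs = np.minimum(
            np.arange(n_words) // int(np.ceil(n_words / n_runs)), n_runs - 1
        )
    if annotations is not None:
        zlen = annotations["length"].to_numpy().astype(float)
        zlen = (zlen - zlen.mean()) / max(zlen.std(), 1e-12)
        zfreq = annotations["zipf"].to_numpy().astype(float)
        zfreq = (zfreq - zfreq.mean()) / max(zfreq.std(), 1e-12)
    else:
        zlen = np.zeros(n_words)
        zfreq = np.zeros(n_words)

    effect = np.zeros(n_words)
    for wl, lag in zip(w, SPILLOVER_LAGS):
        if wl == 0:
            continue
        shifted = np.zeros(n_words)
        if lag >= 0:
            shifted[lag:] = zsurp[: n_words - lag] if lag > 0 else zsurp
        else:
            shifted[:lag] = zsurp[-lag:]
        effect += wl * shifted

    frames = []
    for p in range(n_participants):
        noise = rng.normal(0, noise_sd, n_words)
        logrt = np.log(baseline_s) + effect + length_effect * zlen + freq_effect * zfreq + noise
        rt = np.clip(np.exp(logrt), 1e-4, 6.0)
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "run": word_runs,
                    "trial": np.arange(n_words),
                    "word_index": np.arange(n_words),
                    "rt_s": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
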