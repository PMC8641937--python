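"""Design-matrix construction: HRF convolution, per-run standardisation,
nuisance assembly and phase-randomised surrogate features.

Word-locked features are modelled as impulse trains at word onsets,
convolved with a canonical double-gamma haemodynamic response function
and sampled at the scanner repetition time.  All columns are z-scored
within runs.  Surrogate versions of the predictiveness columns preserve
each column's amplitude spectrum while randomising phase, and serve as
the null family for encoding-accuracy calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "hrf",
    "hrf_convolve",
    "phase_scramble",
    "DesignMatrix",
    "assemble_design",
    "ScrambleSet",
]


def hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Gamma densities with shape ``peak`` and ``undershoot`` (scale 1), the
    undershoot scaled by ``ratio``; the response peak sits near 5 s.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x, a):
        return np.exp((a - 1) * np.log(x) - x - gammaln(a))

    out[pos] = gpdf(tp, peak) - ratio * gpdf(tp, undershoot)
    return out


def hrf_convolve(
    events: Iterable[Tuple[float, float]],
    run_length: int,
    tr: float,
    *,
    dt: float = 0.05,
    hrf_kwargs: Optional[dict] = None,
) -> np.ndarray:
    """Convolve an (onset, amplitude) event train with the HRF.

    The train is laid out on a fine grid (``dt`` seconds), convolved, and
    sampled at multiples of ``tr``; returns a length ``run_length`` array.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    events = list(events)
    duration = run_length * tr
    n_fine = int(np.ceil(duration / dt)) + 1
    train = np.zeros(n_fine)
    for onset, amp in events:
        if onset < 0:
            raise ValueError(f"negative onset {onset}")
        idx = int(round(onset / dt))
        if idx < n_fine:
            train[idx] += amp
    kernel = hrf(np.arange(0, 32.0, dt), **(hrf_kwargs or {}))
    resp = np.convolve(train, kernel)[:n_fine] * dt
    sample_idx = np.round(np.arange(run_length) * tr / dt).astype(int)
    return resp[np.minimum(sample_idx, n_fine - 1)]


def phase_scramble(column: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Phase-randomised surrogates preserving the amplitude spectrum.

    Rotates the phase of every non-DC (and non-Nyquist) frequency
    component by an independent uniform angle with conjugate symmetry, so
    the inverse transform is real and the power spectrum is untouched.
    Returns an (n, len(column)) array.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 4:
        raise ValueError("series too short to scramble")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    n_freq = spec.size
    out = np.empty((n, x.size))
    has_nyquist = x.size % 2 == 0
    for i in range(n):
        phases = rng.uniform(0, 2 * np.pi, n_freq)
        phases[0] = 0.0
        if has_nyquist:
            phases[-1] = 0.0
        out[i] = np.fft.irfft(spec * np.exp(1j * phases), n=x.size)
    return out


@dataclass
class DesignMatrix:
    """Sample-aligned stimulus matrix with per-run z-scored columns."""

    S: np.ndarray  # (samples, features)
    columns: List[str]
    run_slices: List[slice]
    predictiveness_columns: List[str] = field(default_factory=list)
    dropped: List[str] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.run_slices)

    def column(self, name: str) -> np.ndarray:
        return self.S[:, self.columns.index(name)]

    def runs_of_rows(self) -> np.ndarray:
        out = np.empty(self.S.shape[0], dtype=int)
        for r, sl in enumerate(self.run_slices):
            out[sl] = r
        return out


def _zscore_per_run(x: np.ndarray, run_slices: List[slice]) -> Tuple[np.ndarray, bool]:
    out = np.empty_like(x, dtype=float)
    degenerate = False
    for sl in run_slices:
        seg = x[sl]
        sd = seg.std()
        if sd < 1e-12:
            out[sl] = 0.0
            degenerate = True
        else:
            out[sl] = (seg - seg.mean()) / sd
    return out, degenerate


def assemble_design(
    features: pd.DataFrame,
    onsets: Sequence[np.ndarray],
    word_runs: np.ndarray,
    run_length: int,
    tr: float,
    *,
    annotations: Optional[pd.DataFrame] = None,
    acoustic: Optional[np.ndarray] = None,
    predictiveness_columns: Optional[List[str]] = None,
    drop_constant: bool = True,
) -> DesignMatrix:
    """Build the sample-aligned design matrix for one feature set.

    ``features`` holds word-locked columns (the predictiveness family and
    any other per-word covariates).  Three linguistic nuisance columns are
    derived from ``annotations``: a word-presentation train (coded 1), the
    content/function flag (coded +1 / -1) and word frequency.  ``acoustic``
    is an optional (total samples, k) matrix of sample-aligned nuisance
    components (e.g. spectrotemporal principal components) appended as-is
    before z-scoring.  Word-locked columns are HRF-convolved per run and
    every column is z-scored per run; constant columns are dropped with a
    log message.  Entropy columns lack a value at each run's final word
    (no successor); those entries are imputed with the run mean and
    flagged.
    """
    n_runs = len(onsets)
    word_runs = np.asarray(word_runs)
    if features.isna().any().any():
        features = features.copy()
        for col in features.columns:
            if features[col].isna().any():
                if not col.startswith("entropy"):
                    bad = int(features[col].isna().idxmax())
                    raise ValueError(f"missing annotation in column {col!r} at word {bad}")
                for r in range(n_runs):
                    m = word_runs == r
                    vals = features.loc[m, col]
                    features.loc[m & features[col].isna(), col] = vals.mean()
                logger.warning("entropy column %s imputed at run-final words", col)

    run_slices = [slice(r * run_length, (r + 1) * run_length) for r in range(n_runs)]
    total = n_runs * run_length

    cols: List[str] = []
    data: List[np.ndarray] = []

    def convolve_column(values: np.ndarray) -> np.ndarray:
        out = np.empty(total)
        for r in range(n_runs):
            m = word_runs == r
            out[run_slices[r]] = hrf_convolve(
                list(zip(onsets[r], values[m])), run_length, tr
            )
        return out

    for col in features.columns:
        cols.append(col)
        data.append(convolve_column(features[col].to_numpy(dtype=float)))

    if annotations is not None:
        cols.append("word_onset")
        data.append(convolve_column(np.ones(len(features))))
        cols.append("content_flag")
        data.append(convolve_column(annotations["content"].to_numpy(dtype=float)))
        cols.append("word_frequency")
        data.append(convolve_column(annotations["zipf"].to_numpy(dtype=float)))

    if acoustic is not None:
        acoustic = np.asarray(acoustic, dtype=float)
        if acoustic.shape[0] != total:
            raise ValueError("acoustic nuisance must be sample-aligned")
        for k in range(acoustic.shape[1]):
            cols.append(f"acoustic_pc{k + 1}")
            data.append(acoustic[:, k])

    S = np.column_stack(data)
    kept, names, dropped = [], [], []
    for j, name in enumerate(cols):
        z, degen = _zscore_per_run(S[:, j], run_slices)
        if degen and drop_constant and np.allclose(z, 0):
            dropped.append(name)
            logger.warning("dropping constant design column %s", name)
            continue
        kept.append(z)
        names.append(name)
    S = np.column_stack(kept)

    if predictiveness_columns is None:
        predictiveness_columns = [
            c
            for c in names
            if c.startswith(("surprisal", "entropy", "dissimilarity"))
        ]
    return DesignMatrix(
        S=S,
        columns=names,
        run_slices=run_slices,
        predictiveness_columns=[c for c in predictiveness_columns if c in names],
        dropped=dropped,
    )


class ScrambleSet:
    """Lazily generated phase-randomised versions of the predictiveness
    columns of a design matrix (nuisance columns untouched).

    Surrogates are generated per run so each run's spectrum is preserved,
    then re-z-scored per run.  Indexing is deterministic in the seed.
    """

    def __init__(self, design: DesignMatrix, n: int = 500, seed: int = 0):
        if n < 1:
            raise ValueError("need at least one surrogate")
        self.design = design
        self.n = n
        self.seed = seed
        self._col_idx = [design.columns.index(c) for c in design.predictiveness_columns]

    def __len__(self) -> int:
        return self.n

    def surrogate(self, i: int) -> np.ndarray:
        """Full design matrix with predictiveness columns replaced by the
        i-th surrogate."""
        if not 0 <= i < self.n:
            raise IndexError(i)
        S = self.design.S.copy()
        for k, j in enumerate(self._col_idx):
            for r, sl in enumerate(self.design.run_slices):
                seed = np.random.SeedSequence([self.seed, i, k, r]).generate_state(1)[0] % (2**31)
                surr = phase_scramble(self.design.S[sl, j], 1, int(seed))[0]
                sd = surr.std()
                S[sl, j] = (surr - surr.mean()) / sd if sd > 1e-12 else 0.0
        return S
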