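import numpy as np
import pandas as pd
import pytest

from eventscales.design import assemble_design
from eventscales.ridge import lambda_grid
from eventscales.synthetic import (
    default_ground_truth,
    generate_corpus,
    generate_cohort,
    synthetic_feature_table,
)

SHEET = (24, 48)
RUN_LEN = 96
SMOOTH = dict(smooth_window=12.0)  # profile smoothing scaled to the small sheet


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(24, 3, [4, 16, 64], 2600, seed=1)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    return synthetic_feature_table(len(small_corpus.tokens), seed=2)


@pytest.fixture(scope="session")
def planted_truth():
    return default_ground_truth(
        8.0,
        sheet_shape=SHEET,
        is_origin=4.0,
        seed_coupling=[(s, s + 1, 1.5) for s in range(1, 5)]
        + [(s + 1, s, 1.5) for s in range(1, 5)],
        spillover_weights=[0, 0, 0.3, 0.15, 0.05, 0, 0, 0],
    )


@pytest.fixture(scope="session")
def planted_cohort(small_corpus, small_features, planted_truth):
    return generate_cohort(
        small_corpus,
        small_features,
        planted_truth,
        n_participants=4,
        n_runs=8,
        noise_sd=1.0,
        gain=1.5,
        seed=3,
        sheet_shape=SHEET,
        run_length=RUN_LEN,
    )


@pytest.fixture(scope="session")
def small_design(small_corpus, small_features, planted_cohort):
    rng = np.random.default_rng(0)
    return assemble_design(
        small_features,
        planted_cohort.word_onsets,
        planted_cohort.word_runs,
        planted_cohort.run_length,
        planted_cohort.tr,
        annotations=small_corpus.annotations,
        acoustic=rng.normal(0, 1, (planted_cohort.n_runs * RUN_LEN, 9)),
    )


@pytest.fixture(scope="session")
def small_grid():
    return lambda_grid(30)
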