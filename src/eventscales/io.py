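"""File formats: tab-separated corpora and reading logs, HDF5 cohorts
and checkpoints, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import h5py
import numpy as np
import pandas as pd

from .lm import LMConfig, SequenceModel
from .synthetic import GroundTruth, SheetSeries, SyntheticCohort, SyntheticCorpus


def save_corpus(corpus: SyntheticCorpus, path_prefix: str | Path) -> None:
    """Token ids + annotations as TSV; embeddings and boundaries in HDF5."""
    prefix = Path(path_prefix)
    df = corpus.annotations.copy()
    df.insert(0, "token", corpus.tokens)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index_label="word_index")
    with h5py.File(prefix.with_suffix(".h5"), "w") as f:
        f.create_dataset("embeddings", data=corpus.embeddings)
        for k, b in enumerate(corpus.boundaries):
            f.create_dataset(f"boundaries/level{k + 1}", data=b)


def load_corpus(path_prefix: str | Path) -> SyntheticCorpus:
    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="word_index")
    with h5py.File(prefix.with_suffix(".h5"), "r") as f:
        emb = f["embeddings"][()]
        levels = sorted(f["boundaries"], key=lambda s: int(s.removeprefix("level")))
        bounds = [f[f"boundaries/{lvl}"][()] for lvl in levels]
    tokens = df.pop("token").to_numpy()
    return SyntheticCorpus(tokens=tokens, boundaries=bounds, embeddings=emb, annotations=df)


def save_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["tr"] = cohort.tr
        f.attrs["run_length"] = cohort.run_length
        geom = f.create_group("geometry")
        geom.create_dataset("coords", data=cohort.participants[0].coords)
        geom.create_dataset("parcel", data=cohort.participants[0].parcel)
        for i, part in enumerate(cohort.participants):
            for j, run in enumerate(part.runs):
                f.create_dataset(f"participant{i}/run{j}/bold", data=run)
        for j, on in enumerate(cohort.word_onsets):
            f.create_dataset(f"onsets/run{j}", data=on)
        f.create_dataset("word_runs", data=cohort.word_runs)
    truth = cohort.truth
    sidecar = {
        "vertex_scale": truth.vertex_scale.tolist(),
        "true_gradient_slope": truth.true_gradient_slope,
        "seed_coupling": [list(c) for c in truth.seed_coupling],
        "spillover_weights": None
        if truth.spillover_weights is None
        else list(map(float, truth.spillover_weights)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_cohort(path: str | Path) -> SyntheticCohort:
    path = Path(path)
    with h5py.File(path, "r") as f:
        coords = f["geometry/coords"][()]
        parcel = f["geometry/parcel"][()]
        participants = []
        i = 0
        while f"participant{i}" in f:
            grp = f[f"participant{i}"]
            runs = [grp[f"run{j}/bold"][()] for j in range(len(grp))]
            participants.append(SheetSeries(runs=runs, coords=coords, parcel=parcel))
            i += 1
        onsets = [f[f"onsets/run{j}"][()] for j in range(len(f["onsets"]))]
        word_runs = f["word_runs"][()]
        tr = float(f.attrs["tr"])
        run_length = int(f.attrs["run_length"])
    side = json.loads(path.with_suffix(".json").read_text())
    truth = GroundTruth(
        vertex_scale=np.asarray(side["vertex_scale"], dtype=int),
        true_gradient_slope=side["true_gradient_slope"],
        seed_coupling=[tuple(c) for c in side["seed_coupling"]],
        spillover_weights=None
        if side["spillover_weights"] is None
        else np.asarray(side["spillover_weights"]),
    )
    return SyntheticCohort(
        participants=participants,
        word_onsets=onsets,
        word_runs=word_runs,
        truth=truth,
        tr=tr,
        run_length=run_length,
    )


def save_checkpoint(model: SequenceModel, path: str | Path, log: Optional[List[dict]] = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in model.params.items():
            f.create_dataset(f"params/{name}", data=arr)
        f.create_dataset("embeddings", data=model.embeddings)
        f.attrs["config"] = json.dumps(model.config.__dict__)
    if log is not None:
        pd.DataFrame(log).to_csv(path.with_suffix(".log.csv"), index=False)


def load_checkpoint(path: str | Path) -> SequenceModel:
    path = Path(path)
    with h5py.File(path, "r") as f:
        config = LMConfig(**json.loads(f.attrs["config"]))
        emb = f["embeddings"][()]
        model = SequenceModel(config, embeddings=emb, seed=0)
        for name in model.params:
            model.params[name] = f[f"params/{name}"][()]
    if config.embeddings_trainable:
        model.embeddings = model.params["embeddings"]
    return model


def save_reading_logs(logs: pd.DataFrame, path: str | Path) -> None:
    logs.to_csv(path, sep="\t", index=False)


def load_reading_logs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
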