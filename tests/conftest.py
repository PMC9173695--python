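"""Shared fixtures.

The "study" fixtures set up the desk-scale end-to-end experiment used by
the heavier tests: a separable synthetic dataset (every mRNA-like sequence
carries the planted domain motif), a scaled-down CNN trained on it, its
test-set predictions, and SHAP attributions for a held-out subset. They
are session-scoped so the suite trains the model and runs the attribution
pass exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import xlnc1d as x
from xlnc1d import explainer

DATA_SEED = 11
MODEL_SEED = 7
N_PER_CLASS = 200          # 150 train + 50 test per class after the 0.25 split
LENGTH_RANGE = (200, 600)
INPUT_LENGTH = 600
N_EXPLAIN_PER_CLASS = 30   # held-out sequences explained with SHAP
BACKGROUND_PER_CLASS = 8
SHAP_STEPS = 25


@pytest.fixture(scope="session")
def study_data():
    spec = x.SyntheticSpec(
        n_per_class=N_PER_CLASS,
        length_range=LENGTH_RANGE,
        motif=x.DEFAULT_MOTIF,
        motif_rate=1.0,
        seed=DATA_SEED,
    )
    records, annotations = x.generate_dataset(spec)
    train_recs, test_recs = x.stratified_split(
        records, x.SplitSpec(test_fraction=0.25, seed=DATA_SEED)
    )
    return {
        "spec": spec,
        "records": records,
        "annotations": {a.seq_id: a for a in annotations},
        "train_records": train_recs,
        "test_records": test_recs,
        "train": x.encode_dataset(train_recs, INPUT_LENGTH),
        "test": x.encode_dataset(test_recs, INPUT_LENGTH),
    }


@pytest.fixture(scope="session")
def study_model(study_data):
    config = x.ModelConfig.scaled_down(seed=MODEL_SEED)
    model = x.build_model(config)
    return x.train(model, study_data["train"], config)


@pytest.fixture(scope="session")
def study_predictions(study_model, study_data):
    preds = x.predict(study_model, study_data["test"])
    labels = {r.id: r.label for r in study_data["test_records"]}
    return preds, labels


@pytest.fixture(scope="session")
def study_attributions(study_model, study_data):
    """SHAP attributions for a held-out subset, both classes."""
    test = study_data["test"]
    background = explainer.select_background(
        study_data["train"], n_per_class=BACKGROUND_PER_CLASS, seed=MODEL_SEED
    )
    mrna_idx = np.flatnonzero(test.labels == 0)[:N_EXPLAIN_PER_CLASS]
    lnc_idx = np.flatnonzero(test.labels == 1)[:N_EXPLAIN_PER_CLASS]
    subset = test.subset(np.concatenate([mrna_idx, lnc_idx]))
    attrs = explainer.compute_shap(
        study_model, background, subset, n_steps=SHAP_STEPS
    )
    by_id = {r.id: r for r in study_data["test_records"]}
    records = [by_id[i] for i in subset.ids]
    tracks = []
    for attr in attrs:
        track = explainer.collapse_to_nucleotide(attr)
        track.values = track.values[: attr.seq_length]
        tracks.append(track)
    return {
        "background": background,
        "subset": subset,
        "attrs": attrs,
        "records": records,
        "tracks": tracks,
    }


@pytest.fixture(scope="session")
def tiny_model():
    """A quickly trained small model for mechanics-level tests."""
    spec = x.SyntheticSpec(
        n_per_class=24, length_range=(200, 240), motif=x.DEFAULT_MOTIF,
        motif_rate=1.0, seed=3,
    )
    records, _ = x.generate_dataset(spec)
    ds = x.encode_dataset(records, 240)
    config = x.ModelConfig.scaled_down(
        input_length=240, filters_per_block=6, epochs=4, batch_size=8, seed=5
    )
    model = x.train(x.build_model(config), ds, config)
    return model, ds, records
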