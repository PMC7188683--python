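"""Shared fixtures.

The planted-motif recovery study (generate -> encode at k=8 -> 1:1 split
with 300 positives) is expensive enough that it is built once per session
and shared by the model-recovery, ablation and projection tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import afplatent as ap

#: Frozen base seed for every session-scoped study in the suite.
BASE_SEED = 0

#: Reduced-epoch budget used for desk-scale training runs; early stopping
#: fires well before this on the synthetic recovery study.
FAST_EPOCHS = 300


@pytest.fixture(scope="session")
def recovery_study():
    """Planted-signal dataset, encoded at k=8, with a 300/300 1:1 split.

    Generator conditions: 500 positives / 500 negatives, default single
    planted pair (A, C, gap 3) at enrichment 10, lengths 50-300, uniform
    background.  The remaining 200/200 sequences are the held-out test set.
    """
    spec = ap.SyntheticSpec(n_pos=500, n_neg=500, seed=BASE_SEED)
    records, labels = ap.generate_dataset(spec)
    X, ids = ap.encode_dataset(records, ap.CKSAAPConfig(k=8))
    train_idx, test_idx = ap.ratio_split(labels, "1:1", 300, seed=BASE_SEED)
    return {
        "records": records,
        "labels": labels,
        "X": X,
        "train_idx": train_idx,
        "test_idx": test_idx,
    }


@pytest.fixture(scope="session")
def recovery_result(recovery_study):
    """The k=8 / LV=4 joint model trained on the recovery study split."""
    s = recovery_study
    cfg = ap.JointModelConfig(input_dim=s["X"].shape[1], latent_dim=4)
    tc = ap.TrainConfig(
        max_epochs=FAST_EPOCHS, early_stop_patience=50, seed=BASE_SEED
    )
    return ap.run_experiment(
        s["X"][s["train_idx"]],
        s["labels"][s["train_idx"]],
        s["X"][s["test_idx"]],
        s["labels"][s["test_idx"]],
        cfg,
        tc,
    )
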