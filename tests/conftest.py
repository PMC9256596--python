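"""Shared fixtures.

The trained-classifier fixtures are session-scoped because CPU training is
the expensive part of the suite; every test that needs a trained model
shares the same run (learnability, permuted-label control, boundary
overlay).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from thgqc import experiments
from thgqc.fcn_model import build_fcn
from thgqc.training import train_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def _split_by_case(samples, val_cases):
    tr = [s for s in samples if s.case_id not in val_cases]
    va = [s for s in samples if s.case_id in val_cases]
    return tr, va


VAL_CASES = frozenset({"epilepsy-00", "glioma-00", "glioma-01",
                       "glioma-02", "glioma-03"})


@pytest.fixture(scope="session")
def separable_samples():
    return experiments.learnability_samples(seed=7)


@pytest.fixture(scope="session")
def separable_run(separable_samples):
    """(model, history, val_samples) trained on cleanly separable phantoms."""
    tr, va = _split_by_case(separable_samples, VAL_CASES)
    model = build_fcn(experiments.DESK_FCN, seed=11)
    cfg = dataclasses.replace(experiments.DESK_TRAIN, max_epochs=12, seed=3)
    model, history = train_model(model, tr, va, cfg)
    return model, history, va


@pytest.fixture(scope="session")
def permuted_run(separable_samples):
    """The no-signal control: same data with permuted labels."""
    shuffled = experiments.permute_labels(separable_samples, seed=5)
    tr, va = _split_by_case(shuffled, VAL_CASES)
    model = build_fcn(experiments.DESK_FCN, seed=11)
    cfg = dataclasses.replace(experiments.DESK_TRAIN, max_epochs=12, seed=3)
    model, history = train_model(model, tr, va, cfg)
    return model, history, va
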