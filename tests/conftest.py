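"""Shared fixtures: small synthetic datasets and fitted state spaces."""

import logging

import numpy as np
import pytest

from raman_cellstate import SpectraDataset, WavenumberAxis
from raman_cellstate import synth
from raman_cellstate.preprocess import snv_rows
from raman_cellstate.state_space import build_state_space

# NIPALS non-convergence warnings on noise-floor components are expected
# at small n; keep test output quiet.
logging.getLogger("raman_cellstate.nipals").setLevel(logging.ERROR)

FP_CROP = (600.0, 1800.0)


def standardize(X_raw: np.ndarray, crop=FP_CROP):
    """Fingerprint-crop + row SNV of raw generator output."""
    axis = synth.default_axis()
    sel = axis.range_mask(*crop)
    return snv_rows(X_raw[:, sel]), WavenumberAxis(axis.values[sel])


def make_dataset(n_per_class=(96, 60), separation=1.0, seed=0, crop=FP_CROP):
    X_raw, labels = synth.simulate_dataset(
        n_per_class=n_per_class, separation=separation, seed=seed
    )
    Z, axis = standardize(X_raw, crop)
    return SpectraDataset(
        X=Z,
        labels=labels,
        cell_ids=[f"sim:{i}" for i in range(Z.shape[0])],
        axis=axis,
    )


@pytest.fixture(scope="session")
def supervisor_dataset():
    """Two-class supervisor data at study scale (96 naive, 60 activated)."""
    return make_dataset(seed=11)


@pytest.fixture(scope="session")
def bundle(supervisor_dataset):
    """Frozen state space fitted on the supervisor dataset (k=7)."""
    return build_state_space(supervisor_dataset, k=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
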