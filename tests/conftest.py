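"""Shared fixtures: synthetic datasets and cached optimizer runs.

The expensive repeated-run results are computed once per session and shared
between the behavioural tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from mantafs import (
    BinaryPSOSelector,
    MantaRayBPSOSelector,
    MaskEvaluator,
    SyntheticSpec,
    synthesize_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def d8_dataset():
    """Tiny 8-feature problem for exhaustive-enumeration oracle checks."""
    spec = SyntheticSpec(
        n_samples=40, n_classes=2, n_informative=2, n_redundant=2,
        n_noise=4, effect_size=2.0, seed=3,
    )
    return synthesize_dataset(spec)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The 60-sample, 3-class, 500-feature recovery benchmark dataset
    (10 informative, 20 redundant, 470 noise, effect size 3)."""
    return synthesize_dataset(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def paired_runs(recovery_dataset):
    """20 paired runs of the manta-ray selector and the S-shaped baseline on
    the recovery dataset, sharing the optimizer seed per run index."""
    ds = recovery_dataset
    mrfl, sbpso = [], []
    for r in range(20):
        mrfl.append(MantaRayBPSOSelector(random_state=r).fit(ds.X, ds.y))
        sbpso.append(BinaryPSOSelector(transfer="s", random_state=r).fit(ds.X, ds.y))
    return mrfl, sbpso


@pytest.fixture(scope="session")
def d8_fitness_oracle(d8_dataset):
    """Deterministic fitness over the 8-feature problem with a frozen split."""

    def factory():
        return MaskEvaluator(d8_dataset.X, d8_dataset.y, rng=0)

    return factory
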