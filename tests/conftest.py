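"""Shared fixtures.

The expensive artifacts — trained fixture models, the synthetic cohorts and
their pipeline-extracted features, and the slide classifiers — are session
scoped and shared across test modules, so the networks are trained exactly
once per run under the documented study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytofna.diagnose import train_gene_gbt, train_wsi_gbt
from cytofna.pipeline import (cohort_features, tile128_config,
                              train_fixture_models)
from cytofna.synthcyto import sample_cohort

SEED = 0


@pytest.fixture(scope="session")
def fixture_models():
    """Segmentation net (50 patches, 30 epochs), cell net (480 crops of the
    six distinct classes, 40 epochs) and morphology GBT, all at seed 0."""
    return train_fixture_models(seed=SEED)


@pytest.fixture(scope="session")
def train_cohort():
    return sample_cohort(150, seed=101)


@pytest.fixture(scope="session")
def test_cohort():
    return sample_cohort(200, seed=202)


@pytest.fixture(scope="session")
def train_features(fixture_models, train_cohort):
    return cohort_features(train_cohort, fixture_models, tile128_config())


@pytest.fixture(scope="session")
def test_features(fixture_models, test_cohort):
    return cohort_features(test_cohort, fixture_models, tile128_config())


@pytest.fixture(scope="session")
def wsi_models(train_features):
    """3-class and 2-class slide classifiers trained on adequate slides."""
    x, labels, _ = train_features
    sel = [i for i, l in enumerate(labels) if l != "I"]
    x2 = x.iloc[sel]
    y2 = [labels[i] for i in sel]
    wsi3 = train_wsi_gbt(x2, y2, n_classes=3, seed=SEED)
    wsi2 = train_wsi_gbt(x2, y2, n_classes=2, seed=SEED)
    return wsi3, wsi2


@pytest.fixture(scope="session")
def gene_model(train_features):
    x, _, braf = train_features
    return train_gene_gbt(x, braf, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
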