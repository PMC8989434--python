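"""Shared fixtures: small in-memory phantom cohorts and trained models.

Everything is generated programmatically and seeded; the heavier trained
fixtures are session-scoped so the detector/measurement/sulci training runs
once for the whole suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ctatrophy import phantom as ph
from ctatrophy.classifier import ClassifierConfig
from ctatrophy.features import prepare_subject
from ctatrophy.measure import MeasureConfig
from ctatrophy.pipeline import PipelineConfig, run_training_suite
from ctatrophy.slice_detect import SliceDetectConfig
from ctatrophy.sulci import SulciConfig


@pytest.fixture(scope="session")
def untilted_phantom():
    """One untilted mild-atrophy phantom with its annotation and spec."""
    spec = ph.sample_phantom_spec("mild", 11)
    spec = dataclasses.replace(spec, head_tilt_deg=0.0)
    volume, annotation = ph.render_volume(spec)
    return spec, volume, annotation


@pytest.fixture(scope="session")
def mini_subjects():
    """15 prepared subjects (5 per class), enough to exercise training."""
    subjects = []
    for sid, spec in ph.dataset_specs(5, 21):
        volume, annotation = ph.render_volume(spec)
        s = prepare_subject(sid, volume, annotation, age=spec.age, gender_code=spec.gender_code)
        s.extras["spec"] = spec
        subjects.append(s)
    return subjects


@pytest.fixture(scope="session")
def mini_config():
    """A fast pipeline configuration for the 15-subject fixtures."""
    return PipelineConfig(
        seed=5,
        task="three_class",
        detect=SliceDetectConfig(epochs=6, seed=5),
        measure=MeasureConfig(epochs=40, seed=5),
        sulci=SulciConfig(epochs=8, seed=5),
        # only 4 training subjects per class in the 15-subject fixture
        classifier=ClassifierConfig(n_folds=3, seed=5),
    )


@pytest.fixture(scope="session")
def mini_bundle(mini_subjects, mini_config):
    """A trained (small) model bundle plus its training report."""
    bundle, report = run_training_suite(mini_subjects, mini_config)
    return bundle, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
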