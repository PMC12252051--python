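"""Shared fixtures: small synthetic cohorts and a trained reduced model.

Everything is generated programmatically and seeded; the expensive trained
model is session-scoped so several tests can interrogate it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gaitlens as gl
from gaitlens import model as M


@pytest.fixture(scope="session")
def clean_two_class_cohort():
    """Noise-free 2-class cohort (regular vs strong left limp)."""
    cfg = gl.CohortConfig(
        n_subjects=6, frames_per_recording=140, seed=11,
        noise_sd=0.0, occlusion_rate=0.0,
        class_list=(gl.PathologySpec("none"),
                    gl.PathologySpec("limp_left", 0.8)))
    return gl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_three_class_cohort():
    """Realistic 3-class cohort with key-point noise and occlusions."""
    cfg = gl.CohortConfig(
        n_subjects=6, frames_per_recording=140, seed=7,
        noise_sd=0.005, occlusion_rate=0.01,
        class_list=(gl.PathologySpec("none"),
                    gl.PathologySpec("limp_left", 0.8),
                    gl.PathologySpec("weighted", 0.8)))
    return gl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_model_config():
    return M.ModelConfig(n_blocks=3, channels_per_block=(8, 16, 24),
                         n_classes=2, attention_heads=2)


@pytest.fixture(scope="session")
def small_train_config():
    return M.TrainConfig(epochs=25, learning_rate=0.02, batch_size=32,
                         folds=1, seed=3)


@pytest.fixture(scope="session")
def trained_two_class(clean_two_class_cohort, small_model_config,
                      small_train_config):
    """Trained reduced model + instances/labels on the separable cohort."""
    instances = gl.preprocess_cohort(clean_two_class_cohort)
    labels = [i.class_label for i in instances]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, fold_metrics = M.train(small_model_config, instances, labels,
                                      small_train_config)
    return {"model": model, "instances": instances, "labels": labels,
            "fold_metrics": fold_metrics}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
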