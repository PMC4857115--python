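"""Shared fixtures: one synthetic study (seed 1) generated once per session
and threaded through the activity → enrichment → network chain."""

import numpy as np
import pytest
from hypothesis import settings

from phytoscreen import (
    GeneratorConfig,
    fit_activity_model,
    generate_dataset,
    predict_library,
    run_acea,
)
from phytoscreen.pipeline import _fps_of

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def reference_fps(dataset):
    _, ra = _fps_of(dataset.reference_actives)
    _, rd = _fps_of(dataset.reference_decoys)
    return ra, rd


@pytest.fixture(scope="session")
def model(reference_fps):
    ra, rd = reference_fps
    return fit_activity_model(ra, rd)


@pytest.fixture(scope="session")
def calls(model, dataset):
    return predict_library(model, dataset.compounds)


@pytest.fixture(scope="session")
def acea_results(dataset, calls):
    return run_acea(dataset.plants, calls)


@pytest.fixture(scope="session")
def library_fps(dataset):
    """(ids, fingerprint matrix, truth labels) of the full library."""
    kept, fps = _fps_of(dataset.compounds)
    labels = np.array(
        [c.compound_id in dataset.truth.active_ids for c in kept], dtype=bool
    )
    return [c.compound_id for c in kept], fps, labels
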