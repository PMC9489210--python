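"""Shared fixtures: one small synthetic session and its derived artifacts.

Session sizes here are deliberately smaller than the generator defaults so
the whole suite runs quickly; statistical assertions use tolerances chosen
for these sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from ratereplay import pipeline, placefields
from ratereplay.config import PipelineConfig
from ratereplay.simulate import SimConfig, make_session


@pytest.fixture(scope="session")
def small_session():
    cfg = SimConfig(seed=11, n_cells=30, n_laps=8, n_events_pre=20,
                    n_events_post_per_track=20)
    return make_session(cfg)


@pytest.fixture(scope="session")
def pipe_cfg():
    cfg = PipelineConfig(seed=11)
    cfg.shuffles.n_shuffles = 300
    cfg.logodds.n_label_shuffles = 300
    cfg.logodds.n_bootstrap = 300
    return cfg


@pytest.fixture(scope="session")
def session_artifacts(small_session, pipe_cfg):
    maps = pipeline.build_ratemaps(small_session, pipe_cfg)
    labels = placefields.select_place_cells(small_session, maps)
    model = pipeline.build_decoder(small_session, maps, labels, pipe_cfg)
    return {"maps": maps, "labels": labels, "model": model}


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
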