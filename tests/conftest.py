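import numpy as np
import pandas as pd
import pytest

from gazemem.synthdata import (ChoiceModel, GazeModel, StudyConfig,
                               generate_study)


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(n_young=4, n_older=4, n_groups=30,
                       trials_per_condition=10, n_new_cues=6, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small but complete simulated study with the reference models."""
    return generate_study(small_config, ChoiceModel.reference(),
                          GazeModel.reference())


@pytest.fixture(scope="session")
def clean_study():
    """Study with no off-stimulus gaze and deterministic choices."""
    cfg = StudyConfig(n_young=3, n_older=3, n_groups=24,
                      trials_per_condition=8, n_new_cues=4, seed=7)
    gaze = GazeModel.constant(p_offstim=0.0, kappa=1.0, early_bias=0.5)
    return generate_study(cfg, ChoiceModel.deterministic(), gaze)


def make_fix_frame(rows):
    """Helper: build a fixation-report frame from (msg, t_on, t_off, x, y)
    tuples for a single participant and eye."""
    return pd.DataFrame(
        [{"participant": "P01", "msg": m, "eye": "R", "t_on_ms": float(a),
          "t_off_ms": float(b), "x_px": x, "y_px": y}
         for m, a, b, x, y in rows])


@pytest.fixture
def fix_builder():
    return make_fix_frame


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
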