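import numpy as np
import pytest

from sensorymap import percepts as pc
from sensorymap import synth


@pytest.fixture(scope="session")
def template():
    return pc.build_hand_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A tiny synthetic study, generated once per session."""
    out = tmp_path_factory.mktemp("study")
    cfg = synth.StudyGenConfig(
        n_subjects=2,
        electrodes_per_subject=(2, 3),
        weeks_per_subject=(3, 4),
        subject_mean_threshold_mA=(1.5, 2.0),
        trials_per_level=30,
        n_reports_per_electrode=12,
        reps_per_week=2,
        write_masks=False,
    )
    return synth.generate_study(cfg, seed=42, out_dir=out)
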