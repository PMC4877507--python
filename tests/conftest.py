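import numpy as np
import pytest

from rhythmtag import RunConfig
from rhythmtag.pipeline import derive_frequencies


def tiny_exp1(seed=0, **cohort_overrides):
    """Cheap Exp-1-style run config for simulation tests: 200 Hz recordings
    (resampling becomes the identity), few channels/trials."""
    cohort = dict(
        n_subjects={"music": 2, "no_music": 2},
        n_trials=2,
        n_channels=4,
        rate_hz=200.0,
        noise_level_uv=2.0,
    )
    cohort.update(cohort_overrides)
    return RunConfig.preset_exp1(seed=seed, cohort=cohort)


@pytest.fixture(scope="session")
def exp1_freqs():
    """Tagged/control frequency sets of the six-slot rhythm (memoised)."""
    return derive_frequencies(RunConfig.preset_exp1())


@pytest.fixture(scope="session")
def exp2_freqs():
    return derive_frequencies(RunConfig.preset_exp2())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
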