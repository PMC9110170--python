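import numpy as np
import pytest

from mindfuse.synth import CohortSpec, generate_cohort, generate_cohort_arrays


def fast_spec(**kwargs) -> CohortSpec:
    """Desk-scale cohort parameters: short streams, 8 kHz audio."""
    params = dict(
        fps=10.0,
        face_duration=30.0,
        gait_duration=8.0,
        voice_segments=1,
        voice_duration=1.0,
        sample_rate=8000,
    )
    params.update(kwargs)
    return CohortSpec(**params)


@pytest.fixture(scope="session")
def tiny_subjects():
    """Four in-memory subjects with mild uniform effects."""
    spec = fast_spec(n_subjects=4, effects=1.0, seed=3)
    return spec, generate_cohort_arrays(spec)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A small cohort written to disk (for CLI / pipeline tests)."""
    # seed chosen so every indicator has at least 3 samples of each class
    spec = fast_spec(n_subjects=12, effects=2.0, seed=14, fps=5.0)
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(spec, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
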