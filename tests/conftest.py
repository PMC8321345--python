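import numpy as np
import pytest

from nestseg.synthetic import FixtureParams, generate_split


def small_fixture_params(n_sections: int, **overrides) -> FixtureParams:
    """CPU-sized fixture profile shared across tests: 256-384 px sections with
    ~4000 um^2 nests, matching the scaled study geometry."""
    kwargs = dict(
        n_sections=n_sections, size_range=(256, 384), mpp=1.0,
        nest_area_median_um2=4000.0, nest_area_sigma=0.3,
        stroma_halo_um=12.0, distractor_area_median_um2=700.0,
        distractor_count_range=(0, 3))
    kwargs.update(overrides)
    return FixtureParams(**kwargs)


@pytest.fixture(scope="session")
def small_sections():
    """Four deterministic small sections (mixed labels) with annotations."""
    return generate_split(small_fixture_params(4), "fix", seed=42)


@pytest.fixture(scope="session")
def study_result():
    """The full scaled end-to-end study (train + select + evaluate), run once
    per session and shared by every test that needs a trained model."""
    from nestseg.study import run_study

    return run_study(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
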