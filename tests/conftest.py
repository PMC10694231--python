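import numpy as np
import pytest

from canopyreg.core_data import TraitVector, split_by_treatment
from canopyreg.synthetic_trial import RenderConfig, generate_trial


@pytest.fixture(scope="session")
def feature_trial():
    """7-treatment feature-mode trial, low noise, split 2 treatments out."""
    ds = generate_trial(7, 2, 12, 6, render=RenderConfig(mode="feature", noise_sd=1e-3), seed=42)
    return split_by_treatment(ds, ["T3", "T6"])


@pytest.fixture(scope="session")
def image_trial(tmp_path_factory):
    """Small image-mode trial (3 treatments x 2 reps, 32px scenes)."""
    td = tmp_path_factory.mktemp("trial")
    ds = generate_trial(
        3, 2, 8, 5, render=RenderConfig(mode="image", image_size=32), seed=7, out_dir=td
    )
    return split_by_treatment(ds, ["T2"])


@pytest.fixture
def mid_season_traits():
    return TraitVector(
        dm_total=10.0,
        lai=4.0,
        n_conc=2.0,
        n_upt=200.0,
        dm_prop=np.array([0.5, 0.25, 0.1, 0.15]),
        nupt_prop=np.array([0.4, 0.25, 0.15, 0.2]),
        n_conc_organ=np.array([1.5, 2.2, 3.0, 2.5]),
    )
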