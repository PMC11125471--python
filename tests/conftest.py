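import numpy as np
import pytest

from octexan import roi as roi_mod
from octexan.pipeline import PipelineConfig, fit_system
from octexan.synthetic import default_config_sampler, generate_scene


def make_scenes(n, master_seed, **overrides):
    """n scenes with varied wing geometry, deterministic in master_seed."""
    rng = np.random.default_rng(master_seed)
    return [generate_scene(default_config_sampler(i, rng, **overrides)) for i in range(n)]


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(roi=roi_mod.scaled_down_config(rng_seed=0))


@pytest.fixture(scope="session")
def trained_system(pipeline_config):
    """ROI segmenter + blob classifier trained once on 40 synthetic scenes.

    Shared by the segmentation-quality and end-to-end tests; training is
    the scaled-down CPU recipe (base_filters 8, 64-px patches, 10 epochs).
    """
    scenes = make_scenes(40, master_seed=1000)
    model, clf, history = fit_system(scenes, pipeline_config)
    return model, clf, history
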