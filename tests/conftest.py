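import numpy as np
import pytest

from sampdetect import simulate
from sampdetect.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def clean_scene():
    """Seeded noise-free scene with well-separated particles."""
    cfg = simulate.SceneConfig(seed=11, n_grains=6, n_fibers=3,
                               background_noise_sd=0.0, n_frames=100)
    frames, log = simulate.render_video(cfg)
    return cfg, frames, log


@pytest.fixture(scope="session")
def clean_scene_result(clean_scene, tmp_path_factory):
    cfg, frames, log = clean_scene
    win = log.window
    rc = RunConfig(output_dir=str(tmp_path_factory.mktemp("clean_run")),
                   window=(win.x0, win.y0, win.width, win.height),
                   classifier="rough")
    return run_pipeline(rc, frames)


@pytest.fixture(scope="session")
def small_crop_dataset():
    """60 crops per class: enough for unit-level classifier checks."""
    return simulate.make_crop_dataset(60, 60, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
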