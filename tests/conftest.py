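import numpy as np
import pytest

from orangesort import (
    SceneConfig,
    apply_detector_noise,
    render_ground_truth,
    sample_scene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(seed=3, n_fruits=30, frame_width=1200, occlusion_mix=None, **kwargs):
    """Scene + ground truth + noisy detections in one call."""
    if occlusion_mix is None:
        occlusion_mix = {"A": 1.0}
    config = SceneConfig(
        n_fruits=n_fruits,
        frame_width=frame_width,
        occlusion_mix=occlusion_mix,
        seed=seed,
        **kwargs,
    )
    scene = sample_scene(config)
    gt = render_ground_truth(scene)
    frames = apply_detector_noise(gt, config)
    return config, scene, gt, frames


def gt_track_boxes(gt_tracks):
    return {t.fruit_id: t.boxes for t in gt_tracks}
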