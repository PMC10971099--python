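import numpy as np
import pytest

from lamescan import detection, synthetic, tracking
from lamescan.depth_io import FRAME_COLS, FRAME_ROWS


@pytest.fixture(scope="session")
def sound_template():
    return synthetic.CowTemplate(peak_height_m=1.4, arch=0.1)


@pytest.fixture(scope="session")
def lame_template():
    return synthetic.CowTemplate(peak_height_m=1.05, arch=0.8)


@pytest.fixture(scope="session")
def noise_free_scene(sound_template):
    """One sound cow traversing a noise-free corridor."""
    config = synthetic.SceneConfig(
        n_frames=24,
        cows=[synthetic.CowPlacement(sound_template, entry_frame=0, lane_row=66)],
        noise_sd_m=0.0,
        seed=11,
    )
    frames, truth = synthetic.render_scene(config)
    return config, frames, truth


@pytest.fixture(scope="session")
def cow_and_human_scene(sound_template):
    """A cow sharing the corridor with a farmer-sized blob in a free lane."""
    config = synthetic.SceneConfig(
        n_frames=24,
        cows=[synthetic.CowPlacement(sound_template, entry_frame=0, lane_row=40)],
        humans=[synthetic.HumanPlacement(entry_frame=0, lane_row=115)],
        noise_sd_m=0.0,
        seed=5,
    )
    frames, truth = synthetic.render_scene(config)
    return config, frames, truth


def gt_footprint_region(frame, obj):
    """InstanceRegion whose mask is the exact ground-truth footprint."""
    mask = np.zeros((FRAME_ROWS, FRAME_COLS), dtype=bool)
    x0, y0, x1, y1 = obj.box
    mask[y0:y1, x0:x1] = True
    return detection.InstanceRegion.from_mask(frame, mask)


def run_reference_pipeline(frames, **tracker_kwargs):
    """detect -> noise filter -> track; returns (tracks, rejected regions)."""
    tracker = tracking.IouTracker(**tracker_kwargs)
    rejected = []
    for frame in frames:
        regions = detection.noise_filter(detection.detect_frame(frame))
        rejected.extend(r for r in regions if r.kind == "rejected")
        tracker.step(frame.index, [r for r in regions if r.kind == "cow"])
    return tracker.tracks, rejected
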