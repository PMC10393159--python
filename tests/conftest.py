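import numpy as np
import pytest

from nictrack import pipeline as pl
from nictrack import synth

UM_PER_PX = 3.75


@pytest.fixture(scope="session")
def small_fixture():
    """Two worms, 20 s at 5 fps on a 400x400 px arena, with ground truth."""
    arena = synth.ArenaSpec(frame_shape=(400, 400))
    worms = synth.default_worms(2)
    video, labels, truth, report = synth.simulate_video(arena, worms, 20.0,
                                                        fps=5.0, seed=7)
    return {"arena": arena, "worms": worms, "video": video, "labels": labels,
            "truth": truth, "report": report}


@pytest.fixture(scope="session")
def e2e_fixture():
    """Ten worms, 2 min at 5 fps on an 800x800 px arena (end-to-end runs)."""
    arena = synth.ArenaSpec(frame_shape=(800, 800))
    worms = synth.default_worms(10, crawl_speed_um_s=30.0)
    video, labels, truth, report = synth.simulate_video(arena, worms, 120.0,
                                                        fps=5.0, seed=11)
    return {"arena": arena, "worms": worms, "video": video, "labels": labels,
            "truth": truth, "report": report}


@pytest.fixture(scope="session")
def e2e_tracks(e2e_fixture):
    """Tracks recovered from perfect probability images of the e2e video."""
    labels = e2e_fixture["labels"]
    prob = np.where(labels > 0, np.uint8(255), np.uint8(0))
    config = pl.PipelineConfig(sigma_um=0.0, threshold=127)
    tracks = pl.build_tracks(prob, config)
    return tracks


def capsule_mask(length_px=120, width_px=10, shape=(60, 160), row=30, col0=20):
    """Horizontal rounded bar (stadium) mask."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = width_px / 2.0
    x0, x1 = col0 + r, col0 + length_px - r
    dx = np.clip(xx, x0, x1)
    mask |= (xx - dx) ** 2 + (yy - row) ** 2 <= r ** 2
    return mask
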