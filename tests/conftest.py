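"""Shared fixtures: synthetic scenes (generated once per session) and
factories for hand-built detections and fragments."""

from __future__ import annotations

import numpy as np
import pytest

from toxid.blob_detection import Detection
from toxid.fragment_tracking import Fragment, TrackingConfig, track_sequence
from toxid.synthetic_scenes import (
    SceneConfig,
    canonical_scene_configs,
    default_detection_config,
    generate_scene,
)


def make_detection(
    x=0.0, y=0.0, frame=0, size=100, hist=None, hu=None, t=None, fps=25.0
) -> Detection:
    """A detection with hand-set features for unit tests."""
    if hist is None:
        hist = np.ones(32, dtype=np.int64)
    if hu is None:
        hu = np.full(7, 0.5)
    return Detection(
        cm=(float(x), float(y)),
        size=int(size),
        hist=np.asarray(hist),
        hu=np.asarray(hu, dtype=np.float64),
        t=frame / fps if t is None else t,
        frame=int(frame),
        bbox=(int(y), int(x), int(y) + 1, int(x) + 1),
    )


def make_fragment(fid, detections, reason="end_of_video") -> Fragment:
    """A closed fragment from pre-built detections (no motion filter)."""
    frag = Fragment(id=fid, active=False, inactive_reason=reason)
    frag.detections = sorted(detections, key=lambda d: d.frame)
    return frag


def make_hist_fragment(fid, hists, start_frame=0, size=100, hu=None) -> Fragment:
    """A fragment whose samples carry the given histogram rows."""
    dets = [
        make_detection(frame=start_frame + k, size=size, hist=h, hu=hu)
        for k, h in enumerate(hists)
    ]
    return make_fragment(fid, dets)


@pytest.fixture(scope="session")
def single_scene():
    """One animal, no crossings: the null scene."""
    cfg = SceneConfig(n_animals=1, frame_size=(220, 220), n_frames=150, seed=101)
    frames, truth, log = generate_scene(cfg)
    return cfg, frames, truth, log


@pytest.fixture(scope="session")
def two_cross_scene():
    """The canonical 2-animal single-crossing scene."""
    cfg = canonical_scene_configs()["two_cross"]
    frames, truth, log = generate_scene(cfg)
    return cfg, frames, truth, log


@pytest.fixture(scope="session")
def two_cross_fragments(two_cross_scene):
    cfg, frames, truth, log = two_cross_scene
    fragments = track_sequence(frames, default_detection_config(cfg), TrackingConfig())
    return cfg, fragments, truth, log
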