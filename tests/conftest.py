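"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import pytest

from beecount.trackmodel import Detection, Track, VirtualFrame

# Representative points for the default 495 x 150 rectangle centred in a
# 640 x 480 image: the image centre is inside, the top-left corner outside.
INSIDE_POINT = (320.0, 240.0)
OUTSIDE_POINT = (30.0, 30.0)


@pytest.fixture
def vf() -> VirtualFrame:
    """Default counting geometry: 495 x 150 centred in 640 x 480 at 240 fps."""
    return VirtualFrame()


def make_state_track(
    states: str,
    frames: list[int] | None = None,
    track_id: int = 1,
) -> Track:
    """Build a track from an inside/outside state string like ``'oioo'``.

    'i' places the centre at the image centre (inside the default
    rectangle), 'o' at the top-left corner (outside).  ``frames`` defaults
    to consecutive integers.
    """
    if frames is None:
        frames = list(range(len(states)))
    assert len(frames) == len(states)
    dets = []
    for f, s in zip(frames, states):
        x, y = INSIDE_POINT if s == "i" else OUTSIDE_POINT
        dets.append(
            Detection(frame_index=f, track_id=track_id, center_x=x, center_y=y,
                      width=20, height=20)
        )
    return Track(track_id=track_id, detections=dets)
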