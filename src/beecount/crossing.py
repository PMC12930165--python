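"""Virtual-frame geometry: inside/outside tests, crossings, and episodes.

A *crossing* is a transition of a track's box centre between outside and
inside the counting rectangle, observed between two consecutive detections
and stamped with the later detection's frame (the first frame at which the
new state holds).  No interpolation is done across detection gaps: however
many frames separate two consecutive detections, at most one transition is
recorded between them.

An *episode* is a maximal run of one track's crossings in which every
inter-crossing gap is strictly below the gap threshold.  A gap of at least
the threshold (one second by default — 240 frames at 240 fps) starts a new
episode.  The parity rule that decides nest entries and exits is evaluated
per episode, which is what lets a single track ID carry two genuinely
separate visits (e.g. after a tracker identity merge) and still be counted
twice.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .trackmodel import Track, VirtualFrame

__all__ = [
    "Direction",
    "RegionState",
    "Crossing",
    "Episode",
    "is_inside",
    "detect_crossings",
    "split_episodes",
    "track_episodes",
]


class Direction(str, enum.Enum):
    INWARD = "inward"
    OUTWARD = "outward"


class RegionState(str, enum.Enum):
    INSIDE = "inside"
    OUTSIDE = "outside"

    def flipped(self) -> "RegionState":
        return RegionState.OUTSIDE if self is RegionState.INSIDE else RegionState.INSIDE


@dataclass(frozen=True)
class Crossing:
    """One inside<->outside boundary transition of a track."""

    track_id: int
    frame_index: int
    direction: Direction


@dataclass(frozen=True)
class Episode:
    """A maximal run of one track's crossings separated by sub-threshold gaps.

    Directions alternate (forced by the state-transition definition), so
    ``end_state == start_state`` exactly when the crossing count is even.
    """

    track_id: int
    crossings: tuple[Crossing, ...]
    start_state: RegionState

    def __post_init__(self) -> None:
        if not self.crossings:
            raise ValueError("episode must contain at least one crossing")

    @property
    def end_state(self) -> RegionState:
        return self.start_state if len(self.crossings) % 2 == 0 else self.start_state.flipped()

    @property
    def first_frame(self) -> int:
        return self.crossings[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.crossings[-1].frame_index

    def __len__(self) -> int:
        return len(self.crossings)


def is_inside(point: tuple[float, float], vf: VirtualFrame) -> bool:
    """Half-open rectangle membership: x_min <= x < x_max and y_min <= y < y_max."""
    x, y = point
    return vf.x_min <= x < vf.x_max and vf.y_min <= y < vf.y_max


def detect_crossings(track: Track, vf: VirtualFrame) -> list[Crossing]:
    """List every boundary transition along a track, in frame order.

    One crossing is emitted per change of :func:`is_inside` between
    consecutive detections, timestamped with the later detection's frame.
    A single-detection track yields no crossings.  The parity of the result
    always equals whether the first and last centres are on opposite sides
    of the boundary.
    """
    crossings: list[Crossing] = []
    states = [is_inside(d.center, vf) for d in track]
    for prev, (curr, det) in zip(states, zip(states[1:], track.detections[1:])):
        if curr != prev:
            crossings.append(
                Crossing(
                    track_id=track.track_id,
                    frame_index=det.frame_index,
                    direction=Direction.INWARD if curr else Direction.OUTWARD,
                )
            )
    return crossings


def split_episodes(
    crossings: list[Crossing],
    gap_threshold_frames: float,
    start_state: RegionState,
) -> list[Episode]:
    """Group a track's crossings into episodes at the gap threshold.

    A new episode begins at every crossing whose frame gap from the previous
    crossing is >= ``gap_threshold_frames``; within an episode all gaps are
    below the threshold.  ``start_state`` is the track's state just before
    its first crossing; each subsequent episode's start state follows from
    the crossings before it.  ``math.inf`` is an accepted threshold (one
    episode for the whole track).

    Raises ``ValueError`` on unsorted input or mixed track IDs.
    """
    if gap_threshold_frames <= 0:
        raise ValueError(f"gap_threshold_frames must be > 0, got {gap_threshold_frames}")
    if not crossings:
        return []
    frames = [c.frame_index for c in crossings]
    if any(b < a for a, b in zip(frames, frames[1:])):
        raise ValueError("crossings must be sorted by frame_index")
    if len({c.track_id for c in crossings}) > 1:
        raise ValueError("crossings must all belong to one track")

    episodes: list[Episode] = []
    state = start_state
    group: list[Crossing] = [crossings[0]]
    for prev, curr in zip(crossings, crossings[1:]):
        if curr.frame_index - prev.frame_index >= gap_threshold_frames:
            episodes.append(Episode(group[0].track_id, tuple(group), state))
            state = episodes[-1].end_state
            group = [curr]
        else:
            group.append(curr)
    episodes.append(Episode(group[0].track_id, tuple(group), state))
    return episodes


def track_episodes(
    track: Track, vf: VirtualFrame, gap_threshold_frames: float = math.inf
) -> list[Episode]:
    """Convenience: crossings of a track split into episodes in one call."""
    crossings = detect_crossings(track, vf)
    if not crossings:
        return []
    start = (
        RegionState.INSIDE
        if is_inside(track.detections[0].center, vf)
        else RegionState.OUTSIDE
    )
    return split_episodes(crossings, gap_threshold_frames, start)
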