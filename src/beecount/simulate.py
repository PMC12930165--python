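"""Synthetic top-view bee trajectories with ground-truth nest events.

No real greenhouse video ships with this package, so every downstream module
is exercised on simulated tracks.  The generator emulates what the top-view
camera sees at 240 fps over a 640 x 480 image with the 495 x 150 counting
rectangle centred in it: a bee is a bounding-box centre moving along a
piecewise-linear waypoint path at a lognormal per-track speed, with optional
Gaussian centre jitter and per-detection dropout, and the tracker failure
modes — identity switches (one bee split over two IDs) and identity merges
(two bees sharing one ID) — applied as corruption operators.

Supported flight patterns (tags):

``A``            approach from the greenhouse, terminate inside the
                 rectangle (descended into the nest) — truth: one entry
``B``            dip into the rectangle and turn back out — truth: none
``C``            emerge inside the rectangle, fly off — truth: one exit
``D``            poke out of the rectangle and return inside — truth: none
``pass_over``    fly straight across the rectangle — truth: none
``multi_turn_k`` make k boundary transitions with sub-threshold dwells;
                 odd k ends inside (one entry), even k ends outside (none)

Ground-truth events are computed from the noise-free path by construction,
before jitter and dropout are applied, and stand in for the visual
observations a human scorer would make.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .crossing import is_inside
from .trackmodel import (
    Detection,
    EventKind,
    EventSource,
    NestEvent,
    Track,
    VirtualFrame,
)

__all__ = [
    "SimConfig",
    "LabelledTrack",
    "SimDataset",
    "DEFAULT_PATTERN_WEIGHTS",
    "sample_track",
    "corrupt_id_switch",
    "corrupt_id_merge",
    "generate_dataset",
]

# Mixture reflecting that straight passes are rare and turn-backs common
# around a nest entrance; entries and exits roughly balance.
DEFAULT_PATTERN_WEIGHTS: dict[str, float] = {
    "A": 0.3,
    "B": 0.2,
    "C": 0.3,
    "D": 0.1,
    "pass_over": 0.1,
}

_MULTI_TURN_RE = re.compile(r"^multi_turn_(\d+)$")

# Distance in pixels kept between waypoints and the rectangle boundary so
# that 1-px observation jitter cannot flip the inside/outside state while a
# bee dwells.
_MARGIN = 20.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the stated simulation world.

    dwell_frames / long_dwell_frames are uniform integer ranges (inclusive)
    for the time a bee lingers at a turn-back point; the defaults keep
    ordinary dwells well under the one-second grouping threshold while
    ``long_dwell_prob`` lingerers exceed it (the documented false-positive
    mode of the parity method).
    """

    n_tracks: int = 100
    pattern_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_WEIGHTS)
    )
    fps: float = 240.0
    speed_median: float = 3.0       # px/frame, lognormal median
    speed_sigma: float = 0.4        # lognormal shape
    jitter_sd: float = 1.0          # px, Gaussian noise on observed centres
    dropout_prob: float = 0.0       # per-detection omission
    id_switch_prob: float = 0.0     # per-track probability of an ID switch
    id_merge_prob: float = 0.0      # per-track probability of merging with the next track
    dwell_frames: tuple[int, int] = (24, 120)        # 0.1-0.5 s at 240 fps
    long_dwell_prob: float = 0.0
    long_dwell_frames: tuple[int, int] = (264, 480)  # 1.1-2 s at 240 fps
    merge_gap_seconds: tuple[float, float] = (0.25, 2.0)
    box_size: float = 20.0          # nominal bounding-box side, +-10% jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError(f"n_tracks must be >= 1, got {self.n_tracks}")
        if not self.pattern_weights:
            raise ValueError("pattern_weights must be non-empty")
        for tag, w in self.pattern_weights.items():
            _parse_pattern(tag)
            if w < 0:
                raise ValueError(f"negative weight for pattern {tag!r}")
        total = sum(self.pattern_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern weights must sum to 1, got {total}")
        for name in ("dropout_prob", "id_switch_prob", "id_merge_prob", "long_dwell_prob"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {p}")
        if self.fps <= 0 or self.speed_median <= 0 or self.jitter_sd < 0:
            raise ValueError("fps and speed_median must be > 0, jitter_sd >= 0")

    def virtual_frame(self) -> VirtualFrame:
        return VirtualFrame(fps=self.fps)


@dataclass
class LabelledTrack:
    """A simulated track with its ground-truth events and lineage.

    ``root_id`` is the identity the track had before any corruption; the
    evaluator uses it to compare events across ID switches fairly.
    """

    track: Track
    true_events: list[NestEvent]
    pattern: str
    root_id: int = 0
    corruption: str | None = None

    def __post_init__(self) -> None:
        if self.root_id == 0:
            self.root_id = self.track.track_id


@dataclass
class SimDataset:
    """Output of :func:`generate_dataset`."""

    tracks: list[Track]
    truth_events: list[NestEvent]
    lineage: dict[int, int]         # track_id -> root_id
    labelled: list[LabelledTrack]
    config: SimConfig

    def __iter__(self):
        # allow `tracks, truth = generate_dataset(cfg)` style unpacking
        return iter((self.tracks, self.truth_events))


def _parse_pattern(tag: str) -> int | None:
    """Return k for multi_turn_k tags, None for the base patterns."""
    if tag in ("A", "B", "C", "D", "pass_over"):
        return None
    m = _MULTI_TURN_RE.match(tag)
    if m and int(m.group(1)) >= 1:
        return int(m.group(1))
    raise ValueError(f"unknown pattern tag {tag!r}")


# ---------------------------------------------------------------------------
# waypoint construction
# ---------------------------------------------------------------------------

def _outside_point(vf: VirtualFrame, rng: np.random.Generator) -> np.ndarray:
    """A point in the image at least _MARGIN outside the rectangle."""
    while True:
        p = rng.uniform([1.0, 1.0], [vf.image_width - 1, vf.image_height - 1])
        if not (
            vf.x_min - _MARGIN <= p[0] < vf.x_max + _MARGIN
            and vf.y_min - _MARGIN <= p[1] < vf.y_max + _MARGIN
        ):
            return p


def _inside_point(vf: VirtualFrame, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(
        [vf.x_min + _MARGIN, vf.y_min + _MARGIN],
        [vf.x_max - _MARGIN, vf.y_max - _MARGIN],
    )


def _entry_point(vf: VirtualFrame, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """First intersection of segment p -> q with the rectangle (p outside, q inside)."""
    d = q - p
    t0 = 0.0
    for lo, hi, pc, dc in (
        (vf.x_min, vf.x_max, p[0], d[0]),
        (vf.y_min, vf.y_max, p[1], d[1]),
    ):
        if dc != 0:
            ta, tb = (lo - pc) / dc, (hi - pc) / dc
            t0 = max(t0, min(ta, tb))
    return p + t0 * d


def _shallow_inside_point(
    vf: VirtualFrame, rng: np.random.Generator, from_point: np.ndarray
) -> np.ndarray:
    """A dip point just inside the rectangle, near where the path enters.

    Turn-backs are shallow by construction: the bee pokes 20-40 px past the
    boundary and turns around, keeping the time between its two crossings
    (transit in + dwell + transit out) below the one-second grouping
    threshold — the stated behaviour of a bee that approaches but does not
    enter the nest.
    """
    cx, cy = vf.center
    target = np.array(
        [cx + rng.uniform(-50, 50), cy + rng.uniform(-30, 30)]
    )
    d = target - from_point
    d = d / np.linalg.norm(d)
    q = _entry_point(vf, from_point, target) + d * rng.uniform(_MARGIN, 2 * _MARGIN)
    return np.array(
        [
            min(max(q[0], vf.x_min + 10), vf.x_max - 10),
            min(max(q[1], vf.y_min + 10), vf.y_max - 10),
        ]
    )


def _shallow_outside_point(
    vf: VirtualFrame, rng: np.random.Generator, from_point: np.ndarray
) -> np.ndarray:
    """A poke point just outside the rectangle, near where the path leaves it.

    The direction points away from the rectangle centre (with angular noise)
    so the bee exits through the nearby boundary rather than transiting the
    whole counting region.
    """
    cx, cy = vf.center
    base = math.atan2(from_point[1] - cy, from_point[0] - cx)
    theta = base + rng.uniform(-0.6, 0.6)
    d = np.array([math.cos(theta), math.sin(theta)])
    t = math.inf
    for lo, hi, pc, dc in (
        (vf.x_min, vf.x_max, from_point[0], d[0]),
        (vf.y_min, vf.y_max, from_point[1], d[1]),
    ):
        if dc > 0:
            t = min(t, (hi - pc) / dc)
        elif dc < 0:
            t = min(t, (lo - pc) / dc)
    p = from_point + (t + rng.uniform(10, 2 * _MARGIN)) * d
    x = min(max(p[0], 1.0), vf.image_width - 1)
    y = min(max(p[1], 1.0), vf.image_height - 1)
    return np.array([x, y])


def _draw_dwell(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = (
        cfg.long_dwell_frames
        if (cfg.long_dwell_prob > 0 and rng.random() < cfg.long_dwell_prob)
        else cfg.dwell_frames
    )
    return int(rng.integers(lo, hi + 1))


def _waypoints(pattern: str, vf: VirtualFrame, cfg: SimConfig,
               rng: np.random.Generator) -> tuple[list[np.ndarray], list[int]]:
    """Waypoint positions and the dwell (frames) spent at each."""
    k = _parse_pattern(pattern)
    short = lambda: int(rng.integers(*cfg.dwell_frames))
    if pattern == "A":
        return [_outside_point(vf, rng), _inside_point(vf, rng)], [0, short() // 4]
    if pattern == "B":
        # a turn-back leaves roughly the way it came in
        start = _outside_point(vf, rng)
        while True:
            back = start + rng.uniform(-30, 30, size=2)
            back[0] = min(max(back[0], 1.0), vf.image_width - 1)
            back[1] = min(max(back[1], 1.0), vf.image_height - 1)
            if not (
                vf.x_min - 10 <= back[0] < vf.x_max + 10
                and vf.y_min - 10 <= back[1] < vf.y_max + 10
            ):
                break
        return (
            [start, _shallow_inside_point(vf, rng, start), back],
            [0, _draw_dwell(cfg, rng), 0],
        )
    if pattern == "C":
        return [_inside_point(vf, rng), _outside_point(vf, rng)], [short() // 4, 0]
    if pattern == "D":
        start = _inside_point(vf, rng)
        return (
            [start, _shallow_outside_point(vf, rng, start), _inside_point(vf, rng)],
            [short() // 4, _draw_dwell(cfg, rng), short() // 4],
        )
    if pattern == "pass_over":
        # straight flight across the rectangle: opposite horizontal sides
        y0 = rng.uniform(vf.y_min + _MARGIN, vf.y_max - _MARGIN)
        y1 = rng.uniform(vf.y_min + _MARGIN, vf.y_max - _MARGIN)
        left = np.array([rng.uniform(1.0, vf.x_min - _MARGIN), y0])
        right = np.array([rng.uniform(vf.x_max + _MARGIN, vf.image_width - 1), y1])
        return ([left, right] if rng.random() < 0.5 else [right, left]), [0, 0]
    # multi_turn_k: k transitions, alternating outside/inside, starting outside;
    # dips are shallow so inter-crossing gaps stay below the threshold
    pts = [_outside_point(vf, rng)]
    dwells = [0]
    for i in range(k):
        inside = i % 2 == 0
        pts.append(
            _shallow_inside_point(vf, rng, pts[-1])
            if inside
            else _shallow_outside_point(vf, rng, pts[-1])
        )
        dwells.append(short())
    return pts, dwells


# ---------------------------------------------------------------------------
# rendering and labelling
# ---------------------------------------------------------------------------

def _render_path(
    waypoints: list[np.ndarray], dwells: list[int], speed: float
) -> np.ndarray:
    """Clean per-frame positions along a piecewise-linear waypoint path."""
    positions: list[np.ndarray] = [waypoints[0]]
    positions.extend([waypoints[0]] * dwells[0])
    for a, b, dwell in zip(waypoints, waypoints[1:], dwells[1:]):
        dist = float(np.linalg.norm(b - a))
        n = max(1, int(math.ceil(dist / speed)))
        ts = np.arange(1, n + 1) / n
        positions.extend(a + t * (b - a) for t in ts)
        positions.extend([b] * dwell)
    return np.asarray(positions)


def _truth_from_path(
    path: np.ndarray, vf: VirtualFrame, track_id: int, start_frame: int
) -> list[NestEvent]:
    """Ground-truth events implied by the noise-free path's start/end states.

    The path's boundary-transition parity decides whether a nest event
    occurred; direction follows from which side the path starts on.  The
    event frame is the last transition's frame.
    """
    states = [is_inside((p[0], p[1]), vf) for p in path]
    transition_frames = [
        start_frame + i + 1 for i, (a, b) in enumerate(zip(states, states[1:])) if a != b
    ]
    if len(transition_frames) % 2 == 0:
        return []
    kind = EventKind.ENTRY if not states[0] else EventKind.EXIT
    return [
        NestEvent(
            frame_index=transition_frames[-1],
            track_id=track_id,
            kind=kind,
            source=EventSource.TRUTH,
        )
    ]


def sample_track(
    pattern: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    track_id: int = 1,
    start_frame: int = 0,
) -> LabelledTrack:
    """Draw one labelled track of the given flight pattern.

    The ground truth is fixed by the clean path before jitter and dropout
    are applied; heavy dropout can therefore make the observed track miss
    events the truth asserts, which is exactly the failure the evaluation
    is meant to expose.
    """
    vf = cfg.virtual_frame()
    waypoints, dwells = _waypoints(pattern, vf, cfg, rng)
    # lognormal flight speed, clipped: hovering slower than 1.5 px/frame or
    # darting faster than 12 px/frame is outside the modelled behaviour.
    # Straight through-flights are brisk (floor 2.5 px/frame): a transit of
    # the full rectangle then stays under the one-second threshold.
    floor = 2.5 if pattern == "pass_over" else 1.5
    speed = float(
        np.clip(rng.lognormal(math.log(cfg.speed_median), cfg.speed_sigma), floor, 12.0)
    )
    path = _render_path(waypoints, dwells, speed)
    truth = _truth_from_path(path, vf, track_id, start_frame)

    observed = path + rng.normal(0.0, cfg.jitter_sd, size=path.shape) \
        if cfg.jitter_sd > 0 else path
    keep = (
        rng.random(len(path)) >= cfg.dropout_prob
        if cfg.dropout_prob > 0
        else np.ones(len(path), dtype=bool)
    )
    sizes = cfg.box_size * rng.uniform(0.9, 1.1, size=(len(path), 2))
    confs = rng.uniform(0.6, 1.0, size=len(path))

    detections = [
        Detection(
            frame_index=start_frame + i,
            track_id=track_id,
            center_x=float(observed[i, 0]),
            center_y=float(observed[i, 1]),
            width=float(sizes[i, 0]),
            height=float(sizes[i, 1]),
            confidence=round(float(confs[i]), 3),
        )
        for i in range(len(path))
        if keep[i]
    ]
    if not detections:
        raise ValueError(
            f"track {track_id}: all detections dropped (dropout_prob={cfg.dropout_prob})"
        )
    return LabelledTrack(
        track=Track(track_id=track_id, detections=detections),
        true_events=truth,
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def corrupt_id_switch(
    lt: LabelledTrack, rng: np.random.Generator, new_id: int | None = None
) -> list[LabelledTrack]:
    """Split a track at a random interior frame, giving the tail a fresh ID.

    Models the tracker losing a bee and re-acquiring it under a new
    identity.  Truth events are re-attributed to the half that contains
    their frame.  Tracks with fewer than 4 detections are returned
    unchanged (flagged via ``corruption=None``).
    """
    dets = lt.track.detections
    if len(dets) < 4:
        return [lt]
    if new_id is None:
        new_id = lt.track.track_id + 1_000_000
    split = int(rng.integers(2, len(dets) - 1))  # both halves get >= 2 detections
    head = dets[:split]
    tail = [replace(d, track_id=new_id) for d in dets[split:]]
    cut_frame = tail[0].frame_index

    def _reattribute(e: NestEvent) -> NestEvent:
        if e.frame_index < cut_frame:
            return e
        return replace(e, track_id=new_id)

    head_events = [e for e in lt.true_events if e.frame_index < cut_frame]
    tail_events = [_reattribute(e) for e in lt.true_events if e.frame_index >= cut_frame]
    return [
        LabelledTrack(
            track=Track(lt.track.track_id, head),
            true_events=head_events,
            pattern=lt.pattern,
            root_id=lt.root_id,
            corruption="id_switch",
        ),
        LabelledTrack(
            track=Track(new_id, tail),
            true_events=tail_events,
            pattern=lt.pattern,
            root_id=lt.root_id,
            corruption="id_switch",
        ),
    ]


def corrupt_id_merge(
    lt1: LabelledTrack, lt2: LabelledTrack, gap_frames: int
) -> LabelledTrack:
    """Concatenate two bees' tracks under the first one's ID.

    Models the tracker handing one identity to a second bee.  ``lt2`` is
    re-stamped to begin ``gap_frames`` after ``lt1`` ends; truth events
    follow the shift and all carry the merged ID.  When the gap is below
    the grouping threshold the two bees' crossings land in one episode and
    the parity rule silently cancels them — the documented false-negative
    mode.
    """
    if gap_frames < 1:
        raise ValueError(f"gap_frames must be >= 1, got {gap_frames}")
    merged_id = lt1.track.track_id
    offset = lt1.track.last_frame + gap_frames - lt2.track.first_frame
    shifted = [
        replace(d, frame_index=d.frame_index + offset, track_id=merged_id)
        for d in lt2.track.detections
    ]
    dets = lt1.track.detections + shifted
    events = list(lt1.true_events) + [
        replace(e, frame_index=e.frame_index + offset, track_id=merged_id)
        for e in lt2.true_events
    ]
    return LabelledTrack(
        track=Track(merged_id, dets),
        true_events=events,
        pattern=f"{lt1.pattern}+{lt2.pattern}",
        root_id=lt1.root_id,
        corruption="id_merge",
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SimConfig) -> SimDataset:
    """Draw a full labelled dataset: tracks, truth events, and ID lineage.

    Tracks are laid out sequentially in time with random inter-track gaps,
    patterns drawn by ``pattern_weights``; merge then switch corruptions are
    applied with their per-track probabilities.  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.dropout_prob > 0.9:
        warnings.warn(
            f"dropout_prob={cfg.dropout_prob}: tracks may lose most or all "
            "detections", stacklevel=2,
        )
    tags = sorted(cfg.pattern_weights)
    weights = np.array([cfg.pattern_weights[t] for t in tags])
    weights = weights / weights.sum()

    base: list[LabelledTrack] = []
    frame_cursor = 0
    for i in range(cfg.n_tracks):
        pattern = tags[int(rng.choice(len(tags), p=weights))]
        try:
            lt = sample_track(pattern, cfg, rng, track_id=i + 1, start_frame=frame_cursor)
        except ValueError:
            continue  # fully dropped-out track: the bee was never seen
        base.append(lt)
        frame_cursor = lt.track.last_frame + int(rng.integers(240, 1200))

    merged: list[LabelledTrack] = []
    i = 0
    while i < len(base):
        if cfg.id_merge_prob > 0 and i + 1 < len(base) and rng.random() < cfg.id_merge_prob:
            lo, hi = cfg.merge_gap_seconds
            gap = max(1, int(round(rng.uniform(lo, hi) * cfg.fps)))
            merged.append(corrupt_id_merge(base[i], base[i + 1], gap))
            i += 2
        else:
            merged.append(base[i])
            i += 1

    labelled: list[LabelledTrack] = []
    next_fresh = cfg.n_tracks + 1
    for lt in merged:
        if cfg.id_switch_prob > 0 and rng.random() < cfg.id_switch_prob:
            parts = corrupt_id_switch(lt, rng, new_id=next_fresh)
            if len(parts) == 2:
                next_fresh += 1
            labelled.extend(parts)
        else:
            labelled.append(lt)

    tracks = [lt.track for lt in labelled]
    truth = sorted(
        (e for lt in labelled for e in lt.true_events),
        key=lambda e: (e.frame_index, e.track_id),
    )
    lineage = {lt.track.track_id: lt.root_id for lt in labelled}
    return SimDataset(tracks=tracks, truth_events=truth, lineage=lineage,
                      labelled=labelled, config=cfg)
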