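"""Core data types for tracked bee detections and the virtual counting frame.

A top-view camera watches the entrance of a bumblebee nest box.  A detector
plus tracker turns each video frame into zero or more bounding boxes with
persistent track IDs; this module holds those observations (:class:`Detection`,
:class:`Track`), the rectangular counting region placed in front of the
entrance (:class:`VirtualFrame`), and the entry/exit events the counting
algorithms predict or that ground truth asserts (:class:`NestEvent`).

Coordinates are 0-based pixels, origin at the top-left corner, x rightward,
y downward.  Rectangle membership is half-open, ``[x_min, x_max) x
[y_min, y_max)``, so a point exactly on the right or bottom edge is outside.
Fractional coordinates are allowed: centring a 495-pixel-wide rectangle in a
640-pixel image puts its edges on half pixels.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Detection",
    "Track",
    "VirtualFrame",
    "NestEvent",
    "EventKind",
    "EventSource",
    "CountingParams",
    "TrackValidationError",
    "ConfigError",
    "DEFAULT_IMAGE_WIDTH",
    "DEFAULT_IMAGE_HEIGHT",
    "DEFAULT_FRAME_WIDTH",
    "DEFAULT_FRAME_HEIGHT",
    "DEFAULT_FPS",
    "DEFAULT_GAP_THRESHOLD_SECONDS",
    "read_tracks",
    "write_tracks",
    "read_events",
    "write_events",
    "load_config",
]

# Defaults mirror the monitoring setup the package models: a 640 x 480 video
# recorded at 240 fps with a 495 x 150 pixel counting rectangle centred in
# the image, and a one-second grouping threshold between boundary crossings.
DEFAULT_IMAGE_WIDTH = 640
DEFAULT_IMAGE_HEIGHT = 480
DEFAULT_FRAME_WIDTH = 495
DEFAULT_FRAME_HEIGHT = 150
DEFAULT_FPS = 240.0
DEFAULT_GAP_THRESHOLD_SECONDS = 1.0

MOT_COLUMNS = [
    "frame", "id", "bb_left", "bb_top", "bb_width", "bb_height",
    "conf", "x", "y", "z",
]


class TrackValidationError(ValueError):
    """A track file or track object violates a structural invariant."""


class ConfigError(ValueError):
    """A configuration value violates a geometric or range invariant."""


class EventKind(str, enum.Enum):
    ENTRY = "entry"
    EXIT = "exit"


class EventSource(str, enum.Enum):
    PREDICTED = "predicted"
    TRUTH = "truth"


@dataclass(frozen=True)
class Detection:
    """One tracked bounding box: a bee seen in one video frame.

    The position used for all counting geometry is the box centre
    (``center_x``, ``center_y``); it is robust to box-size jitter.
    """

    frame_index: int
    track_id: int
    center_x: float
    center_y: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise TrackValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.track_id < 1:
            raise TrackValidationError(f"track_id must be >= 1, got {self.track_id}")
        if self.width <= 0 or self.height <= 0:
            raise TrackValidationError(
                f"box size must be positive, got {self.width} x {self.height}"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise TrackValidationError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_x, self.center_y)


@dataclass
class Track:
    """The ordered detections sharing one tracker-assigned ID.

    Frame indices are strictly increasing; gaps are allowed (detection
    dropout).  A track must be non-empty.
    """

    track_id: int
    detections: list[Detection]

    def __post_init__(self) -> None:
        if not self.detections:
            raise TrackValidationError(f"track {self.track_id} has no detections")
        for d in self.detections:
            if d.track_id != self.track_id:
                raise TrackValidationError(
                    f"detection with id {d.track_id} inside track {self.track_id}"
                )
        frames = [d.frame_index for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise TrackValidationError(
                f"track {self.track_id}: frame indices not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    @property
    def first_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame_index


@dataclass(frozen=True)
class VirtualFrame:
    """The rectangular counting region in image coordinates.

    The rectangle models the cross-section of a counting volume placed over
    the nest-box entrance as seen from above.  A track that terminates inside
    the rectangle is taken to have descended into the nest entrance; a track
    that begins inside is taken to have emerged from it.

    Membership is half-open: ``x_min <= x < x_max`` and ``y_min <= y < y_max``.
    """

    x_min: float = (DEFAULT_IMAGE_WIDTH - DEFAULT_FRAME_WIDTH) / 2
    y_min: float = (DEFAULT_IMAGE_HEIGHT - DEFAULT_FRAME_HEIGHT) / 2
    x_max: float = (DEFAULT_IMAGE_WIDTH + DEFAULT_FRAME_WIDTH) / 2
    y_max: float = (DEFAULT_IMAGE_HEIGHT + DEFAULT_FRAME_HEIGHT) / 2
    image_width: float = DEFAULT_IMAGE_WIDTH
    image_height: float = DEFAULT_IMAGE_HEIGHT
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max <= self.image_width):
            raise ConfigError(
                "frame_x_min/frame_x_max: need 0 <= x_min < x_max <= image_width, "
                f"got [{self.x_min}, {self.x_max}) in width {self.image_width}"
            )
        if not (0 <= self.y_min < self.y_max <= self.image_height):
            raise ConfigError(
                "frame_y_min/frame_y_max: need 0 <= y_min < y_max <= image_height, "
                f"got [{self.y_min}, {self.y_max}) in height {self.image_height}"
            )
        if self.fps <= 0:
            raise ConfigError(f"fps: must be > 0, got {self.fps}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)

    def seconds_to_frames(self, seconds: float) -> int:
        """Convert a time threshold in seconds to a whole number of frames."""
        return max(1, int(round(seconds * self.fps)))


@dataclass(frozen=True, order=True)
class NestEvent:
    """A nest-box entry or exit attributed to a track at a frame.

    ``frame_index`` is the frame of the decisive boundary crossing.  Events
    come either from a counting method (``source=predicted``) or from ground
    truth (``source=truth``; visual observation on real video, simulator
    labels here).
    """

    frame_index: int
    track_id: int
    kind: EventKind
    source: EventSource = EventSource.PREDICTED


@dataclass(frozen=True)
class CountingParams:
    """Algorithm parameters resolved from configuration."""

    gap_threshold_seconds: float = DEFAULT_GAP_THRESHOLD_SECONDS
    method: str = "parity"

    def __post_init__(self) -> None:
        if self.gap_threshold_seconds <= 0:
            raise ConfigError(
                f"gap_threshold_seconds: must be > 0, got {self.gap_threshold_seconds}"
            )
        if self.method not in ("parity", "yolo-only"):
            raise ConfigError(f"method: must be 'parity' or 'yolo-only', got {self.method!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path, fps: float = DEFAULT_FPS) -> list[Track]:
    """Read tracked detections from a MOT-challenge-style CSV file.

    Expected columns (no header):
    ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` — the last
    three are ignored and may be -1.  The bee position is taken as the box
    centre ``(bb_left + bb_width/2, bb_top + bb_height/2)``.

    Returns one :class:`Track` per distinct ID, detections sorted by frame,
    tracks sorted by ID.  An empty file yields an empty list.

    Raises
    ------
    TrackValidationError
        On a malformed row (with its line number) or a duplicate
        (frame, id) pair.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 6:
        raise TrackValidationError(
            f"{path}: expected >= 6 MOT columns, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(MOT_COLUMNS)]
    df.columns = MOT_COLUMNS[: df.shape[1]]
    if "conf" not in df.columns:
        df["conf"] = 1.0

    dupes = df.duplicated(subset=["frame", "id"], keep=False)
    if dupes.any():
        first = df.index[dupes][0]
        raise TrackValidationError(
            f"{path}: duplicate (frame, id) pair at line {first + 1}: "
            f"frame={df.at[first, 'frame']}, id={df.at[first, 'id']}"
        )

    tracks: list[Track] = []
    for track_id, group in df.groupby("id", sort=True):
        group = group.sort_values("frame")
        detections = []
        for row in group.itertuples(index=True):
            try:
                conf = float(row.conf)
                if conf < 0:  # MOT files use -1 for "no confidence"
                    conf = 1.0
                detections.append(
                    Detection(
                        frame_index=int(row.frame),
                        track_id=int(row.id),
                        center_x=float(row.bb_left) + float(row.bb_width) / 2,
                        center_y=float(row.bb_top) + float(row.bb_height) / 2,
                        width=float(row.bb_width),
                        height=float(row.bb_height),
                        confidence=conf,
                    )
                )
            except (TypeError, ValueError, TrackValidationError) as exc:
                raise TrackValidationError(f"{path}: line {row.Index + 1}: {exc}") from exc
        tracks.append(Track(track_id=int(track_id), detections=detections))
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks as MOT-challenge CSV (headerless), sorted by (frame, id)."""
    rows = []
    for track in tracks:
        for d in track:
            rows.append(
                (
                    d.frame_index, d.track_id,
                    d.center_x - d.width / 2, d.center_y - d.height / 2,
                    d.width, d.height, d.confidence, -1, -1, -1,
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=MOT_COLUMNS)
    df.to_csv(path, header=False, index=False, float_format="%.3f")


def write_events(events: Iterable[NestEvent], path: str | Path) -> None:
    """Write nest events as CSV with header ``track_id,kind,frame_index,source``.

    Rows are sorted by (frame_index, track_id); read-back round-trips.
    """
    rows = sorted(events, key=lambda e: (e.frame_index, e.track_id))
    df = pd.DataFrame(
        {
            "track_id": [e.track_id for e in rows],
            "kind": [e.kind.value for e in rows],
            "frame_index": [e.frame_index for e in rows],
            "source": [e.source.value for e in rows],
        }
    )
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[NestEvent]:
    """Read back a nest-event CSV written by :func:`write_events`."""
    df = pd.read_csv(path)
    return [
        NestEvent(
            frame_index=int(r.frame_index),
            track_id=int(r.track_id),
            kind=EventKind(r.kind),
            source=EventSource(r.source),
        )
        for r in df.itertuples()
    ]


def check_in_image(detections: Iterable[Detection], vf: VirtualFrame) -> None:
    """Warn (do not reject) about centres outside the declared image bounds.

    Detectors can emit boxes straddling the border, so this is advisory.
    """
    n = sum(
        1
        for d in detections
        if not (0 <= d.center_x < vf.image_width and 0 <= d.center_y < vf.image_height)
    )
    if n:
        warnings.warn(f"{n} detection centre(s) outside the {vf.image_width}x"
                      f"{vf.image_height} image bounds", stacklevel=2)


_CONFIG_KEYS = {
    "image_width", "image_height",
    "frame_x_min", "frame_y_min", "frame_x_max", "frame_y_max",
    "fps", "gap_threshold_seconds", "method",
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, object] | None = None,
                ) -> tuple[VirtualFrame, CountingParams]:
    """Load a YAML/JSON configuration, falling back to built-in defaults.

    Missing keys default to the standard monitoring geometry: 640 x 480
    image, 495 x 150 rectangle centred in it, 240 fps, 1.0 s gap threshold,
    parity method.  Unknown keys raise :class:`ConfigError`; so does
    invariant-violating geometry, naming the offending key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None  # YAML is a JSON superset
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

    iw = float(data.get("image_width", DEFAULT_IMAGE_WIDTH))
    ih = float(data.get("image_height", DEFAULT_IMAGE_HEIGHT))
    # Default rectangle: centred, standard size (scaled position only when the
    # image size is customised but the rectangle is not).
    x_min = float(data.get("frame_x_min", (iw - DEFAULT_FRAME_WIDTH) / 2
                           if iw >= DEFAULT_FRAME_WIDTH else 0))
    x_max = float(data.get("frame_x_max", (iw + DEFAULT_FRAME_WIDTH) / 2
                           if iw >= DEFAULT_FRAME_WIDTH else iw))
    y_min = float(data.get("frame_y_min", (ih - DEFAULT_FRAME_HEIGHT) / 2
                           if ih >= DEFAULT_FRAME_HEIGHT else 0))
    y_max = float(data.get("frame_y_max", (ih + DEFAULT_FRAME_HEIGHT) / 2
                           if ih >= DEFAULT_FRAME_HEIGHT else ih))
    fps = float(data.get("fps", DEFAULT_FPS))
    vf = VirtualFrame(x_min=x_min, y_min=y_min, x_max=x_max, y_max=y_max,
                      image_width=iw, image_height=ih, fps=fps)
    params = CountingParams(
        gap_threshold_seconds=float(
            data.get("gap_threshold_seconds", DEFAULT_GAP_THRESHOLD_SECONDS)
        ),
        method=str(data.get("method", "parity")),
    )
    return vf, params
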