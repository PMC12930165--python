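"""The two nest-entrance counting methods.

``count_yolo_only`` is the naive baseline: every boundary crossing of the
virtual frame is taken at face value — an inward crossing is reported as a
nest entry, an outward crossing as an exit.  A bee that merely dips into the
counting region and turns back is therefore double-counted, which is the
baseline's characteristic false-positive mode, but no true event is ever
missed, so its recall is structurally 100% whenever every true event
produces at least one detected crossing.

``count_parity`` adds the crossing-parity rule: a track's crossings are
grouped into episodes at the gap threshold, and an episode is declared a
nest event only when its crossing count is odd.  Odd parity forces the
episode's start and end states to differ, which also decides the direction:
outside -> inside means the bee came from the greenhouse and descended into
the nest (entry); inside -> outside means it emerged and flew off (exit).
Even-parity episodes — turn-backs and pass-overs — produce nothing.
"""

from __future__ import annotations

from typing import Iterable

from .crossing import Direction, Episode, RegionState, detect_crossings, track_episodes
from .trackmodel import EventKind, EventSource, NestEvent, Track, VirtualFrame

__all__ = ["count_yolo_only", "classify_episode", "count_parity"]


def count_yolo_only(tracks: Iterable[Track], vf: VirtualFrame) -> list[NestEvent]:
    """Naive counter: one nest event per virtual-frame crossing.

    Inward crossing -> entry, outward crossing -> exit, stamped with the
    crossing's frame.  The gap threshold and episode structure play no role.
    """
    events: list[NestEvent] = []
    for track in tracks:
        for c in detect_crossings(track, vf):
            events.append(
                NestEvent(
                    frame_index=c.frame_index,
                    track_id=c.track_id,
                    kind=EventKind.ENTRY if c.direction is Direction.INWARD else EventKind.EXIT,
                    source=EventSource.PREDICTED,
                )
            )
    events.sort(key=lambda e: (e.frame_index, e.track_id))
    return events


def classify_episode(episode: Episode) -> NestEvent | None:
    """Apply the parity rule to one episode.

    Odd crossing count -> one nest event, stamped with the last crossing's
    frame; even -> ``None`` (the bee turned back, or returned without fully
    leaving).  Direction comes from the start/end states, which differ
    exactly when parity is odd.
    """
    if len(episode) % 2 == 0:
        return None
    if episode.start_state == episode.end_state:  # unreachable given Episode invariant
        raise RuntimeError("odd-parity episode with equal start and end states")
    kind = (
        EventKind.ENTRY
        if episode.start_state is RegionState.OUTSIDE
        else EventKind.EXIT
    )
    return NestEvent(
        frame_index=episode.last_frame,
        track_id=episode.track_id,
        kind=kind,
        source=EventSource.PREDICTED,
    )


def count_parity(
    tracks: Iterable[Track], vf: VirtualFrame, gap_threshold_frames: float
) -> list[NestEvent]:
    """Parity counter: detect crossings, split into episodes, keep odd ones.

    Per track the event count never exceeds the episode count, which never
    exceeds the crossing count, so the parity method always reports at most
    as many events as the naive counter.
    """
    if gap_threshold_frames <= 0:
        raise ValueError(f"gap_threshold_frames must be > 0, got {gap_threshold_frames}")
    events: list[NestEvent] = []
    for track in tracks:
        for episode in track_episodes(track, vf, gap_threshold_frames):
            event = classify_episode(episode)
            if event is not None:
                events.append(event)
    events.sort(key=lambda e: (e.frame_index, e.track_id))
    return events
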