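"""Confusion-matrix evaluation of predicted nest events against ground truth.

Predicted and true events are matched greedily, one-to-one, in frame order:
a pair may match only if it has the same event kind, the same track lineage
(the identity a track had before any tracker corruption), and a frame
difference within the tolerance (one second by default).  Matched pairs are
true positives, unmatched predictions false positives, unmatched truths
false negatives.

True negatives need a unit of observation, which counting on continuous
video does not naturally supply.  The unit adopted here is the *candidate
unit*: one threshold-separated episode of a track that touched the virtual
frame.  A candidate unit carrying neither a true nor a predicted event is a
true negative — a turn-back correctly ignored.  The naive one-event-per-
crossing baseline asserts an event for every unit it sees, so it can never
produce a true negative; evaluate it with ``units=None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .crossing import track_episodes
from .trackmodel import NestEvent, Track, VirtualFrame

__all__ = [
    "ConfusionCounts",
    "CandidateUnit",
    "candidate_units",
    "match_events",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "all_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies; TP+FP = predictions, TP+FN = truths."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CandidateUnit:
    """One threshold-separated episode of a frame-touching track."""

    root_id: int
    first_frame: int
    last_frame: int


def candidate_units(
    tracks: Iterable[Track],
    vf: VirtualFrame,
    gap_threshold_frames: float,
    lineage: Mapping[int, int] | None = None,
) -> list[CandidateUnit]:
    """Enumerate the units at which negatives are counted.

    One unit per episode of every track with at least one crossing; tracks
    that never touched the rectangle contribute nothing.
    """
    lineage = lineage or {}
    units = []
    for track in tracks:
        root = lineage.get(track.track_id, track.track_id)
        for ep in track_episodes(track, vf, gap_threshold_frames):
            units.append(CandidateUnit(root, ep.first_frame, ep.last_frame))
    return units


def match_events(
    predicted: Sequence[NestEvent],
    truth: Sequence[NestEvent],
    tolerance_frames: int = 240,
    lineage: Mapping[int, int] | None = None,
    units: Sequence[CandidateUnit] | None = None,
) -> ConfusionCounts:
    """Greedy one-to-one matching of predictions to truth.

    Predictions are scanned in frame order; each takes the earliest
    still-unmatched truth event of the same kind and track lineage within
    ``tolerance_frames``.  With ``units`` supplied, every unit that carries
    neither a matched nor an unmatched event (within the padded frame span)
    counts as a true negative.
    """
    if tolerance_frames < 0:
        raise ValueError(f"tolerance_frames must be >= 0, got {tolerance_frames}")
    lineage = lineage or {}
    root = lambda tid: lineage.get(tid, tid)

    preds = sorted(predicted, key=lambda e: (e.frame_index, e.track_id))
    truths = sorted(truth, key=lambda e: (e.frame_index, e.track_id))
    truth_used = [False] * len(truths)
    tp = 0
    pred_matched = [False] * len(preds)
    for pi, p in enumerate(preds):
        for ti, t in enumerate(truths):
            if truth_used[ti]:
                continue
            if t.kind != p.kind or root(t.track_id) != root(p.track_id):
                continue
            if abs(t.frame_index - p.frame_index) <= tolerance_frames:
                truth_used[ti] = True
                pred_matched[pi] = True
                tp += 1
                break
    fp = len(preds) - tp
    fn = len(truths) - tp

    tn = 0
    if units is not None:
        events = preds + truths
        for u in units:
            lo = u.first_frame - tolerance_frames
            hi = u.last_frame + tolerance_frames
            if not any(
                root(e.track_id) == u.root_id and lo <= e.frame_index <= hi
                for e in events
            ):
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# metrics — undefined denominators yield None (reported as NA), never 0
# ---------------------------------------------------------------------------

def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def accuracy(c: ConfusionCounts) -> float | None:
    """(TP + TN) / (TP + FP + FN + TN)."""
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn)


def f1(c: ConfusionCounts) -> float | None:
    """2 TP / (2 TP + FP + FN) — the harmonic mean of precision and recall."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def all_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    return {
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1(c),
    }
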