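# Methods

## Problem setting

A fixed camera looks straight down at a bumblebee nest-box entrance and
records 640 × 480 video at 240 fps.  A detector/tracker reduces each frame
to bounding boxes with persistent track IDs.  The package's job starts
there: given those tracks, decide how many bees entered and exited the
nest box.  A rectangular counting region (the virtual frame), by default
495 × 150 px centred in the image, is placed over the entrance; all
counting logic is built from transitions of the box-centre across its
boundary.

## Conventions and parameters

| parameter | default | meaning |
|---|---|---|
| rectangle | 495 × 150 px centred in 640 × 480 | counting region in image coordinates |
| fps | 240 | video frame rate; converts seconds to frames |
| gap threshold τ | 1.0 s (240 frames) | maximum inter-crossing gap within one episode |
| matching tolerance | 240 frames | frame slack when pairing predicted and true events |

- Coordinates are 0-based pixels, origin top-left, x right, y down.
  Rectangle membership is half-open, `[x_min, x_max) × [y_min, y_max)`, so
  boundary points are counted exactly once.  Fractional edges are allowed
  (centring a 495-px rectangle in a 640-px image puts edges at 72.5 and
  567.5).
- A bee's position is its bounding-box centre.  The centre is the standard
  tripwire convention and is insensitive to box-size jitter.
- A crossing is a *point-state change* between consecutive detections, not
  a segment–boundary intersection; the two differ only if a bee jumps the
  entire 150-px depth of the rectangle between frames, which at 240 fps
  would require implausible speed.  No interpolation is done across
  detection dropout: however long the gap between two consecutive
  detections, at most one transition is recorded.
- A crossing is stamped with the *later* detection's frame — the first
  frame at which the new state is observed.
- Episode parity decides events; the direction rule (odd episode starting
  outside → entry, starting inside → exit) is forced to be total because
  odd parity implies the start and end states differ.
- A track that never crosses the boundary contributes nothing: no events
  and no candidate unit.

## Evaluation

Greedy one-to-one matching in frame order: each prediction takes the
earliest unmatched truth event of the same kind and the same track
*lineage* within the tolerance.  Lineage maps a corrupted track ID back to
the identity it had before an ID-switch corruption, so a correct
prediction made on the renamed half of a split track still scores as a
true positive.  On the tolerance-interval compatibility structure this
greedy matching attains maximum cardinality (verified against
Hopcroft–Karp in the tests).

Continuous video has no natural negative instances, so a unit of
observation is defined: every threshold-separated episode of every track
that touched the rectangle is a *candidate unit*, and a unit carrying
neither a true nor a predicted event is a true negative.  This gives the
parity method credit for correctly ignoring turn-backs.  The naive
counter converts every crossing into an event, so it can produce no
negatives; it is evaluated with no units (TN = 0), which also makes its
false negatives structurally zero whenever every true event yields at
least one detected crossing.

Metrics with a zero denominator return `None` and are printed as `NA`,
never silently 0.

## The simulator

The generator emulates the *topology* of entrance traffic, not bee
biomechanics.  A track is a piecewise-linear waypoint path rendered at one
detection per frame with a per-track speed drawn lognormally (median
3 px/frame, σ = 0.4, clipped to [1.5, 12]); Gaussian jitter (default
σ = 1 px) is added to observed centres, and ground truth is computed from
the noise-free path by construction.  Patterns:

- **A** — approach from outside, terminate inside (descended into the
  nest): one entry.
- **B** — dip into the rectangle, dwell, leave the way it came: nothing.
- **C** — emerge inside, fly off: one exit.
- **D** — poke just outside, dwell, return inside: nothing.
- **pass_over** — straight transit across the rectangle: nothing.
- **multi_turn_k** — k boundary transitions with sub-threshold dwells;
  odd k ends inside (one entry), even k ends outside (nothing).

Default pattern mix A .3, B .2, C .3, D .1, pass_over .1 — straight passes
are deliberately rare, entries and exits balanced.

Choices that keep the stated world consistent with its labels:

- Turn-backs are *shallow*: the dip point sits 20–40 px past the boundary
  near where the path crosses it, and dwells are 0.1–0.5 s, so the two
  crossings of a clean turn-back always fall within one threshold window.
  A configurable fraction of dwells (`long_dwell_prob`) instead lasts
  1.1–2 s, reproducing the false-positive mode in which a lingering bee's
  episode is split in two.
- Through-flights get a higher speed floor (2.5 px/frame) so a transit of
  the 495-px rectangle stays under one second; slow hovering is a
  behaviour of bees maneuvering at the entrance, not of bees in transit.
- Tracker faults are explicit operators: an *ID switch* splits a track at
  a random interior frame and renames the tail (false-positive mode); an
  *ID merge* re-stamps a second bee's track to follow a first bee under
  one ID with a configurable gap (false-negative mode when the gap is
  below τ).  Merge gaps default to 0.25–2 s, straddling the threshold.
- Box sizes are 20 px ± 10% — irrelevant to centre-based counting, kept
  only so files look like real tracker output.

What the simulator does **not** model: image appearance, detector
confidence correlated with pose, multi-bee occlusion, curved flight,
diurnal traffic rates.  A green test therefore establishes that the
counting and evaluation logic is correct on the stated trajectory
topologies and failure modes — not that any detector achieves a
particular score on real greenhouse video, whose headline numbers depend
on undeposited footage.

## Degenerate inputs and numerics

- Empty track file → empty track collection; empty event list → header-only
  CSV; both round-trip.
- Single-detection tracks produce no crossings.
- `dropout_prob` near 1 can delete whole tracks; the generator warns above
  0.9 and silently omits bees that were never observed.
- An infinite gap threshold is accepted (one episode per track), matching
  the no-threshold reading of the parity rule.
- All randomness flows through one `numpy` Generator seeded from the
  configuration; every artifact is byte-reproducible from the seed.

## Known limitations

- The counting region is a single axis-aligned rectangle; polygonal or
  3-D regions are out of scope.
- No re-identification: an ID switch away from the boundary is harmless,
  but one between a turn-back's crossings is counted wrongly by design —
  that is the failure mode being studied, and fixing it belongs in the
  tracker.
- Entry/exit direction is inferred from episode start/end states; a track
  first detected exactly on the boundary frame resolves by the half-open
  membership rule.
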