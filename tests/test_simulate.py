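"""The trajectory simulator: patterns, labels, corruption operators."""

from __future__ import annotations

import numpy as np
import pytest

from beecount.counter import count_parity
from beecount.crossing import detect_crossings
from beecount.simulate import (
    LabelledTrack,
    SimConfig,
    corrupt_id_merge,
    corrupt_id_switch,
    generate_dataset,
    sample_track,
)
from beecount.trackmodel import EventKind

TRUTH_BY_PATTERN = {
    "A": [EventKind.ENTRY],
    "B": [],
    "C": [EventKind.EXIT],
    "D": [],
    "pass_over": [],
    "multi_turn_3": [EventKind.ENTRY],  # odd transitions ending at the nest
    "multi_turn_4": [],
}


def clean_cfg(**kw) -> SimConfig:
    return SimConfig(n_tracks=10, jitter_sd=0.0, seed=kw.pop("seed", 0), **kw)


class TestSampleTrack:
    @pytest.mark.parametrize("pattern", sorted(TRUTH_BY_PATTERN))
    def test_label_consistency(self, vf, pattern):
        """Every pattern's ground truth matches its declared semantics, and
        on a noise-free track the parity counter reproduces it exactly."""
        cfg = clean_cfg()
        rng = np.random.default_rng(42)
        for _ in range(20):
            lt = sample_track(pattern, cfg, rng, track_id=1, start_frame=0)
            assert [e.kind for e in lt.true_events] == TRUTH_BY_PATTERN[pattern]
            predicted = count_parity([lt.track], vf, 240)
            assert [(e.frame_index, e.kind) for e in predicted] == \
                   [(e.frame_index, e.kind) for e in lt.true_events]

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            sample_track("Z", clean_cfg(), np.random.default_rng(0))

    def test_long_dwell_splits_turn_back(self, vf):
        """A bee lingering inside for more than the threshold makes the
        parity method emit two spurious events — its documented FP mode."""
        cfg = SimConfig(n_tracks=1, jitter_sd=0.0, seed=0,
                        long_dwell_prob=0.999, pattern_weights={"B": 1.0})
        rng = np.random.default_rng(5)
        lt = sample_track("B", cfg, rng)
        assert lt.true_events == []
        events = count_parity([lt.track], vf, 240)
        assert [e.kind for e in events] == [EventKind.ENTRY, EventKind.EXIT]


class TestCorruptions:
    def _b_track(self, seed=0) -> LabelledTrack:
        rng = np.random.default_rng(seed)
        return sample_track("B", clean_cfg(), rng)

    def test_switch_between_crossings_creates_fp(self, vf):
        # split a turn-back between its two crossings: each half carries one
        # crossing, so the parity method reports two events where none occurred
        lt = self._b_track()
        crossings = detect_crossings(lt.track, vf)
        assert len(crossings) == 2
        for attempt in range(50):
            parts = corrupt_id_switch(lt, np.random.default_rng(attempt), new_id=99)
            cut = parts[1].track.first_frame
            if crossings[0].frame_index <= cut <= crossings[1].frame_index:
                events = count_parity([p.track for p in parts], vf, 240)
                assert len(events) == 2
                assert all(p.root_id == lt.track.track_id for p in parts)
                return
        pytest.fail("no split landed between the crossings")

    def test_switch_deterministic_and_conservative(self):
        lt = self._b_track()
        a = corrupt_id_switch(lt, np.random.default_rng(3), new_id=50)
        b = corrupt_id_switch(self._b_track(), np.random.default_rng(3), new_id=50)
        assert [p.track.first_frame for p in a] == [p.track.first_frame for p in b]
        assert sum(len(p.track) for p in a) == len(lt.track)

    def test_switch_too_short_returned_unchanged(self, vf):
        rng = np.random.default_rng(0)
        lt = sample_track("A", clean_cfg(), rng)
        short = LabelledTrack(
            track=type(lt.track)(lt.track.track_id, lt.track.detections[:3]),
            true_events=[], pattern="A",
        )
        assert corrupt_id_switch(short, rng) == [short]

    def test_merge_below_threshold_cancels_events(self, vf):
        """One ID carrying an entering bee then an exiting bee within the
        threshold: parity cancels both events (2 FN); with a gap over the
        threshold the episode split recovers them."""
        rng = np.random.default_rng(1)
        a = sample_track("A", clean_cfg(), rng, track_id=1)
        c = sample_track("C", clean_cfg(), rng, track_id=2)
        merged_close = corrupt_id_merge(a, c, gap_frames=100)
        assert len(merged_close.true_events) == 2
        assert count_parity([merged_close.track], vf, 240) == []

        a2 = sample_track("A", clean_cfg(), rng, track_id=3)
        c2 = sample_track("C", clean_cfg(), rng, track_id=4)
        merged_far = corrupt_id_merge(a2, c2, gap_frames=500)
        events = count_parity([merged_far.track], vf, 240)
        assert sorted(e.kind for e in events) == [EventKind.ENTRY, EventKind.EXIT]

    def test_merge_conserves_detections(self):
        rng = np.random.default_rng(2)
        a = sample_track("A", clean_cfg(), rng, track_id=1)
        c = sample_track("C", clean_cfg(), rng, track_id=2)
        merged = corrupt_id_merge(a, c, gap_frames=10)
        assert len(merged.track) == len(a.track) + len(c.track)
        assert merged.track.track_id == 1

    def test_merge_rejects_non_positive_gap(self):
        rng = np.random.default_rng(2)
        a = sample_track("A", clean_cfg(), rng, track_id=1)
        c = sample_track("C", clean_cfg(), rng, track_id=2)
        with pytest.raises(ValueError):
            corrupt_id_merge(a, c, gap_frames=0)


class TestGenerateDataset:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(pattern_weights={"A": 0.5, "B": 0.4})  # does not sum to 1
        with pytest.raises(ValueError):
            SimConfig(dropout_prob=1.0)
        with pytest.raises(ValueError):
            SimConfig(n_tracks=0)

    def test_determinism(self):
        cfg = SimConfig(n_tracks=30, seed=11, id_switch_prob=0.2, id_merge_prob=0.2)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert [
            (d.frame_index, d.track_id, d.center_x, d.center_y)
            for t in d1.tracks for d in t
        ] == [
            (d.frame_index, d.track_id, d.center_x, d.center_y)
            for t in d2.tracks for d in t
        ]
        assert d1.truth_events == d2.truth_events
        assert d1.lineage == d2.lineage

    def test_all_entries_world(self):
        cfg = SimConfig(n_tracks=10, seed=4, jitter_sd=0.0,
                        pattern_weights={"A": 1.0})
        ds = generate_dataset(cfg)
        assert len(ds.truth_events) == 10
        assert all(e.kind is EventKind.ENTRY for e in ds.truth_events)

    def test_entry_fraction_statistics(self):
        """With equal A/C weights the entry fraction sits inside the
        binomial 99% interval around one half."""
        cfg = SimConfig(n_tracks=1000, seed=8, pattern_weights={"A": 0.5, "C": 0.5})
        ds = generate_dataset(cfg)
        entries = sum(e.kind is EventKind.ENTRY for e in ds.truth_events)
        assert len(ds.truth_events) == 1000
        margin = 2.576 * (0.25 / 1000) ** 0.5
        assert abs(entries / 1000 - 0.5) < margin

    def test_heavy_dropout_warns_not_crashes(self):
        cfg = SimConfig(n_tracks=20, seed=9, dropout_prob=0.95)
        with pytest.warns(UserWarning, match="dropout"):
            ds = generate_dataset(cfg)
        assert all(len(t) >= 1 for t in ds.tracks)

    def test_lineage_covers_all_tracks(self):
        cfg = SimConfig(n_tracks=50, seed=12, id_switch_prob=0.3, id_merge_prob=0.3)
        ds = generate_dataset(cfg)
        assert set(ds.lineage) == {t.track_id for t in ds.tracks}
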