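import itertools

import numpy as np
import pytest

from ocpam.core import LabelMask, OrganoidRecord
from ocpam.segment import summarize_mask
from ocpam.synthetic import generate_organoid_timeseries
from ocpam.tracking import (
    Track,
    build_tracks,
    detect_merges,
    match_day_pair,
    score_pair,
    select_reference_day,
)


def _rec(label, centroid, volume=1000.0, bbox=None, day=None):
    if bbox is None:
        bbox = tuple((int(c // 1) - 2, int(c // 1) + 2) for c in centroid)
    return OrganoidRecord(label=label, centroid=centroid, volume=volume,
                          bbox=bbox, day=day)


class TestReferenceDay:
    def test_odd_series_median(self):
        assert select_reference_day((3, 5, 7, 9, 11, 13, 15)) == 9

    def test_even_series_earlier_central(self):
        assert select_reference_day((3, 5)) == 3
        assert select_reference_day((3, 5, 7, 9)) == 5

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            select_reference_day((3,))


class TestScorePair:
    def test_identical_records_score_one(self):
        a = _rec(1, (10.0, 10.0, 10.0))
        s = score_pair(a, a)
        assert s.spatial == s.volume == s.bbox == 1.0
        assert s.combined == pytest.approx(1.0)

    def test_spatial_kernel_monotone_decreasing(self):
        a = _rec(1, (0.0, 0.0, 0.0))
        prev = 1.0
        for d in (10.0, 30.0, 60.0, 120.0, 500.0):
            s = score_pair(a, _rec(2, (0.0, 0.0, d)))
            assert s.spatial < prev
            prev = s.spatial
        assert prev < 1e-6  # -> 0 as d -> infinity

    def test_volume_kernel_arithmetic(self):
        a = _rec(1, (0.0, 0.0, 0.0), volume=100.0)
        b = _rec(2, (0.0, 0.0, 0.0), volume=400.0)
        assert score_pair(a, b).volume == pytest.approx(0.25)

    def test_zero_volume_rejected(self):
        a = _rec(1, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            OrganoidRecord(label=2, centroid=(0, 0, 0), volume=0.0,
                           bbox=((0, 1), (0, 1), (0, 1)))
        # records cannot be built with zero volume, so score_pair's
        # precondition is enforced at the type level


class TestMatchDayPair:
    def test_one_to_one_small_displacement(self):
        a = [_rec(1, (50.0, 50.0, 50.0))]
        b = [_rec(1, (52.0, 50.0, 49.0))]
        mapping, ua, ub = match_day_pair(a, b)
        assert mapping == {1: 1} and not ua and not ub

    def test_crossing_pair_matches_brute_force(self):
        # two organoids swap-ish positions; optimal assignment must equal
        # exhaustive enumeration over both possible pairings
        a = [_rec(1, (50.0, 50.0, 50.0), volume=1000.0),
             _rec(2, (50.0, 50.0, 90.0), volume=2000.0)]
        b = [_rec(1, (50.0, 50.0, 62.0), volume=1100.0),
             _rec(2, (50.0, 50.0, 95.0), volume=2100.0)]
        mapping, _, _ = match_day_pair(a, b, tau=0.0)

        def total(assign):
            return sum(score_pair(a[i], b[j]).combined for i, j in assign)

        best = max(
            [((0, 0), (1, 1)), ((0, 1), (1, 0))],
            key=total,
        )
        expected = {a[i].label: b[j].label for i, j in best}
        assert mapping == expected

    def test_all_below_threshold_unmatched(self):
        a = [_rec(1, (0.0, 0.0, 0.0), volume=10.0)]
        b = [_rec(1, (500.0, 500.0, 500.0), volume=1e6)]
        mapping, ua, ub = match_day_pair(a, b, tau=0.4)
        assert mapping == {} and ua == {1} and ub == {1}

    def test_set_level_symmetry(self):
        rng = np.random.default_rng(3)
        a = [_rec(i + 1, tuple(rng.uniform(0, 200, 3)), volume=rng.uniform(500, 5000))
             for i in range(5)]
        b = [_rec(i + 1, tuple(rng.uniform(0, 200, 3)), volume=rng.uniform(500, 5000))
             for i in range(4)]
        fwd, _, _ = match_day_pair(a, b, tau=0.1)
        rev, _, _ = match_day_pair(b, a, tau=0.1)
        assert {(k, v) for k, v in fwd.items()} == {(v, k) for k, v in rev.items()}


class TestBuildTracks:
    def test_synthetic_series_identity_accuracy(self):
        # well-separated organoids, small drift: identity must be perfect,
        # and ground-truth labels are stable across days by construction
        _, masks, _ = generate_organoid_timeseries(
            15, days=(3, 5, 7, 9, 11), class_mix={"WEAK": 0.6, "MEDIUM": 0.4},
            seed=11, field_um=(250.0, 500.0, 500.0), drift_um_per_day=2.0,
            separation_margin_um=20.0, initial_semiaxis_um=(6, 9, 0.2))
        recs = {m.day: summarize_mask(m) for m in masks}
        tracks = build_tracks(recs)
        assert len(tracks) == 15
        for t in tracks:
            labels = set(t.entries.values())
            assert len(labels) == 1 and None not in labels

    def test_absent_on_final_day_flagged_lost(self):
        days = (3, 5, 7)
        recs = {d: [_rec(1, (50.0, 50.0, 50.0), day=d)] for d in days}
        recs[7] = []  # organoid gone on the last day
        tracks = build_tracks(recs)
        assert len(tracks) == 1
        assert ("LOST", 7) in tracks[0].flags
        assert tracks[0].entries[7] is None

    def test_appearing_after_reference_gets_new_track(self):
        days = (3, 5, 7)
        recs = {
            3: [_rec(1, (50.0, 50.0, 50.0), day=3)],
            5: [_rec(1, (50.0, 50.0, 50.0), day=5)],
            7: [_rec(1, (50.0, 50.0, 50.0), day=7),
                _rec(2, (150.0, 150.0, 150.0), day=7)],
        }
        tracks = build_tracks(recs)
        assert len(tracks) == 2
        newcomer = [t for t in tracks if t.entries[7] == 2][0]
        assert ("APPEARED", 7) in newcomer.flags
        assert newcomer.entries[3] is None and newcomer.entries[5] is None

    def test_track_count_bounded_by_distinct_labels(self):
        rng = np.random.default_rng(5)
        days = (3, 5, 7, 9)
        recs = {
            d: [_rec(i + 1, tuple(rng.uniform(0, 300, 3)),
                     volume=rng.uniform(500, 3000), day=d)
                for i in range(rng.integers(1, 5))]
            for d in days
        }
        tracks = build_tracks(recs)
        total_labels = sum(len(v) for v in recs.values())
        assert len(tracks) <= total_labels


class TestDetectMerges:
    def _masks_for_merge(self):
        # day 3: labels 1 (big) and 2 (small); day 5: single label 1
        a = np.zeros((4, 12, 12), np.int32)
        a[1:3, 1:7, 1:7] = 1
        a[1:3, 8:11, 8:11] = 2
        b = np.zeros((4, 12, 12), np.int32)
        b[1:3, 1:11, 1:11] = 1
        return {3: LabelMask(a, (1, 1, 1), day=3), 5: LabelMask(b, (1, 1, 1), day=5)}

    def test_two_into_one_flags_smaller(self):
        masks = self._masks_for_merge()
        recs = {d: summarize_mask(m) for d, m in masks.items()}
        tracks = build_tracks(recs)
        tracks = detect_merges(tracks, masks, overlap_fraction=0.5)
        flagged = [t for t in tracks if any(f[0] == "MERGED_INTO" for f in t.flags)]
        assert len(flagged) == 1
        assert flagged[0].entries[3] == 2  # the smaller day-3 organoid

    def test_no_overlap_no_flags(self):
        a = np.zeros((3, 10, 10), np.int32)
        a[1, 1:4, 1:4] = 1
        b = np.zeros((3, 10, 10), np.int32)
        b[1, 6:9, 6:9] = 1
        masks = {3: LabelMask(a, (1, 1, 1), day=3), 5: LabelMask(b, (1, 1, 1), day=5)}
        tracks = build_tracks({d: summarize_mask(m) for d, m in masks.items()})
        tracks = detect_merges(tracks, masks)
        assert all(not any(f[0] == "MERGED_INTO" for f in t.flags) for t in tracks)

    def test_three_into_one_survivor_is_largest(self):
        a = np.zeros((4, 20, 20), np.int32)
        a[1:3, 1:9, 1:9] = 1      # largest
        a[1:3, 11:15, 1:5] = 2
        a[1:3, 11:14, 11:14] = 3
        b = np.zeros((4, 20, 20), np.int32)
        b[1:3, 1:15, 1:15] = 1
        masks = {3: LabelMask(a, (1, 1, 1), day=3), 5: LabelMask(b, (1, 1, 1), day=5)}
        tracks = build_tracks({d: summarize_mask(m) for d, m in masks.items()})
        tracks = detect_merges(tracks, masks, overlap_fraction=0.5)
        survivor = [t for t in tracks if t.entries[3] == 1][0]
        merged = [t for t in tracks
                  if any(f[0] == "MERGED_INTO" for f in t.flags)]
        # brute-force overlap enumeration says labels 2 and 3 merged into 1
        assert len(merged) == 2
        assert {t.entries[3] for t in merged} == {2, 3}
        assert all(f[1] == survivor.id
                   for t in merged for f in t.flags if f[0] == "MERGED_INTO")
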