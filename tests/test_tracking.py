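"""Frame-to-frame linking: births, deaths, collisions, separations, threads."""

import numpy as np
import pytest

from conftest import make_image
from lcrtrack.frames_io import FrameStack
from lcrtrack.tracking import (
    ImagePair,
    Tracker,
    classify_track,
    pair_images,
    track_stack,
)


def run_frames(frames):
    """Feed hand-built per-frame image lists through a fresh tracker."""
    tr = Tracker()
    for images in frames:
        tr.step(images)
    last = max((im.frame_index for images in frames for im in images), default=len(frames) - 1)
    tracks = tr.finalize(last)
    return tr, tracks


class TestPairing:
    def test_shared_voxel_pairs(self):
        prev = [make_image(0, 0, [(2, 2), (2, 3)])]
        curr = [make_image(1, 0, [(2, 3), (2, 4)])]
        assert pair_images(prev, curr) == [ImagePair((0, 0), (1, 0))]

    def test_disjoint_images_do_not_pair(self):
        prev = [make_image(0, 0, [(2, 2)])]
        curr = [make_image(1, 0, [(5, 5)])]
        assert pair_images(prev, curr) == []

    def test_one_curr_overlapping_two_prev_gives_two_pairs(self):
        prev = [make_image(0, 0, [(1, 1)]), make_image(0, 1, [(1, 4)])]
        curr = [make_image(1, 0, [(1, 1), (1, 2), (1, 3), (1, 4)])]
        pairs = pair_images(prev, curr)
        assert [(p.prev_key, p.curr_key) for p in pairs] == [
            ((0, 0), (1, 0)),
            ((0, 1), (1, 0)),
        ]


class TestSimpleDynamics:
    def test_birth_life_attrition(self):
        blob = [(3, 3), (3, 4)]
        frames = [[make_image(k, 0, blob)] for k in range(4)] + [[]]
        tr, tracks = run_frames(frames)
        assert len(tracks) == 1
        t = tracks[0]
        assert (t.birth_frame, t.death_frame, t.termination) == (0, 3, "attrition")
        kinds = [(e.kind, e.frame) for e in tr.events]
        assert kinds == [("birth", 0), ("death_attrition", 4)]

    def test_track_alive_at_end(self):
        frames = [[make_image(k, 0, [(1, 1)])] for k in range(5)]
        _, tracks = run_frames(frames)
        assert tracks[0].termination == "alive_at_end"

    def test_blank_stack_has_no_tracks(self):
        _, tracks = run_frames([[], [], []])
        assert tracks == []

    def test_every_image_belongs_to_exactly_one_track(self):
        frames = [
            [make_image(0, 0, [(1, 1)]), make_image(0, 1, [(5, 5)])],
            [make_image(1, 0, [(1, 1), (1, 2)]), make_image(1, 1, [(5, 5)])],
            [make_image(2, 0, [(1, 2)])],
        ]
        tr, tracks = run_frames(frames)
        all_keys = [k for f in frames for k in (im.key for im in f)]
        assigned = [k for t in tracks for k in t.image_keys]
        assert sorted(assigned) == sorted(all_keys)

    def test_lifetime_contiguity(self):
        frames = [
            [make_image(0, 0, [(1, 1)])],
            [make_image(1, 0, [(1, 1)])],
            [],
            [make_image(3, 0, [(1, 1)])],  # same spot, but a new release
        ]
        _, tracks = run_frames(frames)
        assert len(tracks) == 2
        for t in tracks:
            lo, hi = min(t.images_by_frame), max(t.images_by_frame)
            assert sorted(t.images_by_frame) == list(range(lo, hi + 1))


class TestCollision:
    def test_larger_previous_mass_survives(self):
        frames = [
            [
                make_image(0, 0, [(1, 1)], signal_mass_nmol=5e-15),
                make_image(0, 1, [(1, 5)], signal_mass_nmol=2e-15),
            ],
            [make_image(1, 0, [(1, 1), (1, 2), (1, 3), (1, 4), (1, 5)])],
        ]
        tr, tracks = run_frames(frames)
        by_id = {t.lcr_id: t for t in tracks}
        assert by_id[1].termination == "collision"
        assert by_id[0].termination == "alive_at_end"
        deaths = [e for e in tr.events if e.kind == "death_collision"]
        assert len(deaths) == 1
        assert deaths[0].lcr_ids == (1, 0)  # (terminated, surviving)
        # the merged current image belongs to the survivor
        assert (1, 0) in by_id[0].image_keys

    def test_tie_goes_to_older_track(self):
        frames = [
            [
                make_image(0, 0, [(1, 1)], signal_mass_nmol=3e-15),
                make_image(0, 1, [(1, 5)], signal_mass_nmol=3e-15),
            ],
            [make_image(1, 0, [(r, c) for r in (1,) for c in range(1, 6)])],
        ]
        _, tracks = run_frames(frames)
        by_id = {t.lcr_id: t for t in tracks}
        assert by_id[0].termination == "alive_at_end"
        assert by_id[1].termination == "collision"

    def test_three_way_collision_single_survivor(self):
        frames = [
            [
                make_image(0, 0, [(1, 1)], signal_mass_nmol=1e-15),
                make_image(0, 1, [(1, 3)], signal_mass_nmol=9e-15),
                make_image(0, 2, [(1, 5)], signal_mass_nmol=4e-15),
            ],
            [make_image(1, 0, [(1, c) for c in range(1, 6)])],
        ]
        tr, tracks = run_frames(frames)
        by_id = {t.lcr_id: t for t in tracks}
        assert by_id[1].termination == "alive_at_end"
        assert by_id[0].termination == by_id[2].termination == "collision"
        assert sum(e.kind == "death_collision" for e in tr.events) == 2

    def test_collision_priority_over_separation(self):
        # Track 1's previous image would separate into (curr C, curr D),
        # but C also collides with the heavier track 0: track 1 dies, its
        # pairs are removed, so no separation happens and D is a new birth.
        frames = [
            [
                make_image(0, 0, [(1, 1)], signal_mass_nmol=9e-15),  # track 0
                make_image(0, 1, [(1, 4), (2, 4)], signal_mass_nmol=2e-15),  # track 1
            ],
            [
                make_image(1, 0, [(1, 1), (1, 2), (1, 3), (1, 4)]),  # C
                make_image(1, 1, [(2, 4), (3, 4)]),  # D
            ],
        ]
        tr, tracks = run_frames(frames)
        kinds = [e.kind for e in tr.events]
        assert "death_collision" in kinds
        assert "separation" not in kinds
        assert kinds.count("birth") == 3  # two initial + D
        by_id = {t.lcr_id: t for t in tracks}
        assert by_id[1].termination == "collision"
        assert by_id[1].n_separations == 0


class TestSeparation:
    def test_split_creates_two_threads_one_track(self):
        frames = [
            [make_image(0, 0, [(1, 1), (1, 2), (1, 3)])],
            [make_image(1, 0, [(1, 1)]), make_image(1, 1, [(1, 3)])],
        ]
        tr, tracks = run_frames(frames)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.n_threads == 2
        assert t.n_separations == 1
        assert sum(e.kind == "separation" for e in tr.events) == 1

    def test_multi_thread_track_survives_one_thread_death(self):
        frames = [
            [make_image(0, 0, [(1, 1), (1, 2), (1, 3)])],
            [make_image(1, 0, [(1, 1)]), make_image(1, 1, [(1, 3)])],
            [make_image(2, 0, [(1, 1)])],  # right thread vanished
            [make_image(3, 0, [(1, 1)])],
        ]
        tr, tracks = run_frames(frames)
        t = tracks[0]
        assert t.termination == "alive_at_end"
        assert not any(e.kind == "death_attrition" for e in tr.events)

    def test_multi_thread_track_dies_when_all_threads_end(self):
        frames = [
            [make_image(0, 0, [(1, 1), (1, 2), (1, 3)])],
            [make_image(1, 0, [(1, 1)]), make_image(1, 1, [(1, 3)])],
            [make_image(2, 0, [(1, 1)])],
            [],
        ]
        tr, tracks = run_frames(frames)
        t = tracks[0]
        assert t.termination == "attrition"
        assert t.death_frame == 2

    def test_threads_of_same_track_merging_is_not_a_collision(self):
        frames = [
            [make_image(0, 0, [(1, 1), (1, 2), (1, 3)])],
            [make_image(1, 0, [(1, 1)]), make_image(1, 1, [(1, 3)])],
            [make_image(2, 0, [(1, 1), (1, 2), (1, 3)])],  # threads rejoin
            [make_image(3, 0, [(1, 2)])],
        ]
        tr, tracks = run_frames(frames)
        assert len(tracks) == 1
        kinds = [e.kind for e in tr.events]
        assert "death_collision" not in kinds
        assert "intra_thread_merge" in kinds
        assert tracks[0].termination == "alive_at_end"


class TestClassification:
    def test_all_simple_images_is_simple(self):
        frames = [[make_image(k, 0, [(1, 1)])] for k in range(3)]
        tr, tracks = run_frames(frames)
        assert classify_track(tracks[0], tr.images) == "simple"

    def test_one_complex_image_makes_complex(self):
        frames = [
            [make_image(0, 0, [(1, 1)])],
            [make_image(1, 0, [(1, 1), (1, 2)], n_peaks=2)],
            [make_image(2, 0, [(1, 1)])],
        ]
        tr, tracks = run_frames(frames)
        assert classify_track(tracks[0], tr.images) == "complex"

    def test_classification_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            frames = []
            for k in range(5):
                n_peaks = int(rng.integers(1, 3))
                frames.append([make_image(k, 0, [(1, 1), (1, 2)], n_peaks=n_peaks)])
            tr, tracks = run_frames(frames)
            expected = (
                "complex"
                if any(tr.images[key].is_complex for key in tracks[0].image_keys)
                else "simple"
            )
            assert classify_track(tracks[0], tr.images) == expected


class TestDeterminism:
    def test_identical_stack_gives_identical_event_log(self, rng):
        data = rng.random((12, 20, 20)) + 0.05
        s1 = FrameStack(data.copy())
        s2 = FrameStack(data.copy())
        r1 = track_stack(s1)
        r2 = track_stack(s2)
        assert r1.events == r2.events
        assert [(t.lcr_id, t.birth_frame, t.death_frame, t.termination) for t in r1.tracks] == [
            (t.lcr_id, t.birth_frame, t.death_frame, t.termination) for t in r2.tracks
        ]
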