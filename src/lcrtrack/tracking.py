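"""Frame-to-frame linking of LCR images into dynamic LCR tracks.

Two images in consecutive frames belong to the same release if their
lowest-bin footprints share at least one voxel (a Boolean AND matchup).
From the resulting image pairs each frame is processed as:

* an unpaired current image starts a new track (*birth*);
* a current image paired with previous images of two or more distinct
  tracks is a *collision*: the track owning the largest-signal-mass
  previous image adopts the current image and survives, every other
  participant is terminated (death by collision) and its pairs are removed
  before separations are considered — collisions take priority;
* one previous image paired with several current images is a *separation*:
  all current images stay within the same track, which gains threads;
* a track none of whose previous images found a partner dies by
  *stochastic attrition* — but a multi-thread track dies only when all of
  its threads have ended;
* a track still alive after the last frame is labelled *alive at end*
  (in a diastolic window this is termination by the Ca transient).

Tracking is fully deterministic: identical stacks and configuration give
identical event logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .frames_io import FrameStack
from .segmentation import LCRImage, SegmentationConfig, segment_frame

__all__ = [
    "ImagePair",
    "LCRTrack",
    "TrackEvent",
    "Tracker",
    "TrackingResult",
    "pair_images",
    "classify_track",
    "track_stack",
]

EventKind = Literal[
    "birth",
    "death_attrition",
    "death_collision",
    "separation",
    "intra_thread_merge",
    "alive_at_end",
]

ImageKey = tuple[int, int]  # (frame_index, image_id)


@dataclass(frozen=True)
class ImagePair:
    """An overlap link between images of consecutive frames."""

    prev_key: ImageKey
    curr_key: ImageKey


@dataclass(frozen=True)
class TrackEvent:
    """One birth/death/collision/separation record in the event log."""

    kind: EventKind
    frame: int
    lcr_ids: tuple[int, ...]
    image_ids: tuple[ImageKey, ...]


@dataclass
class LCRTrack:
    """A dynamic LCR: the time-linked set of its LCR images.

    ``threads`` are the branches created by separations; each thread is a
    chain of image keys.  A track with a separation history is multi-thread
    and dies only when all threads have ended.  ``death_frame`` is the last
    frame in which the track had an image (None while alive / alive at end).
    """

    lcr_id: int
    birth_frame: int
    images_by_frame: dict[int, set[ImageKey]] = field(default_factory=dict)
    threads: dict[int, list[ImageKey]] = field(default_factory=dict)
    n_separations: int = 0
    status: Literal["alive", "dead"] = "alive"
    termination: Literal["none", "attrition", "collision", "alive_at_end"] = "none"
    death_frame: int | None = None
    _next_thread_id: int = 0
    _live_threads: dict[int, ImageKey] = field(default_factory=dict)  # thread -> tip

    @property
    def n_threads(self) -> int:
        return len(self.threads)

    @property
    def last_frame(self) -> int:
        return max(self.images_by_frame)

    @property
    def image_keys(self) -> list[ImageKey]:
        return [k for f in sorted(self.images_by_frame) for k in sorted(self.images_by_frame[f])]

    def _add_image(self, key: ImageKey) -> None:
        self.images_by_frame.setdefault(key[0], set()).add(key)

    def _new_thread(self, tip: ImageKey) -> int:
        tid = self._next_thread_id
        self._next_thread_id += 1
        self.threads[tid] = [tip]
        self._live_threads[tid] = tip
        return tid


def pair_images(
    prev_images: Sequence[LCRImage], curr_images: Sequence[LCRImage]
) -> list[ImagePair]:
    """All pairs of consecutive-frame images sharing >= 1 lowest-bin voxel.

    Ordered deterministically by (prev id, curr id).
    """
    pairs: list[ImagePair] = []
    for p in prev_images:
        for c in curr_images:
            if p.voxels & c.voxels:
                pairs.append(ImagePair(p.key, c.key))
    pairs.sort(key=lambda pr: (pr.prev_key, pr.curr_key))
    return pairs


def classify_track(track: LCRTrack, images: dict[ImageKey, LCRImage]) -> str:
    """"complex" if any member image has >= 2 peaks, else "simple"."""
    for key in track.image_keys:
        if images[key].is_complex:
            return "complex"
    return "simple"


class Tracker:
    """Incremental frame-by-frame LCR tracker.

    Feed frames in order with :meth:`step`, then call :meth:`finalize`.
    The tracker owns the registry of all LCR images it has seen.
    """

    def __init__(self) -> None:
        self.tracks: dict[int, LCRTrack] = {}
        self.images: dict[ImageKey, LCRImage] = {}
        self.events: list[TrackEvent] = []
        self._next_lcr_id = 0
        self._prev_images: list[LCRImage] = []
        self._owner: dict[ImageKey, int] = {}  # image key -> lcr_id
        self._last_frame_seen: int | None = None

    # -- helpers -----------------------------------------------------------

    def _live_tracks_with_tips(self) -> dict[int, LCRTrack]:
        return {i: t for i, t in self.tracks.items() if t.status == "alive"}

    def _birth(self, image: LCRImage) -> LCRTrack:
        track = LCRTrack(lcr_id=self._next_lcr_id, birth_frame=image.frame_index)
        self._next_lcr_id += 1
        track._add_image(image.key)
        track._new_thread(image.key)
        self.tracks[track.lcr_id] = track
        self._owner[image.key] = track.lcr_id
        self.events.append(
            TrackEvent("birth", image.frame_index, (track.lcr_id,), (image.key,))
        )
        return track

    def _kill(self, track: LCRTrack, termination: str, death_frame: int) -> None:
        track.status = "dead"
        track.termination = termination  # type: ignore[assignment]
        track.death_frame = death_frame
        track._live_threads.clear()

    # -- main step ---------------------------------------------------------

    def step(
        self,
        curr_images: Sequence[LCRImage],
        pairs: Sequence[ImagePair] | None = None,
    ) -> list[TrackEvent]:
        """Process the next frame's images; returns the events it produced."""
        if curr_images:
            frames = {im.frame_index for im in curr_images}
            if len(frames) != 1:
                raise ValueError("curr_images must all come from one frame")
            frame = frames.pop()
        elif self._last_frame_seen is not None:
            frame = self._last_frame_seen + 1
        else:
            frame = 0
        if self._last_frame_seen is not None and frame != self._last_frame_seen + 1:
            raise ValueError(
                f"frames must be consecutive: got {frame} after {self._last_frame_seen}"
            )
        self._last_frame_seen = frame

        for im in curr_images:
            self.images[im.key] = im

        if pairs is None:
            pairs = pair_images(self._prev_images, curr_images)
        else:
            for pr in pairs:
                if pr.prev_key not in self.images or pr.prev_key not in self._owner:
                    raise ValueError(f"pair references unknown previous image {pr.prev_key}")
        for pr in pairs:
            if pr.curr_key not in {im.key for im in curr_images}:
                raise ValueError(f"pair references unknown current image {pr.curr_key}")

        events_before = len(self.events)
        pair_set = list(pairs)

        # --- collisions first: a current image claimed by >= 2 tracks.
        by_curr: dict[ImageKey, list[ImagePair]] = {}
        for pr in pair_set:
            by_curr.setdefault(pr.curr_key, []).append(pr)
        removed_pairs: set[ImagePair] = set()
        for curr_key in sorted(by_curr):
            prs = by_curr[curr_key]
            track_ids = sorted({self._owner[pr.prev_key] for pr in prs})
            live_ids = [i for i in track_ids if self.tracks[i].status == "alive"]
            if len(live_ids) < 2:
                continue
            # Survivor: track owning the largest-mass previous image;
            # tie -> oldest (smallest lcr_id).
            def prev_mass(tid: int) -> float:
                return max(
                    self.images[pr.prev_key].signal_mass_nmol
                    for pr in prs
                    if self._owner[pr.prev_key] == tid
                )

            survivor = min(live_ids, key=lambda tid: (-prev_mass(tid), tid))
            for tid in live_ids:
                if tid == survivor:
                    continue
                loser = self.tracks[tid]
                self._kill(loser, "collision", frame - 1)
                self.events.append(
                    TrackEvent(
                        "death_collision",
                        frame,
                        (tid, survivor),
                        (curr_key,),
                    )
                )
                # Collision has priority: the loser's pairs are removed
                # before separation processing.
                for pr in pair_set:
                    if self._owner[pr.prev_key] == tid:
                        removed_pairs.add(pr)
        pair_set = [pr for pr in pair_set if pr not in removed_pairs]

        # --- assign current images to tracks; detect separations and
        #     intra-track thread merges.
        by_prev: dict[ImageKey, list[ImagePair]] = {}
        by_curr = {}
        for pr in pair_set:
            by_prev.setdefault(pr.prev_key, []).append(pr)
            by_curr.setdefault(pr.curr_key, []).append(pr)

        curr_sorted = sorted(curr_images, key=lambda im: im.key)
        for im in curr_sorted:
            prs = by_curr.get(im.key, [])
            if not prs:
                self._birth(im)
                continue
            owner_ids = sorted({self._owner[pr.prev_key] for pr in prs})
            # After collision resolution at most one live track remains.
            tid = owner_ids[0]
            track = self.tracks[tid]
            track._add_image(im.key)
            self._owner[im.key] = tid
            prev_keys = sorted({pr.prev_key for pr in prs})
            # Threads of this track whose tip is one of prev_keys.
            tip_threads = sorted(
                t for t, tip in track._live_threads.items() if tip in prev_keys
            )
            if len(tip_threads) >= 2:
                # One current image continues several threads of the same
                # track: merge them into the lowest-id thread.
                keep = tip_threads[0]
                for t in tip_threads[1:]:
                    track._live_threads.pop(t, None)
                track.threads[keep].append(im.key)
                track._live_threads[keep] = im.key
                self.events.append(
                    TrackEvent("intra_thread_merge", frame, (tid,), (im.key,))
                )

        # Separations: one previous image linked to several current images.
        for prev_key in sorted(by_prev):
            prs = by_prev[prev_key]
            curr_keys = sorted({pr.curr_key for pr in prs})
            if len(curr_keys) < 2:
                continue
            tid = self._owner[prev_key]
            track = self.tracks[tid]
            # The thread that ended at prev_key continues with the first
            # current image; each further image starts a new thread.
            base_threads = [
                t for t, tip in track._live_threads.items() if tip == prev_key
            ]
            first, rest = curr_keys[0], curr_keys[1:]
            if base_threads:
                t0 = min(base_threads)
                if track._live_threads[t0] == prev_key:
                    track.threads[t0].append(first)
                    track._live_threads[t0] = first
            for ck in rest:
                track._new_thread(ck)
            track.n_separations += 1
            self.events.append(
                TrackEvent(
                    "separation", frame, (tid,), tuple([prev_key] + curr_keys)
                )
            )

        # Ordinary one-to-one continuations: advance thread tips.
        handled = set()
        for pr in pair_set:
            curr_keys_of_prev = {p.curr_key for p in by_prev[pr.prev_key]}
            if len(curr_keys_of_prev) != 1:
                continue  # separation handled above
            tid = self._owner[pr.prev_key]
            track = self.tracks[tid]
            if (tid, pr.prev_key) in handled:
                continue
            handled.add((tid, pr.prev_key))
            for t, tip in list(track._live_threads.items()):
                if tip == pr.prev_key:
                    if track._live_threads[t] != pr.curr_key:
                        track.threads[t].append(pr.curr_key)
                        track._live_threads[t] = pr.curr_key

        # --- attrition: threads whose tip found no partner end; a track
        #     dies only when all of its threads have ended.
        matched_prev = {pr.prev_key for pr in pair_set}
        for tid in sorted(self.tracks):
            track = self.tracks[tid]
            if track.status != "alive":
                continue
            for t, tip in list(track._live_threads.items()):
                if tip[0] == frame - 1 and tip not in matched_prev:
                    del track._live_threads[t]
                elif tip[0] < frame - 1:
                    # Stale tip (thread already ended earlier).
                    del track._live_threads[t]
            if not track._live_threads:
                last = track.last_frame
                self._kill(track, "attrition", last)
                self.events.append(
                    TrackEvent("death_attrition", frame, (tid,), ())
                )

        self._prev_images = list(curr_sorted)
        return self.events[events_before:]

    def finalize(self, last_frame: int | None = None) -> list[LCRTrack]:
        """Close out tracks still alive after the last processed frame."""
        if last_frame is None:
            last_frame = self._last_frame_seen if self._last_frame_seen is not None else 0
        for tid in sorted(self.tracks):
            track = self.tracks[tid]
            if track.status == "alive":
                track.status = "dead"
                track.termination = "alive_at_end"
                track.death_frame = track.last_frame
                track._live_threads.clear()
                self.events.append(TrackEvent("alive_at_end", last_frame, (tid,), ()))
        return [self.tracks[i] for i in sorted(self.tracks)]


@dataclass
class TrackingResult:
    """Everything the tracker produced for one stack."""

    stack: FrameStack
    config: SegmentationConfig
    tracks: list[LCRTrack]
    events: list[TrackEvent]
    images: dict[ImageKey, LCRImage]
    images_by_frame: dict[int, list[LCRImage]]

    def track_class(self, lcr_id: int) -> str:
        return classify_track(self._track_by_id(lcr_id), self.images)

    def _track_by_id(self, lcr_id: int) -> LCRTrack:
        for t in self.tracks:
            if t.lcr_id == lcr_id:
                return t
        raise KeyError(lcr_id)


def track_stack(
    stack: FrameStack,
    config: SegmentationConfig | None = None,
    frame_range: tuple[int, int] | None = None,
) -> TrackingResult:
    """Segment every frame of a stack and track the images through time.

    ``frame_range`` (start, end), inclusive, restricts analysis to a
    window of the stack (e.g. the diastolic MDP-to-threshold window).
    """
    config = config or SegmentationConfig()
    if stack.periodic_x and not config.periodic_x:
        config = replace(config, periodic_x=True)
    start, end = (0, stack.n_frames - 1) if frame_range is None else frame_range
    if not (0 <= start <= end < stack.n_frames):
        raise ValueError(f"invalid frame range ({start}, {end}) for {stack.n_frames} frames")
    tracker = Tracker()
    images_by_frame: dict[int, list[LCRImage]] = {}
    for k in range(start, end + 1):
        imgs = segment_frame(stack.frame(k), k, config, stack.voxel_edge_nm)
        images_by_frame[k] = imgs
        tracker.step(imgs)
    tracks = tracker.finalize(end)
    return TrackingResult(
        stack=stack,
        config=config,
        tracks=tracks,
        events=tracker.events,
        images=tracker.images,
        images_by_frame=images_by_frame,
    )
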