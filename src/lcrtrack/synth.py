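"""Synthetic frame-stack generator with exact ground truth.

Scenarios render scripted release events — isotropic Gaussian blobs with
per-frame centre, amplitude, and width trajectories — on top of a uniform,
exponentially decaying background emulating the tail of the action-
potential-induced Ca transient:

    B(t) = B_rest + (B0 − B_rest) · exp(−t / τ)

The generator emulates only the statistical *appearance* of local release
events (blob-like footprints that appear, move, merge, separate and
vanish); it is not a reaction-diffusion or release-channel model.  Frames
are noise-free by default, matching the character of simulation output;
optional Gaussian noise can be added for robustness experiments.

Everything is deterministic given the scenario seed, and every scenario
serializes its exact ground truth (birth/end frames, peak amplitudes,
per-frame footprints, scheduled merges/splits) so detection and tracking
can be validated without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frames_io import FrameStack

__all__ = [
    "EventScript",
    "Scenario",
    "GroundTruth",
    "render",
    "make_merge_scenario",
    "make_split_scenario",
    "make_population_scenario",
]

# A blob's "footprint" for ground-truth bookkeeping: voxels where the
# event's own contribution exceeds exp(-2) of its amplitude (~2 sigma).
_FOOTPRINT_LEVEL = math.exp(-2.0)


@dataclass(frozen=True)
class EventScript:
    """One scripted release event.

    Trajectories are arrays of length ``end_frame − birth_frame + 1``
    (frames inclusive): centre (row, col) in voxels, amplitude in μM,
    width σ in voxels.  Scalars are broadcast to constant trajectories.
    """

    event_id: int
    birth_frame: int
    end_frame: int
    row: np.ndarray
    col: np.ndarray
    amplitude: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        n = self.end_frame - self.birth_frame + 1
        if n < 1:
            raise ValueError("end_frame must be >= birth_frame")
        for name in ("row", "col", "amplitude", "sigma"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=np.float64), (n,)).copy()
            object.__setattr__(self, name, arr)
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitude must stay positive while the event is alive")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must stay positive while the event is alive")

    @property
    def n_live_frames(self) -> int:
        return self.end_frame - self.birth_frame + 1

    def alive_at(self, frame: int) -> bool:
        return self.birth_frame <= frame <= self.end_frame

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "birth_frame": self.birth_frame,
            "end_frame": self.end_frame,
            "row": self.row.tolist(),
            "col": self.col.tolist(),
            "amplitude": self.amplitude.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventScript":
        return cls(
            event_id=int(d["event_id"]),
            birth_frame=int(d["birth_frame"]),
            end_frame=int(d["end_frame"]),
            row=np.asarray(d["row"], dtype=np.float64),
            col=np.asarray(d["col"], dtype=np.float64),
            amplitude=np.asarray(d["amplitude"], dtype=np.float64),
            sigma=np.asarray(d["sigma"], dtype=np.float64),
        )


@dataclass
class Scenario:
    """A complete synthetic recording description.

    Background defaults emulate a diastolic transient tail: resting Ca
    just below 0.1 μM, decaying from 0.5 μM with a ~150 ms time constant.
    Noise defaults to zero (simulation output is noise-free).
    """

    height: int = 64
    width: int = 64
    n_frames: int = 100
    dt_ms: float = 5.0
    voxel_edge_nm: float = 100.0
    b_rest: float = 0.09
    b0: float = 0.5
    tau_ms: float = 150.0
    events: list[EventScript] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    periodic_x: bool = False

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1 or self.n_frames < 1:
            raise ValueError("grid and frame counts must be >= 1")
        if self.b_rest <= 0 or self.b0 <= 0 or self.tau_ms <= 0:
            raise ValueError("background parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def background(self, frame: int) -> float:
        t = frame * self.dt_ms
        return self.b_rest + (self.b0 - self.b_rest) * math.exp(-t / self.tau_ms)

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "width": self.width,
            "n_frames": self.n_frames,
            "dt_ms": self.dt_ms,
            "voxel_edge_nm": self.voxel_edge_nm,
            "b_rest": self.b_rest,
            "b0": self.b0,
            "tau_ms": self.tau_ms,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "periodic_x": self.periodic_x,
            "events": [e.to_dict() for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        events = [EventScript.from_dict(e) for e in d.pop("events", [])]
        return cls(events=events, **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    """Exact per-event truth for a rendered scenario."""

    events: list[dict]  # event_id, birth_frame, end_frame, peak_amplitude_uM
    footprints: dict[int, dict[int, list[tuple[int, int]]]]  # event -> frame -> voxels
    merges: list[dict] = field(default_factory=list)  # {"frame", "event_ids"}
    splits: list[dict] = field(default_factory=list)  # {"frame", "event_id"}

    def to_dict(self) -> dict:
        return {
            "events": self.events,
            "footprints": {
                str(eid): {str(f): [list(v) for v in vox] for f, vox in per_frame.items()}
                for eid, per_frame in self.footprints.items()
            },
            "merges": self.merges,
            "splits": self.splits,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _blob(
    height: int,
    width: int,
    row: float,
    col: float,
    amplitude: float,
    sigma: float,
    periodic_x: bool,
) -> np.ndarray:
    rr = np.arange(height, dtype=np.float64)[:, None] - row
    cc = np.arange(width, dtype=np.float64)[None, :] - col
    if periodic_x:
        cc = (cc + width / 2.0) % width - width / 2.0
    d2 = rr**2 + cc**2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def render(scenario: Scenario) -> tuple[FrameStack, GroundTruth]:
    """Render a scenario into a frame stack plus its ground truth.

    frame(t) = B(t) + Σ_events A(t)·exp(−d²/2σ(t)²) + noise.  Identical
    scenarios (including seed) render bit-identical stacks.
    """
    h, w = scenario.height, scenario.width
    data = np.empty((scenario.n_frames, h, w), dtype=np.float64)
    footprints: dict[int, dict[int, list[tuple[int, int]]]] = {}
    gt_events: list[dict] = []
    for ev in scenario.events:
        if ev.birth_frame < 0 or ev.end_frame >= scenario.n_frames:
            raise ValueError(
                f"event {ev.event_id} lives outside the scenario's {scenario.n_frames} frames"
            )
        if not scenario.periodic_x and (
            np.any(ev.col < 0) or np.any(ev.col > w - 1)
        ):
            raise ValueError(f"event {ev.event_id} leaves the grid (periodic_x is off)")
        if np.any(ev.row < 0) or np.any(ev.row > h - 1):
            raise ValueError(f"event {ev.event_id} leaves the grid vertically")
        footprints[ev.event_id] = {}
        gt_events.append(
            {
                "event_id": ev.event_id,
                "birth_frame": ev.birth_frame,
                "end_frame": ev.end_frame,
                "peak_amplitude_uM": float(ev.amplitude.max()),
            }
        )

    for k in range(scenario.n_frames):
        frame = np.full((h, w), scenario.background(k), dtype=np.float64)
        for ev in scenario.events:
            if not ev.alive_at(k):
                continue
            i = k - ev.birth_frame
            blob = _blob(
                h, w, ev.row[i], ev.col[i], ev.amplitude[i], ev.sigma[i], scenario.periodic_x
            )
            frame += blob
            mask = blob > ev.amplitude[i] * _FOOTPRINT_LEVEL
            footprints[ev.event_id][k] = [
                (int(r), int(c)) for r, c in zip(*np.nonzero(mask))
            ]
        data[k] = frame

    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        data += rng.normal(0.0, scenario.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    stack = FrameStack(
        data,
        dt_ms=scenario.dt_ms,
        voxel_edge_nm=scenario.voxel_edge_nm,
        periodic_x=scenario.periodic_x,
    )
    return stack, GroundTruth(events=gt_events, footprints=footprints)


def _linspace_traj(a: float, b: float, n: int) -> np.ndarray:
    return np.linspace(a, b, n)


def make_merge_scenario(
    height: int = 48,
    width: int = 64,
    n_frames: int = 20,
    amp_large: float = 3.0,
    amp_small: float = 2.0,
    sigma: float = 2.5,
    start_gap: float = 30.0,
    end_gap: float = 3.0,
    seed: int = 0,
) -> Scenario:
    """Two events converging until their footprints fuse.

    The larger-amplitude blob should survive the resulting collision; the
    smaller should be terminated by collision when one detected image first
    spans both previous footprints.
    """
    n = n_frames
    mid_r = height / 2.0
    mid_c = (width - 1) / 2.0
    ev_a = EventScript(
        event_id=0,
        birth_frame=0,
        end_frame=n - 1,
        row=mid_r,
        col=_linspace_traj(mid_c - start_gap / 2.0, mid_c - end_gap / 2.0, n),
        amplitude=amp_large,
        sigma=sigma,
    )
    ev_b = EventScript(
        event_id=1,
        birth_frame=0,
        end_frame=n - 1,
        row=mid_r,
        col=_linspace_traj(mid_c + start_gap / 2.0, mid_c + end_gap / 2.0, n),
        amplitude=amp_small,
        sigma=sigma,
    )
    sc = Scenario(
        height=height, width=width, n_frames=n, events=[ev_a, ev_b], seed=seed,
        b_rest=0.05, b0=0.05, tau_ms=1e9,
    )
    return sc


def make_split_scenario(
    height: int = 48,
    width: int = 64,
    n_frames: int = 20,
    amplitude: float = 3.0,
    sigma: float = 2.5,
    start_gap: float = 3.0,
    end_gap: float = 30.0,
    seed: int = 0,
) -> Scenario:
    """One release whose supra-mean footprint becomes disconnected.

    Rendered as two equal blobs that start fused (one connected image,
    hence one LCR at birth) and drift apart; the detected track should
    record exactly one separation and end with two threads.
    """
    n = n_frames
    mid_r = height / 2.0
    mid_c = (width - 1) / 2.0
    ev_a = EventScript(
        event_id=0,
        birth_frame=0,
        end_frame=n - 1,
        row=mid_r,
        col=_linspace_traj(mid_c - start_gap / 2.0, mid_c - end_gap / 2.0, n),
        amplitude=amplitude,
        sigma=sigma,
    )
    ev_b = EventScript(
        event_id=1,
        birth_frame=0,
        end_frame=n - 1,
        row=mid_r,
        col=_linspace_traj(mid_c + start_gap / 2.0, mid_c + end_gap / 2.0, n),
        amplitude=amplitude,
        sigma=sigma,
    )
    sc = Scenario(
        height=height, width=width, n_frames=n, events=[ev_a, ev_b], seed=seed,
        b_rest=0.05, b0=0.05, tau_ms=1e9,
    )
    return sc


def make_population_scenario(
    n_events: int = 30,
    height: int = 64,
    width: int = 64,
    n_frames: int = 200,
    seed: int = 0,
    amp_range: tuple[float, float] = (2.0, 5.0),
    sigma_range: tuple[float, float] = (1.5, 3.0),
    duration_frames: tuple[int, int] = (4, 12),
    min_distance: float = 20.0,
    noise_sd: float = 0.0,
) -> Scenario:
    """A population of static, non-interacting release events.

    Events are placed by rejection sampling so that any two whose lifetimes
    overlap (±1 frame) keep at least ``min_distance`` voxels between their
    centres — far enough, at the default amplitudes and widths, that their
    supra-mean footprints never touch.  Amplitudes and widths are constant
    per event, so detected births, deaths, and peak amplitudes can be
    compared with the script exactly.
    """
    rng = np.random.default_rng(seed)
    margin = 10.0
    events: list[EventScript] = []
    placed: list[tuple[float, float, int, int]] = []  # row, col, birth, end
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place all events; relax min_distance or grid size")
        birth = int(rng.integers(1, n_frames - duration_frames[1] - 2))
        dur = int(rng.integers(duration_frames[0], duration_frames[1] + 1))
        end = birth + dur - 1
        r = float(rng.uniform(margin, height - 1 - margin))
        c = float(rng.uniform(margin, width - 1 - margin))
        ok = True
        for pr, pc, pb, pe in placed:
            if birth <= pe + 1 and pb <= end + 1:  # lifetimes overlap (±1 frame)
                if math.hypot(r - pr, c - pc) < min_distance:
                    ok = False
                    break
        if not ok:
            continue
        amp = float(rng.uniform(*amp_range))
        sig = float(rng.uniform(*sigma_range))
        events.append(
            EventScript(
                event_id=len(events),
                birth_frame=birth,
                end_frame=end,
                row=r,
                col=c,
                amplitude=amp,
                sigma=sig,
            )
        )
        placed.append((r, c, birth, end))
    return Scenario(
        height=height,
        width=width,
        n_frames=n_frames,
        events=events,
        seed=seed,
        noise_sd=noise_sd,
    )
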