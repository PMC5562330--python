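"""Per-LCR statistics and ensemble summaries.

For each finalized track the module computes:

* signal mass (nmol·ms) — the sum of the signal masses of all constituent
  images multiplied by the frame interval;
* path area (μm²) — the area of the union of every voxel the LCR ever
  occupied (a static event's path area is independent of its duration);
* max amplitude (μM) — the largest [Ca] reached anywhere in the LCR over
  its lifetime;
* duration (ms) — inclusive frame count × dt, so a single-frame event
  lasts one frame interval, not zero;
* birth time (ms) — frames since the start of the analysis window.

``summarize`` aggregates these into a per-class (all / complex / simple)
table with counts, totals, means, the complex-collision count, and
histogram data for birth time and signal mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frames_io import FrameStack
from .segmentation import LCRImage
from .tracking import ImageKey, LCRTrack, TrackEvent, TrackingResult, classify_track

__all__ = [
    "LCRMetrics",
    "SummaryTable",
    "lcr_signal_mass",
    "lcr_path_area",
    "lcr_duration_birth",
    "lcr_max_amplitude",
    "compute_metrics",
    "metrics_frame",
    "summarize",
]


@dataclass(frozen=True)
class LCRMetrics:
    """The statistics of one dynamic LCR."""

    lcr_id: int
    lcr_class: str  # "simple" | "complex"
    signal_mass_nmol_ms: float
    path_area_um2: float
    max_amplitude_uM: float
    duration_ms: float
    birth_time_ms: float
    birth_frame: int
    n_threads: int
    n_separations: int
    termination: str


def lcr_signal_mass(
    track: LCRTrack, images: dict[ImageKey, LCRImage], dt_ms: float
) -> float:
    """Σ image signal masses (nmol) × frame interval (ms) → nmol·ms."""
    return sum(images[k].signal_mass_nmol for k in track.image_keys) * dt_ms


def lcr_path_area(
    track: LCRTrack, images: dict[ImageKey, LCRImage], voxel_edge_nm: float
) -> float:
    """Area of the union of all voxels the LCR ever occupied, in μm²."""
    union: set[tuple[int, int]] = set()
    for k in track.image_keys:
        union |= images[k].voxels
    return len(union) * (voxel_edge_nm / 1000.0) ** 2


def lcr_duration_birth(
    track: LCRTrack, dt_ms: float, window_start_frame: int = 0
) -> tuple[float, float]:
    """(duration_ms, birth_time_ms) of a finalized track.

    Duration counts frames inclusively: (last − birth + 1) × dt.  Birth
    time is measured from the window start (the MDP frame in a diastolic
    analysis).
    """
    last = track.death_frame if track.death_frame is not None else track.last_frame
    duration = (last - track.birth_frame + 1) * dt_ms
    birth_time = (track.birth_frame - window_start_frame) * dt_ms
    return duration, birth_time


def lcr_max_amplitude(track: LCRTrack, images: dict[ImageKey, LCRImage]) -> float:
    """Maximum [Ca] (μM) reached by the LCR during its lifetime."""
    return max(images[k].max_amplitude for k in track.image_keys)


def compute_metrics(
    result: TrackingResult, window_start_frame: int | None = None
) -> list[LCRMetrics]:
    """Per-LCR metrics for every track of a tracking result."""
    stack = result.stack
    if window_start_frame is None:
        window_start_frame = min(
            (t.birth_frame for t in result.tracks), default=0
        )
        # Default the window start to the first analyzed frame.
        if result.images_by_frame:
            window_start_frame = min(result.images_by_frame)
    out: list[LCRMetrics] = []
    for track in result.tracks:
        duration, birth_time = lcr_duration_birth(track, stack.dt_ms, window_start_frame)
        out.append(
            LCRMetrics(
                lcr_id=track.lcr_id,
                lcr_class=classify_track(track, result.images),
                signal_mass_nmol_ms=lcr_signal_mass(track, result.images, stack.dt_ms),
                path_area_um2=lcr_path_area(track, result.images, stack.voxel_edge_nm),
                max_amplitude_uM=lcr_max_amplitude(track, result.images),
                duration_ms=duration,
                birth_time_ms=birth_time,
                birth_frame=track.birth_frame,
                n_threads=track.n_threads,
                n_separations=track.n_separations,
                termination=track.termination,
            )
        )
    return out


def metrics_frame(metrics: Sequence[LCRMetrics]) -> pd.DataFrame:
    """Metrics as a tidy DataFrame, one row per LCR."""
    return pd.DataFrame(
        [
            {
                "lcr_id": m.lcr_id,
                "class": m.lcr_class,
                "signal_mass_nmol_ms": m.signal_mass_nmol_ms,
                "path_area_um2": m.path_area_um2,
                "max_amplitude_uM": m.max_amplitude_uM,
                "duration_ms": m.duration_ms,
                "birth_time_ms": m.birth_time_ms,
                "birth_frame": m.birth_frame,
                "n_threads": m.n_threads,
                "n_separations": m.n_separations,
                "termination": m.termination,
            }
            for m in metrics
        ]
    )


@dataclass
class SummaryTable:
    """Per-class ensemble aggregates (classes: all, complex, simple).

    ``per_class[cls]`` holds count, total_signal_mass_nmol_ms,
    signal_mass_per_lcr_nmol_ms, avg_path_area_um2, avg_max_amplitude_uM,
    avg_duration_ms, avg_birth_time_ms.  Averages over an empty class are
    NaN; totals are 0.
    """

    per_class: dict[str, dict[str, float]]
    total_complex_collisions: int
    birth_time_hist: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (counts, edges)
    signal_mass_hist: dict[str, tuple[np.ndarray, np.ndarray]]
    excluded_frame0_births: int = 0

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "total_complex_collisions": self.total_complex_collisions,
            "excluded_frame0_births": self.excluded_frame0_births,
        }


def _class_stats(rows: pd.DataFrame, birth_rows: pd.DataFrame) -> dict[str, float]:
    n = len(rows)
    total_mass = float(rows["signal_mass_nmol_ms"].sum()) if n else 0.0
    return {
        "count": n,
        "total_signal_mass_nmol_ms": total_mass,
        "signal_mass_per_lcr_nmol_ms": total_mass / n if n else float("nan"),
        "avg_path_area_um2": float(rows["path_area_um2"].mean()) if n else float("nan"),
        "avg_max_amplitude_uM": float(rows["max_amplitude_uM"].mean()) if n else float("nan"),
        "avg_duration_ms": float(rows["duration_ms"].mean()) if n else float("nan"),
        "avg_birth_time_ms": (
            float(birth_rows["birth_time_ms"].mean()) if len(birth_rows) else float("nan")
        ),
    }


def summarize(
    metrics: Sequence[LCRMetrics] | pd.DataFrame,
    events: Sequence[TrackEvent] | None = None,
    exclude_frame0_births: bool = True,
    birth_time_bin_ms: float = 25.0,
    complex_collision_rule: str = "survivor",
) -> SummaryTable:
    """Aggregate per-LCR metrics into a per-class summary table.

    Tracks born in the very first analyzed frame are pre-existing releases
    adopted as new; with ``exclude_frame0_births`` they are dropped from the
    birth-time averages and histograms (counts and masses still include
    them).  Complex collisions are collision events whose surviving LCR is
    classified complex (``complex_collision_rule="survivor"``); with
    ``"either"`` a collision counts if either participant is complex.

    Birth-time histograms use fixed-width bins (default 25 ms); signal-mass
    histograms use log-spaced decade edges spanning the observed range.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if df.empty:
        df = metrics_frame([])
        empty = pd.DataFrame(columns=["signal_mass_nmol_ms", "path_area_um2",
                                      "max_amplitude_uM", "duration_ms", "birth_time_ms"])
        zero = _class_stats(empty, empty)
        return SummaryTable(
            per_class={"all": dict(zero), "complex": dict(zero), "simple": dict(zero)},
            total_complex_collisions=0,
            birth_time_hist={},
            signal_mass_hist={},
        )

    if exclude_frame0_births:
        # Birth time 0 == born in the window's first frame (the "0 bin"
        # of pre-existing releases adopted as new).
        birth_mask = df["birth_time_ms"] > 0
    else:
        birth_mask = pd.Series(True, index=df.index)

    per_class: dict[str, dict[str, float]] = {}
    birth_hist: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mass_hist: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in ("all", "complex", "simple"):
        rows = df if cls == "all" else df[df["class"] == cls]
        brows = rows[birth_mask.reindex(rows.index, fill_value=False)]
        per_class[cls] = _class_stats(rows, brows)
        if len(brows):
            bmax = float(brows["birth_time_ms"].max())
            edges = np.arange(0.0, bmax + birth_time_bin_ms, birth_time_bin_ms)
            if len(edges) < 2:
                edges = np.array([0.0, birth_time_bin_ms])
            counts, edges = np.histogram(brows["birth_time_ms"], bins=edges)
            birth_hist[cls] = (counts, edges)
        masses = rows["signal_mass_nmol_ms"].to_numpy()
        masses = masses[masses > 0]
        if masses.size:
            lo = math.floor(math.log10(masses.min()))
            hi = math.ceil(math.log10(masses.max()))
            if hi <= lo:
                hi = lo + 1
            edges = np.logspace(lo, hi, (hi - lo) * 4 + 1)
            counts, edges = np.histogram(masses, bins=edges)
            mass_hist[cls] = (counts, edges)

    n_collisions = 0
    if events is not None:
        cls_by_id = dict(zip(df["lcr_id"], df["class"]))
        for ev in events:
            if ev.kind != "death_collision":
                continue
            loser, survivor = ev.lcr_ids[0], ev.lcr_ids[1]
            if complex_collision_rule == "survivor":
                if cls_by_id.get(survivor) == "complex":
                    n_collisions += 1
            elif complex_collision_rule == "either":
                if "complex" in (cls_by_id.get(survivor), cls_by_id.get(loser)):
                    n_collisions += 1
            else:
                raise ValueError(f"unknown complex_collision_rule {complex_collision_rule!r}")

    return SummaryTable(
        per_class=per_class,
        total_complex_collisions=n_collisions,
        birth_time_hist=birth_hist,
        signal_mass_hist=mass_hist,
        excluded_frame0_births=int((~birth_mask).sum()),
    )
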