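"""Tabular views of detection and tracking output, ready for export."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import LCRImage
from .tracking import LCRTrack, TrackEvent, TrackingResult, classify_track
from .metrics import SummaryTable

__all__ = [
    "images_table",
    "track_table",
    "event_table",
    "label_stack",
    "summary_histograms",
]


def images_table(images_by_frame: Mapping[int, Sequence[LCRImage]]) -> pd.DataFrame:
    """One row per detected LCR image."""
    rows = []
    for frame in sorted(images_by_frame):
        for im in images_by_frame[frame]:
            cr, cc = im.centroid
            rows.append(
                {
                    "frame_index": frame,
                    "image_id": im.image_id,
                    "n_voxels": len(im.voxels),
                    "n_peaks": im.n_peaks,
                    "is_complex": im.is_complex,
                    "signal_mass_nmol": im.signal_mass_nmol,
                    "max_amplitude_uM": im.max_amplitude,
                    "centroid_row": cr,
                    "centroid_col": cc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame_index", "image_id", "n_voxels", "n_peaks", "is_complex",
            "signal_mass_nmol", "max_amplitude_uM", "centroid_row", "centroid_col",
        ],
    )


def track_table(result: TrackingResult) -> pd.DataFrame:
    """One row per dynamic LCR."""
    rows = []
    for t in result.tracks:
        rows.append(
            {
                "lcr_id": t.lcr_id,
                "class": classify_track(t, result.images),
                "birth_frame": t.birth_frame,
                "death_frame": t.death_frame,
                "termination": t.termination,
                "n_threads": t.n_threads,
                "n_separations": t.n_separations,
                "n_images": len(t.image_keys),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lcr_id", "class", "birth_frame", "death_frame", "termination",
            "n_threads", "n_separations", "n_images",
        ],
    )


def event_table(events: Sequence[TrackEvent]) -> pd.DataFrame:
    """The event log: one row per birth/death/collision/separation."""
    rows = [
        {
            "frame": ev.frame,
            "kind": ev.kind,
            "lcr_ids": ";".join(str(i) for i in ev.lcr_ids),
            "image_ids": ";".join(f"{f}:{i}" for f, i in ev.image_ids),
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=["frame", "kind", "lcr_ids", "image_ids"])


def label_stack(result: TrackingResult) -> np.ndarray:
    """Integer label volume: voxel -> lcr_id + 1 (0 = background)."""
    stack = result.stack
    labels = np.zeros((stack.n_frames, stack.height, stack.width), dtype=np.int32)
    owner: dict = {}
    for t in result.tracks:
        for key in t.image_keys:
            owner[key] = t.lcr_id
    for key, im in result.images.items():
        lid = owner.get(key)
        if lid is None:
            continue
        for r, c in im.voxels:
            labels[key[0], r, c] = lid + 1
    return labels


def summary_histograms(summary: SummaryTable) -> dict[str, pd.DataFrame]:
    """Histogram data as DataFrames keyed 'birth_time_<class>' / 'signal_mass_<class>'."""
    out: dict[str, pd.DataFrame] = {}
    for name, hists in (
        ("birth_time", summary.birth_time_hist),
        ("signal_mass", summary.signal_mass_hist),
    ):
        for cls, (counts, edges) in hists.items():
            out[f"{name}_{cls}"] = pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            )
    return out
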