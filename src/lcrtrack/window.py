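"""Diastolic analysis-window selection from a membrane-potential trace.

The window runs from the maximal diastolic potential (MDP, the most
negative Vm of the cycle) to the first upward crossing of a threshold
(default −50 mV, the level at which L-type Ca channels activate and the
action-potential-induced Ca transient begins).  Within this window the
releases are purely spontaneous diastolic events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames_io import VoltageTrace

__all__ = ["AnalysisWindow", "select_window"]


@dataclass(frozen=True)
class AnalysisWindow:
    """Frame indices and times of the MDP-to-threshold window."""

    start_frame: int
    end_frame: int
    t_mdp_ms: float
    t_threshold_ms: float
    threshold_mV: float

    def to_dict(self) -> dict:
        return {
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
            "t_mdp_ms": self.t_mdp_ms,
            "t_threshold_ms": self.t_threshold_ms,
            "threshold_mV": self.threshold_mV,
        }


def _cycle_bounds(trace: VoltageTrace, cycle_index: int) -> tuple[int, int]:
    """Sample-index bounds of one pacemaker cycle.

    Cycles are delimited by action-potential peaks: local Vm maxima above
    0 mV.  With fewer than two such peaks the whole trace is one cycle.
    """
    v = trace.vm_mV
    peaks = [
        i
        for i in range(1, len(v) - 1)
        if v[i] > 0 and v[i] >= v[i - 1] and v[i] > v[i + 1]
    ]
    if len(peaks) < 2:
        if cycle_index != 0:
            raise ValueError(f"trace has a single cycle; cycle_index {cycle_index} invalid")
        return 0, len(v) - 1
    bounds = [0] + peaks + [len(v) - 1]
    n_cycles = len(bounds) - 1
    if not 0 <= cycle_index < n_cycles:
        raise ValueError(f"cycle_index {cycle_index} out of range (trace has {n_cycles} cycles)")
    return bounds[cycle_index], bounds[cycle_index + 1]


def select_window(
    trace: VoltageTrace,
    threshold_mV: float = -50.0,
    stack_dt_ms: float = 5.0,
    stack_t0_ms: float = 0.0,
    n_frames: int | None = None,
    cycle_index: int = 0,
) -> AnalysisWindow:
    """Locate the MDP-to-threshold window and map it onto the frame grid.

    The MDP is the minimum Vm within the selected cycle (ties resolved to
    the earliest sample).  The end is the first upward crossing of the
    threshold after the MDP, located by linear interpolation between the
    bracketing samples.  Times are mapped to frames by rounding to the
    stack's grid (frame k at ``stack_t0_ms + k * stack_dt_ms``).

    Raises ``ValueError`` when Vm never rises above the threshold after
    the MDP, or when the mapped frames fall outside a stack of ``n_frames``.
    """
    lo, hi = _cycle_bounds(trace, cycle_index)
    t = trace.t_ms
    v = trace.vm_mV
    seg_v = v[lo : hi + 1]
    i_mdp = lo + int(np.argmin(seg_v))  # argmin returns the earliest tie
    t_mdp = float(t[i_mdp])

    t_cross = None
    for i in range(i_mdp, hi):
        if v[i] <= threshold_mV < v[i + 1]:
            frac = (threshold_mV - v[i]) / (v[i + 1] - v[i])
            t_cross = float(t[i] + frac * (t[i + 1] - t[i]))
            break
        if v[i] > threshold_mV:
            # Already above threshold right at the MDP sample.
            t_cross = float(t[i])
            break
    if t_cross is None:
        raise ValueError(
            f"membrane potential never crosses {threshold_mV} mV after the MDP"
        )

    start_frame = int(round((t_mdp - stack_t0_ms) / stack_dt_ms))
    end_frame = int(round((t_cross - stack_t0_ms) / stack_dt_ms))
    if end_frame < start_frame:
        end_frame = start_frame
    if n_frames is not None:
        if not (0 <= start_frame < n_frames) or not (0 <= end_frame < n_frames):
            raise ValueError(
                f"window frames [{start_frame}, {end_frame}] fall outside the "
                f"{n_frames}-frame stack (is the trace aligned with the stack?)"
            )
    return AnalysisWindow(
        start_frame=start_frame,
        end_frame=end_frame,
        t_mdp_ms=t_mdp,
        t_threshold_ms=t_cross,
        threshold_mV=threshold_mV,
    )
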