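"""Frame-stack and voltage-trace I/O with explicit calibration metadata.

Conventions are fixed throughout the package: [Ca] in μM, time in ms, voxel
edge in nm; 0-based (row, col) coordinates with row 0 at the top; frame k
lies at time ``k * dt_ms`` relative to the start of the stack.  Loaders
never rescale or guess units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "Frame",
    "FrameStack",
    "VoltageTrace",
    "load_stack",
    "write_stack",
    "load_voltage",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass(frozen=True)
class Frame:
    """A single 2D image of instantaneous [Ca] (μM) per submembrane voxel."""

    values: np.ndarray  # 2D float array, μM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"frame must be a 2D matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("frame contains non-finite [Ca] values")
        if np.any(v < 0):
            raise ValueError("frame contains negative [Ca] values")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class FrameStack:
    """Time-ordered stack of equally shaped frames with calibration.

    Parameters
    ----------
    data : array, shape (n_frames, height, width)
        Instantaneous [Ca] per voxel, μM.
    dt_ms : float
        Frame interval, ms.
    voxel_edge_nm : float
        Edge length of the cubic voxel, nm.
    periodic_x : bool
        Wrap-around in the column (cell-perimeter) dimension.
    """

    data: np.ndarray
    dt_ms: float = 5.0
    voxel_edge_nm: float = 100.0
    periodic_x: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 3 or d.shape[0] < 1:
            raise ValueError(
                f"stack must be (n_frames, height, width) with >= 1 frame, got shape {d.shape}"
            )
        if d.shape[1] < 1 or d.shape[2] < 1:
            raise ValueError(f"frames must be at least 1x1, got shape {d.shape[1:]}")
        if not np.all(np.isfinite(d)):
            raise ValueError("stack contains non-finite [Ca] values")
        if np.any(d < 0):
            raise ValueError("stack contains negative [Ca] values")
        if not self.dt_ms > 0:
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")
        if not self.voxel_edge_nm > 0:
            raise ValueError(f"voxel_edge_nm must be positive, got {self.voxel_edge_nm}")
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def frame(self, k: int) -> Frame:
        return Frame(self.data[k])

    def frame_time_ms(self, k: int) -> float:
        return k * self.dt_ms

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for k in range(self.n_frames):
            yield self.frame(k)


@dataclass(frozen=True)
class VoltageTrace:
    """Membrane-potential samples: strictly increasing t (ms), Vm (mV)."""

    t_ms: np.ndarray
    vm_mV: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=np.float64).ravel()
        v = np.asarray(self.vm_mV, dtype=np.float64).ravel()
        if t.size != v.size:
            raise ValueError("t_ms and vm_mV must have equal length")
        if t.size < 1:
            raise ValueError("voltage trace is empty")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError("voltage trace contains non-finite values")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time column must be strictly increasing")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "vm_mV", v)

    def __len__(self) -> int:
        return self.t_ms.size


def _load_text_matrix(path: Path) -> np.ndarray:
    """Read one delimited-text matrix (comma or whitespace, optional header row)."""
    last_exc: Exception | None = None
    for skiprows in (0, 1):
        for delimiter in (",", None):
            try:
                return np.loadtxt(
                    path, delimiter=delimiter, skiprows=skiprows, dtype=np.float64, ndmin=2
                )
            except ValueError as exc:
                last_exc = exc
    raise ValueError(f"could not parse {path} as a numeric matrix: {last_exc}")


def load_stack(
    path: str | os.PathLike,
    dt_ms: float = 5.0,
    voxel_edge_nm: float = 100.0,
    periodic_x: bool = False,
) -> FrameStack:
    """Load a frame stack from a multi-page TIFF, a text matrix, or a directory.

    A directory is read as one frame per delimited-text file, in sorted
    filename order.  Values are taken verbatim as μM.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.is_file())
        if not files:
            raise ValueError(f"directory {p} contains no frame files")
        pages = [_load_text_matrix(f) for f in files]
    elif p.suffix.lower() in _TIFF_SUFFIXES:
        try:
            raw = tifffile.imread(p)
        except Exception as exc:  # noqa: BLE001 - surface as a load error
            raise ValueError(f"could not read TIFF {p}: {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise ValueError(f"TIFF {p} is not a stack of 2D grayscale pages (shape {raw.shape})")
        pages = list(raw.astype(np.float64))
    else:
        pages = [_load_text_matrix(p)]
    shapes = {pg.shape for pg in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent page shapes in {p}: {sorted(shapes)}")
    return FrameStack(
        np.stack(pages), dt_ms=dt_ms, voxel_edge_nm=voxel_edge_nm, periodic_x=periodic_x
    )


def write_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a stack as an uncompressed multi-page float32 grayscale TIFF."""
    if not isinstance(stack, FrameStack):
        raise TypeError("write_stack expects a FrameStack")
    p = Path(path)
    tifffile.imwrite(p, stack.data.astype(np.float32), photometric="minisblack")


def load_voltage(path: str | os.PathLike) -> VoltageTrace:
    """Load a two-column (t_ms, vm_mV) delimited-text voltage trace."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    arr = _load_text_matrix(p)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"voltage trace must have exactly two columns, got shape {arr.shape}")
    return VoltageTrace(arr[:, 0], arr[:, 1])


def write_voltage(trace: VoltageTrace, path: str | os.PathLike) -> None:
    """Write a voltage trace as two-column comma-delimited text."""
    np.savetxt(path, np.column_stack([trace.t_ms, trace.vm_mV]), delimiter=",", fmt="%.10g")
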