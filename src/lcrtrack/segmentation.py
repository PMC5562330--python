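"""Single-frame LCR detection by adaptive intensity binning.

Each frame is sliced into nested Boolean masks ("intensity bins") at levels
``mean + Δ·i`` where the increment Δ = (max − mean) / n_bins is recomputed
per frame.  The lowest bin (level = frame mean, strict ``>``) separates
release footprints from background: every connected component of it is one
*LCR image*.  Within each image the local intensity maxima are its release
peaks; an image with two or more peaks is *complex* (it embraces several
interacting release sites).  The Ca content ("signal mass") of an image is
the summed voxel [Ca] converted to nmol via the voxel volume.

Nothing here smooths, denoises or detrends the input: the intended input is
noise-free reaction-diffusion simulation output, and the per-frame adaptive
threshold is applied to the raw values.  Because mean and Δ are recomputed
every frame, segmentation levels drift with the global Ca transient; this
is a property of the method, not corrected for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .frames_io import Frame

__all__ = [
    "SegmentationConfig",
    "BinSet",
    "IntensityCluster",
    "Peak",
    "LCRImage",
    "compute_increment",
    "build_bins",
    "find_clusters",
    "find_peaks",
    "build_lcr_images",
    "image_signal_mass",
    "voxel_volume_liter",
    "segment_frame",
]

# 4-connectivity: edge-sharing neighbours only ("common border");
# 8-connectivity adds the diagonals.
_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)

_OFFSETS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS8 = _OFFSETS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT4
    if connectivity == 8:
        return _STRUCT8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _offsets(connectivity: int):
    if connectivity == 4:
        return _OFFSETS4
    if connectivity == 8:
        return _OFFSETS8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Detection parameters.

    n_bins : number of intensity bins per frame (the increment divisor).
    cluster_connectivity : 4 or 8; voxel adjacency when forming clusters.
        Default 4 — a "common border" is an edge, not a corner.
    peak_neighborhood : 4 or 8; adjacency when comparing a voxel with its
        neighbours for peak detection.  Default 8, so diagonal neighbours
        suppress spurious twin peaks.
    periodic_x : wrap-around in the column dimension (toroidal perimeter).
    """

    n_bins: int = 50
    cluster_connectivity: int = 4
    peak_neighborhood: int = 8
    periodic_x: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        _structure(self.cluster_connectivity)
        _structure(self.peak_neighborhood)


@dataclass(frozen=True)
class BinSet:
    """Nested supra-threshold masks of one frame.

    ``masks[i]`` is the Boolean grid ``values > frame_mean + delta * i`` for
    i = 0..n_bins−1, so masks are nested: masks[i+1] ⊆ masks[i].  A frame
    whose maximum equals its mean has delta = 0 and is flagged degenerate.
    """

    frame_mean: float
    frame_max: float
    delta: float
    n_bins: int
    masks: np.ndarray  # bool, shape (n_bins, H, W)

    @property
    def degenerate(self) -> bool:
        return self.delta == 0.0

    @property
    def lowest(self) -> np.ndarray:
        """The lowest (background-separating) mask: values > frame mean."""
        return self.masks[0]


@dataclass(frozen=True)
class IntensityCluster:
    """One connected component of TRUE voxels at a given bin level."""

    bin_index: int
    voxels: frozenset  # of (row, col)

    @property
    def anchor(self) -> tuple[int, int]:
        return min(self.voxels)


@dataclass(frozen=True)
class Peak:
    """A local [Ca] maximum; a connected equal-valued plateau is one peak."""

    voxel: tuple[int, int]
    amplitude: float  # μM


@dataclass(frozen=True)
class LCRImage:
    """The single-frame footprint of a release.

    One connected component of the lowest intensity bin, with its peaks.
    ``is_complex`` ⇔ the image has at least two peaks.
    """

    frame_index: int
    image_id: int
    voxels: frozenset  # of (row, col)
    peaks: tuple[Peak, ...]
    signal_mass_nmol: float

    @property
    def is_complex(self) -> bool:
        return len(self.peaks) >= 2

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def key(self) -> tuple[int, int]:
        return (self.frame_index, self.image_id)

    @property
    def max_amplitude(self) -> float:
        return max(p.amplitude for p in self.peaks)

    @property
    def centroid(self) -> tuple[float, float]:
        rows = [r for r, _ in self.voxels]
        cols = [c for _, c in self.voxels]
        return (sum(rows) / len(rows), sum(cols) / len(cols))


def voxel_volume_liter(voxel_edge_nm: float) -> float:
    """Volume of the cubic voxel in liters; 100 nm edge gives 1e-18 L."""
    edge_m = voxel_edge_nm * 1e-9
    return edge_m**3 * 1000.0  # m^3 -> L


def compute_increment(frame: Frame, n_bins: int = 50) -> tuple[float, float]:
    """Per-frame mean and intensity increment Δ = (max − mean) / n_bins.

    A uniform frame yields Δ = 0 (degenerate: no supra-mean voxels exist
    under the strict threshold, so the frame carries no LCR images).
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    v = frame.values
    mean = float(v.mean())
    vmax = float(v.max())
    span = vmax - mean
    # A uniform frame must yield delta = 0 exactly, but floating-point
    # summation can leave max - mean within a few ULP of zero (either
    # sign).  Anything below 1e-12 of the frame scale is no contrast.
    if span <= 1e-12 * max(abs(vmax), abs(mean)):
        span = 0.0
    return mean, span / n_bins


def build_bins(frame: Frame, mean: float, delta: float, n_bins: int = 50) -> BinSet:
    """Build the nested Boolean masks ``values > mean + Δ·i``, i = 0..n_bins−1.

    The inequality is strict at every level, including the lowest (mean)
    level, so background voxels at exactly the mean are excluded.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    v = frame.values
    if delta == 0.0:
        # Degenerate (uniform) frame: in exact arithmetic no voxel exceeds
        # the mean, but summation round-off can leave a few 1-ULP
        # stragglers; force the ideal empty masks.
        masks = np.zeros((n_bins,) + v.shape, dtype=bool)
    else:
        levels = mean + delta * np.arange(n_bins)
        masks = v[None, :, :] > levels[:, None, None]
    return BinSet(
        frame_mean=mean,
        frame_max=float(v.max()),
        delta=delta,
        n_bins=n_bins,
        masks=masks,
    )


def _label(mask: np.ndarray, connectivity: int, periodic_x: bool) -> tuple[np.ndarray, int]:
    """Connected-component labels of a Boolean grid, optionally wrapping columns."""
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if periodic_x and n > 1 and mask.shape[1] > 1:
        # Merge labels that touch across the column seam.
        parent = list(range(n + 1))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        left = labels[:, 0]
        right = labels[:, -1]
        h = mask.shape[0]
        row_offsets = (0,) if connectivity == 4 else (-1, 0, 1)
        for r in range(h):
            if right[r] == 0:
                continue
            for dr in row_offsets:
                rr = r + dr
                if 0 <= rr < h and left[rr] != 0:
                    union(right[r], left[rr])
        remap = np.array([find(a) for a in range(n + 1)])
        labels = remap[labels]
        n = len(np.unique(labels)) - 1
    return labels, n


def find_clusters(
    mask: np.ndarray,
    connectivity: int = 4,
    periodic_x: bool = False,
    bin_index: int = 0,
) -> list[IntensityCluster]:
    """Partition the TRUE voxels of a mask into maximal connected components.

    Components are returned sorted by their smallest (row, col) member, so
    the ordering is deterministic.  An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, _ = _label(mask, connectivity, periodic_x)
    clusters: dict[int, list[tuple[int, int]]] = {}
    for r, c in zip(*np.nonzero(labels)):
        clusters.setdefault(int(labels[r, c]), []).append((int(r), int(c)))
    out = [
        IntensityCluster(bin_index=bin_index, voxels=frozenset(vox))
        for vox in clusters.values()
    ]
    out.sort(key=lambda cl: cl.anchor)
    return out


def find_peaks(
    frame: Frame,
    region: Iterable[tuple[int, int]],
    neighborhood: int = 8,
    periodic_x: bool = False,
) -> list[Peak]:
    """All local [Ca] maxima of a frame restricted to a voxel region.

    A voxel is a peak if its amplitude is >= that of every neighbour within
    the region; a connected plateau of equal maximal values counts as one
    peak, represented by its smallest-(row, col) voxel.  A non-empty region
    always yields at least one peak (its maximum).
    """
    region = set((int(r), int(c)) for r, c in region)
    if not region:
        raise ValueError("region must be non-empty")
    v = frame.values
    w = frame.width
    offs = _offsets(neighborhood)

    def neighbors(r: int, c: int):
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if periodic_x:
                cc %= w
            if (rr, cc) in region:
                yield rr, cc

    # Group region voxels into equal-value plateaus connected under the
    # peak neighbourhood, then keep plateaus with no strictly higher
    # in-region neighbour.
    seen: set[tuple[int, int]] = set()
    peaks: list[Peak] = []
    for start in sorted(region):
        if start in seen:
            continue
        val = v[start]
        plateau = [start]
        seen.add(start)
        is_peak = True
        stack = [start]
        while stack:
            r, c = stack.pop()
            for rr, cc in neighbors(r, c):
                nv = v[rr, cc]
                if nv > val:
                    is_peak = False
                elif nv == val and (rr, cc) not in seen:
                    seen.add((rr, cc))
                    plateau.append((rr, cc))
                    stack.append((rr, cc))
        if is_peak:
            peaks.append(Peak(voxel=min(plateau), amplitude=float(val)))
    peaks.sort(key=lambda p: p.voxel)
    return peaks


def build_lcr_images(
    frame: Frame,
    bins: BinSet,
    frame_index: int = 0,
    config: SegmentationConfig | None = None,
    voxel_edge_nm: float = 100.0,
) -> list[LCRImage]:
    """Construct all LCR images of a frame from its bin set.

    One image per connected component of the lowest bin; the images are
    pairwise disjoint and their union is exactly the lowest mask.  A
    degenerate (uniform) frame yields an empty list.
    """
    config = config or SegmentationConfig(n_bins=bins.n_bins)
    if bins.degenerate:
        return []
    clusters = find_clusters(
        bins.lowest, config.cluster_connectivity, config.periodic_x
    )
    images: list[LCRImage] = []
    for image_id, cluster in enumerate(clusters):
        peaks = tuple(
            find_peaks(frame, cluster.voxels, config.peak_neighborhood, config.periodic_x)
        )
        mass = _signal_mass_of_voxels(frame, cluster.voxels, voxel_edge_nm)
        images.append(
            LCRImage(
                frame_index=frame_index,
                image_id=image_id,
                voxels=cluster.voxels,
                peaks=peaks,
                signal_mass_nmol=mass,
            )
        )
    return images


def _signal_mass_of_voxels(
    frame: Frame, voxels: Iterable[tuple[int, int]], voxel_edge_nm: float
) -> float:
    vol = voxel_volume_liter(voxel_edge_nm)
    total_uM = sum(float(frame.values[r, c]) for r, c in voxels)
    return total_uM * 1000.0 * vol  # μM -> nmol/L, × liters -> nmol


def image_signal_mass(frame: Frame, image: LCRImage, voxel_edge_nm: float = 100.0) -> float:
    """Ca content of an LCR image in nmol: Σ [Ca] (nmol/L) × V_voxel (L)."""
    return _signal_mass_of_voxels(frame, image.voxels, voxel_edge_nm)


def segment_frame(
    frame: Frame,
    frame_index: int = 0,
    config: SegmentationConfig | None = None,
    voxel_edge_nm: float = 100.0,
) -> list[LCRImage]:
    """Full single-frame detection: increment, bins, images."""
    config = config or SegmentationConfig()
    mean, delta = compute_increment(frame, config.n_bins)
    bins = build_bins(frame, mean, delta, config.n_bins)
    return build_lcr_images(frame, bins, frame_index, config, voxel_edge_nm)
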