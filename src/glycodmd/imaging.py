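"""Video I/O, per-cell trace extraction, and the synthetic-video generator.

Time-lapse autofluorescence recordings are grayscale frame stacks; cell
segmentation is consumed as an integer label mask (0 = background, 1..C =
cells) sharing the spatial grid.  Per-cell traces are the mean pixel
intensity of each labelled region per frame, exactly the observable the
downstream DMD analysis decomposes.  The synthetic-video generator closes
the loop for testing: it renders disk-shaped cells whose pixel intensities
follow prescribed per-cell traces plus Gaussian noise, with a
ground-truth mask, so extraction and reconstruction can be validated
against known truth.

Coordinate convention: 0-based pixel centers, ``x`` = column, ``y`` = row,
origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .containers import TraceMatrix

__all__ = [
    "LabeledVideo",
    "extract_traces",
    "synth_video",
    "frame_snapshot_matrix",
    "read_video",
    "write_video",
    "read_mask",
]


@dataclass
class LabeledVideo:
    frames: np.ndarray                 # (T, H, W) nonnegative intensities
    mask: np.ndarray                   # (H, W) int labels, 0 = background
    dt: float = 1.0                    # frame interval, seconds
    ground_truth: TraceMatrix | None = None   # synthetic videos only
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T >= 2, H, W)")
        if self.mask.shape != self.frames.shape[1:]:
            raise ValueError("mask shape must match the frame grid")
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("mask must hold integer labels")
        labels = np.unique(self.mask)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels,
                                              np.arange(1, labels.size + 1)):
            raise ValueError("mask labels must be contiguous 1..C")
        if (self.frames < 0).any():
            raise ValueError("frame intensities must be nonnegative")

    @property
    def n_cells(self) -> int:
        return int(self.mask.max())

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def extract_traces(video: LabeledVideo) -> tuple[TraceMatrix, np.ndarray]:
    """Mean intensity per labelled cell per frame, plus centroids.

    Centroids are the unweighted centers of mass of each label's pixels,
    returned as (x, y) in 0-based pixel coordinates.
    """
    n_cells = video.n_cells
    if n_cells == 0:
        raise ValueError("mask contains no cells")
    label_ids = np.arange(1, n_cells + 1)
    counts = np.bincount(video.mask.ravel(), minlength=n_cells + 1)[1:]
    empty = label_ids[counts == 0]
    if empty.size:
        raise ValueError(f"empty label(s) in mask: {empty.tolist()}")
    T = video.n_frames
    flat_mask = video.mask.ravel()
    data = np.empty((n_cells, T))
    for t in range(T):
        sums = np.bincount(flat_mask, weights=video.frames[t].ravel(),
                           minlength=n_cells + 1)[1:]
        data[:, t] = sums / counts
    com = ndimage.center_of_mass(np.ones_like(video.mask), video.mask,
                                 label_ids)
    centroids = np.array([(c[1], c[0]) for c in com])  # (row, col) -> (x, y)
    traces = TraceMatrix(data=data, dt=video.dt, centroids=centroids,
                         meta={"source": "extract_traces", **video.meta})
    return traces, centroids


def _hex_centers(height: int, width: int, radius: int, n: int) -> np.ndarray:
    """Non-overlapping disk centers on a hexagonal grid; raises if full."""
    pitch = 2 * radius + 2
    row_step = int(np.ceil(pitch * np.sqrt(3) / 2))
    centers = []
    y = radius + 1
    row = 0
    while y + radius < height:
        x = radius + 1 + (pitch // 2 if row % 2 else 0)
        while x + radius < width:
            centers.append((x, y))
            x += pitch
        y += row_step
        row += 1
    if n > len(centers):
        raise ValueError(
            f"grid {height}x{width} fits at most {len(centers)} cells of "
            f"radius {radius}; {n} requested")
    return np.array(centers[:n], dtype=float)


def synth_video(
    traces: TraceMatrix,
    height: int = 64,
    width: int = 64,
    cell_radius: int = 4,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LabeledVideo:
    """Render per-cell traces as disk-shaped cells on a constant background.

    Every pixel of cell ``i`` in frame ``t`` takes the trace value
    ``traces.data[i, t]`` plus independent Gaussian noise, clipped at
    zero.  Cells are placed on a hexagonal grid so disks never overlap;
    the ground-truth traces (with the placed centroids) are stored on the
    returned video.  Deterministic under ``seed``.
    """
    n_cells, T = traces.data.shape
    centers = _hex_centers(height, width, cell_radius, n_cells)
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=np.int32)
    for i, (cx, cy) in enumerate(centers, start=1):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius ** 2
        mask[disk] = i
    frames = np.full((T, height, width), float(background))
    for i in range(n_cells):
        frames[:, mask == i + 1] = traces.data[i][:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    truth = TraceMatrix(data=traces.data.copy(), dt=traces.dt,
                        cell_ids=list(traces.cell_ids),
                        conditions=list(traces.conditions),
                        centroids=centers, meta=dict(traces.meta))
    return LabeledVideo(frames=frames, mask=mask, dt=traces.dt,
                        ground_truth=truth,
                        meta={"noise_sd": noise_sd, "seed": seed,
                              "background": background})


def frame_snapshot_matrix(video: LabeledVideo) -> np.ndarray:
    """Flatten frames into a pixels-by-time snapshot matrix (row-major).

    Column ``k`` is frame ``k`` flattened; the inverse reshape
    ``M[:, k].reshape(H, W)`` is exact.
    """
    T = video.n_frames
    return video.frames.reshape(T, -1).T.copy()


def snapshots_to_frames(matrix: np.ndarray, height: int, width: int
                        ) -> np.ndarray:
    """Inverse of :func:`frame_snapshot_matrix`."""
    return np.asarray(matrix).T.reshape(-1, height, width)


# ------------------------------------------------------------------- I/O


def write_video(video: LabeledVideo, stack_path: str | Path,
                mask_path: str | Path | None = None) -> None:
    """Write the frame stack as multi-page grayscale TIFF (float32) and the
    mask as single-page integer TIFF."""
    tifffile.imwrite(str(stack_path), video.frames.astype(np.float32))
    if mask_path is not None:
        tifffile.imwrite(str(mask_path), video.mask.astype(np.int32))


def read_video(stack_path: str | Path, mask_path: str | Path,
               dt: float = 1.0) -> LabeledVideo:
    """Read a multi-page grayscale TIFF stack plus its label mask.

    Intensities are normalized to floating point on read; no photometric
    calibration is applied.
    """
    frames = np.asarray(tifffile.imread(str(stack_path)), dtype=float)
    mask = read_mask(mask_path)
    return LabeledVideo(frames=frames, mask=mask, dt=dt)


def read_mask(mask_path: str | Path) -> np.ndarray:
    """Read an integer label mask from single-page TIFF or PNG."""
    path = Path(mask_path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        mask = tifffile.imread(str(path))
    else:
        from imageio.v3 import imread  # PNG fallback
        mask = imread(str(path))
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.allclose(mask, np.round(mask)):
            raise ValueError("mask image does not hold integer labels")
        mask = mask.astype(np.int32)
    return mask.astype(np.int32)
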