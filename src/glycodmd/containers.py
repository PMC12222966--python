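"""Cell-by-time trace matrices, the package's universal exchange object.

A :class:`TraceMatrix` holds one real-valued time series per cell, all
sampled on the same uniform grid, together with the sampling interval, a
per-cell condition label (e.g. the glucose influx the cell was simulated
with, or the glucose bolus an imaged field received) and, when the traces
were extracted from segmented video, the per-cell centroid coordinates.

Serialization follows a flat CSV dialect: first column ``cell_id``, second
column ``condition``, remaining columns one per timepoint with the time in
minutes as the header.  A JSON sidecar (same stem, ``.json`` suffix) stores
the sampling interval, seeds and any provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class TraceMatrix:
    data: np.ndarray                      # (n_cells, n_times)
    dt: float                             # sampling interval, minutes
    cell_ids: list[str] = None            # type: ignore[assignment]
    conditions: list[str] = None          # type: ignore[assignment]
    centroids: np.ndarray | None = None   # (n_cells, 2) as (x, y) pixels
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trace data must be 2-D (cells x timepoints)")
        if not np.isfinite(self.data).all():
            raise ValueError("trace data must be finite")
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be positive")
        n = self.n_cells
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i + 1}" for i in range(n)]
        if self.conditions is None:
            self.conditions = [""] * n
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.conditions = [str(c) for c in self.conditions]
        if len(self.cell_ids) != n or len(self.conditions) != n:
            raise ValueError("cell_ids/conditions length must match rows")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (n, 2):
                raise ValueError("centroids must have shape (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_times)

    def subset(self, idx: Sequence[int]) -> "TraceMatrix":
        idx = list(idx)
        return TraceMatrix(
            data=self.data[idx],
            dt=self.dt,
            cell_ids=[self.cell_ids[i] for i in idx],
            conditions=[self.conditions[i] for i in idx],
            centroids=None if self.centroids is None else self.centroids[idx],
            t0=self.t0,
            meta=dict(self.meta),
        )

    @classmethod
    def concatenate(cls, matrices: Sequence["TraceMatrix"]) -> "TraceMatrix":
        """Stack several trace matrices row-wise (shared time grid required)."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        first = matrices[0]
        for m in matrices[1:]:
            if m.n_times != first.n_times or not np.isclose(m.dt, first.dt):
                raise ValueError("trace matrices must share the time grid")
        cents = [m.centroids for m in matrices]
        return cls(
            data=np.vstack([m.data for m in matrices]),
            dt=first.dt,
            cell_ids=[c for m in matrices for c in m.cell_ids],
            conditions=[c for m in matrices for c in m.conditions],
            centroids=(np.vstack(cents) if all(c is not None for c in cents)
                       else None),
            t0=first.t0,
            meta=dict(first.meta),
        )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        cols = [f"{t:.6g}" for t in self.times]
        df = pd.DataFrame(self.data, columns=cols)
        df.insert(0, "condition", self.conditions)
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(path, index=False)
        if sidecar:
            side = {
                "dt": self.dt,
                "t0": self.t0,
                "meta": self.meta,
            }
            if self.centroids is not None:
                side["centroids"] = self.centroids.tolist()
            path.with_suffix(".json").write_text(
                json.dumps(side, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraceMatrix":
        path = Path(path)
        df = pd.read_csv(path, dtype={"cell_id": str, "condition": str})
        if list(df.columns[:2]) != ["cell_id", "condition"]:
            raise ValueError(
                "expected 'cell_id' and 'condition' as the first two columns")
        times = np.array([float(c) for c in df.columns[2:]])
        data = df.iloc[:, 2:].to_numpy(dtype=float)
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        t0 = float(times[0]) if len(times) else 0.0
        centroids = None
        meta: dict = {}
        side_path = path.with_suffix(".json")
        if side_path.exists():
            side = json.loads(side_path.read_text())
            dt = float(side.get("dt", dt))
            t0 = float(side.get("t0", t0))
            meta = side.get("meta", {})
            if "centroids" in side:
                centroids = np.asarray(side["centroids"], dtype=float)
        return cls(data=data, dt=dt,
                   cell_ids=list(df["cell_id"]),
                   conditions=list(df["condition"].fillna("")),
                   centroids=centroids, t0=t0, meta=meta)
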