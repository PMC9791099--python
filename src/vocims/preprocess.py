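"""Chromatogram dimensionality reduction: crop, threshold, vectorize.

Every sample of a study is reduced with the *same* crop window and the same
intensity threshold; values strictly below the threshold are zeroed, values
equal to it survive.  Crop intervals are closed on both ends and operate on
axis coordinates, not indices.  Vectorization is row-major (retention time
outer, drift time inner) with a recoverable pixel -> (rt, dt) mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    EmptyCropError,
    IncompatibleGridsError,
    InvalidThresholdError,
)
from .synthetic import ChromatogramGrid

__all__ = [
    "CropWindow",
    "FeatureMatrix",
    "crop",
    "apply_threshold",
    "vectorize",
    "build_matrix",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class CropWindow:
    """Closed coordinate intervals retained on each axis."""

    rt_min: float
    rt_max: float
    dt_min: float
    dt_max: float

    def __post_init__(self) -> None:
        if not (self.rt_min < self.rt_max and self.dt_min < self.dt_max):
            raise EmptyCropError("crop window bounds must satisfy min < max")

    @classmethod
    def full(cls, grid: ChromatogramGrid) -> "CropWindow":
        return cls(grid.rt_axis[0], grid.rt_axis[-1], grid.dt_axis[0], grid.dt_axis[-1])


@dataclass(frozen=True, eq=False)
class FeatureMatrix:
    """Samples x flattened-pixel feature table with provenance metadata."""

    matrix: np.ndarray  # (n_samples, n_features), non-negative
    feature_index: np.ndarray  # (n_features, 2): (rt, dt) coordinate per column
    sample_ids: tuple[str, ...]
    threshold_used: float
    crop_used: CropWindow

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.sample_ids):
            raise IncompatibleGridsError("row count does not match sample_ids")
        if self.matrix.shape[1] != self.feature_index.shape[0]:
            raise IncompatibleGridsError("column count does not match feature_index")
        if np.any(self.matrix < 0):
            raise IncompatibleGridsError("feature matrix must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write rows as CSV plus a JSON sidecar with index/crop/threshold."""
        df = pd.DataFrame(self.matrix, index=list(self.sample_ids))
        df.index.name = "sample_id"
        df.to_csv(path)
        if sidecar_path is not None:
            meta = {
                "feature_index": self.feature_index.tolist(),
                "crop": vars(self.crop_used),
                "threshold": self.threshold_used,
            }
            Path(sidecar_path).write_text(json.dumps(meta, sort_keys=True))

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        meta = json.loads(Path(sidecar_path).read_text())
        return cls(
            matrix=df.to_numpy(dtype=float),
            feature_index=np.asarray(meta["feature_index"], dtype=float),
            sample_ids=tuple(str(s) for s in df.index),
            threshold_used=float(meta["threshold"]),
            crop_used=CropWindow(**meta["crop"]),
        )


def crop(grid: ChromatogramGrid, window: CropWindow) -> ChromatogramGrid:
    """Keep cells whose coordinates fall inside the closed window on both axes."""
    rt_mask = (grid.rt_axis >= window.rt_min) & (grid.rt_axis <= window.rt_max)
    dt_mask = (grid.dt_axis >= window.dt_min) & (grid.dt_axis <= window.dt_max)
    if not rt_mask.any() or not dt_mask.any():
        raise EmptyCropError("crop window does not intersect the grid")
    return ChromatogramGrid(
        grid.rt_axis[rt_mask],
        grid.dt_axis[dt_mask],
        grid.intensity[np.ix_(rt_mask, dt_mask)],
    )


def apply_threshold(grid: ChromatogramGrid, tau: float) -> ChromatogramGrid:
    """Zero all values strictly below ``tau``; values >= tau are unchanged."""
    if tau < 0:
        raise InvalidThresholdError(f"threshold must be >= 0, got {tau}")
    intensity = np.where(grid.intensity < tau, 0.0, grid.intensity)
    return ChromatogramGrid(grid.rt_axis, grid.dt_axis, intensity)


def vectorize(grid: ChromatogramGrid) -> tuple[np.ndarray, np.ndarray]:
    """Row-major flatten; returns (vector, feature_index).

    ``feature_index[p]`` is the (rt, dt) coordinate pair of vector position
    ``p``; reshaping the vector to ``(len(rt_axis), len(dt_axis))`` recovers
    the grid.
    """
    vector = grid.intensity.reshape(-1)
    rt_coords = np.repeat(grid.rt_axis, grid.dt_axis.size)
    dt_coords = np.tile(grid.dt_axis, grid.rt_axis.size)
    feature_index = np.column_stack([rt_coords, dt_coords])
    return vector, feature_index


def _check_shared_axes(grids: Sequence[ChromatogramGrid]) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not (
            np.array_equal(g.rt_axis, ref.rt_axis)
            and np.array_equal(g.dt_axis, ref.dt_axis)
        ):
            raise IncompatibleGridsError("all sample grids must share identical axes")


def build_matrix(
    samples: Sequence[tuple[str, ChromatogramGrid]],
    window: CropWindow,
    tau: float,
) -> FeatureMatrix:
    """Apply crop -> threshold -> vectorize uniformly across samples."""
    if not samples:
        raise IncompatibleGridsError("no samples supplied")
    ids = tuple(sid for sid, _ in samples)
    grids = [g for _, g in samples]
    _check_shared_axes(grids)
    rows = []
    feature_index = None
    for g in grids:
        vec, idx = vectorize(apply_threshold(crop(g, window), tau))
        rows.append(vec)
        if feature_index is None:
            feature_index = idx
    return FeatureMatrix(
        matrix=np.vstack(rows),
        feature_index=feature_index,
        sample_ids=ids,
        threshold_used=float(tau),
        crop_used=window,
    )


def calibrate_threshold(
    samples: Sequence[tuple[str, ChromatogramGrid]] | Sequence[ChromatogramGrid],
    target_nnz: int,
    candidates: Sequence[float] | None = None,
    n_candidates: int = 200,
) -> float:
    """Smallest candidate tau whose median per-sample non-zero count <= target.

    The default candidate grid is the set of pooled intensity quantiles
    (plus 0), which is dense where the data are dense, so the achieved
    median non-zero count lands close below the target.  Because the
    non-zero count is non-increasing in tau, a scan of the ascending
    candidates finds the smallest admissible threshold.
    """
    if target_nnz < 1:
        raise CalibrationError("target_nnz must be >= 1")
    if not samples:
        raise CalibrationError("no samples supplied")
    grids = [s[1] if isinstance(s, tuple) else s for s in samples]
    stacked = [g.intensity for g in grids]
    if candidates is None:
        pooled = np.concatenate([a.ravel() for a in stacked])
        qs = np.quantile(pooled, np.linspace(0.0, 1.0, n_candidates))
        candidates = np.unique(np.concatenate([[0.0], qs]))
    candidates = sorted(float(c) for c in candidates)
    if any(c < 0 for c in candidates):
        raise CalibrationError("threshold candidates must be >= 0")
    for tau in candidates:
        nnz = [int(np.count_nonzero(a >= max(tau, np.finfo(float).tiny))) for a in stacked]
        if float(np.median(nnz)) <= target_nnz:
            return tau
    nnz_at_max = float(np.median(
        [np.count_nonzero(a >= candidates[-1]) for a in stacked]
    ))
    raise CalibrationError(
        f"no candidate reaches target_nnz={target_nnz}; "
        f"median nnz at largest candidate {candidates[-1]}: {nnz_at_max}"
    )
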