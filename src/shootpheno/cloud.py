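"""Core colored point-cloud container shared by every pipeline stage.

Coordinates are in arbitrary photogrammetric units until scale calibration,
after which they are millimetres (z-up).  Colors are 8-bit RGB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class ColoredPointCloud:
    """Points + per-point RGB colors, with optional unit normals.

    Parameters
    ----------
    points : (n, 3) float array
        Cartesian coordinates, z-up.  Millimetres once ``frame_note`` is
        ``"metric"``; arbitrary multi-view-stereo units before that.
    colors : (n, 3) uint8 array
        RGB, each channel in [0, 255].
    normals : (n, 3) float array, optional
        Unit normals; ``None`` until estimated.
    frame_note : str
        ``"raw-scale"`` or ``"metric"``.
    """

    points: np.ndarray
    colors: np.ndarray
    normals: np.ndarray | None = None
    frame_note: str = "raw-scale"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors)
        if self.colors.ndim != 2 or self.colors.shape != (len(self.points), 3):
            raise ValueError(
                f"colors shape {self.colors.shape} does not match "
                f"{len(self.points)} points"
            )
        if self.colors.dtype != np.uint8:
            c = np.asarray(self.colors, dtype=np.float64)
            if c.min() < 0 or c.max() > 255:
                raise ValueError("color channels must lie in [0, 255]")
            self.colors = c.astype(np.uint8)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise ValueError("normals length mismatch")
            norms = np.linalg.norm(self.normals, axis=1)
            if len(norms) and np.abs(norms - 1.0).max() > 1e-6:
                raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "ColoredPointCloud":
        """Subset cloud by boolean mask or integer index array."""
        idx = np.asarray(index)
        return ColoredPointCloud(
            points=self.points[idx],
            colors=self.colors[idx],
            normals=None if self.normals is None else self.normals[idx],
            frame_note=self.frame_note,
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ColoredPointCloud":
        """Apply rigid transform x -> R x + t (normals rotate with R)."""
        R = np.asarray(R, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64).reshape(3)
        return replace(
            self,
            points=self.points @ R.T + t,
            normals=None if self.normals is None else self.normals @ R.T,
        )

    def mean_spacing(self, sample: int = 2000, seed: int = 0) -> float:
        """Mean nearest-neighbour distance, estimated on a random subsample."""
        n = len(self)
        if n < 2:
            raise ValueError("need at least two points")
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=min(sample, n), replace=False)
        tree = cKDTree(self.points)
        d, _ = tree.query(self.points[idx], k=2)
        return float(d[:, 1].mean())

    def concat(self, other: "ColoredPointCloud") -> "ColoredPointCloud":
        normals = None
        if self.normals is not None and other.normals is not None:
            normals = np.vstack([self.normals, other.normals])
        return ColoredPointCloud(
            points=np.vstack([self.points, other.points]),
            colors=np.vstack([self.colors, other.colors]),
            normals=normals,
            frame_note=self.frame_note,
        )
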