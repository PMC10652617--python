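"""Cone region geometry: ROI polygon and the upper/lower split.

The WHO cone is fixed to the rig, so its projection into the image is a
per-setup calibration, not something detected per video.  The calibration is
a polygon outlining the cone's projection plus a horizontal line splitting
the projection into the upper half (UHC) and the lower half (LHC, the half
bordering the net surface).  Image coordinates are 0-based with the origin
top-left and y increasing downward — the net surface is at the *bottom* of
the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import yaml
from skimage.draw import polygon2mask

from .video import STANDARD_HEIGHT, STANDARD_WIDTH

UPPER = "upper"
LOWER = "lower"


@dataclass(frozen=True)
class RegionGeometry:
    """Cone ROI polygon and upper/lower partition for one camera setup.

    Parameters
    ----------
    polygon
        (N, 2) array of (x, y) vertices in pixels outlining the cone ROI.
    split_line_y
        Horizontal boundary (pixels): centroids with y < split_line_y are in
        the upper half, y >= split_line_y in the lower half.  A centroid
        exactly on the line counts as lower — the net-facing half is the half
        of interest, and the tie must be fixed for determinism.
    frame_dims
        (width, height) of the standardized frame the coordinates refer to.
    """

    polygon: np.ndarray
    split_line_y: float
    frame_dims: tuple[int, int] = (STANDARD_WIDTH, STANDARD_HEIGHT)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (N>=3, 2) array of (x, y) vertices")
        object.__setattr__(self, "polygon", poly)
        w, h = self.frame_dims
        if poly[:, 0].min() < 0 or poly[:, 0].max() > w:
            raise ValueError("polygon extends outside the frame horizontally")
        if poly[:, 1].min() < 0 or poly[:, 1].max() > h:
            raise ValueError("polygon extends outside the frame vertically")
        if not poly[:, 1].min() < self.split_line_y < poly[:, 1].max():
            raise ValueError("split_line_y must lie strictly inside the ROI")

    @classmethod
    def default(cls) -> "RegionGeometry":
        """Calibration for the standard rig at 540 x 960: a trapezoidal cone
        projection, wide at the net surface (bottom), split at mid-height."""
        poly = [(90.0, 120.0), (450.0, 120.0), (480.0, 880.0), (60.0, 880.0)]
        return cls(np.array(poly), split_line_y=500.0)

    @cached_property
    def roi_mask(self) -> np.ndarray:
        """Boolean (H, W) mask of the cone ROI."""
        w, h = self.frame_dims
        # polygon2mask wants (row, col) = (y, x)
        return polygon2mask((h, w), self.polygon[:, ::-1])

    @cached_property
    def upper_mask(self) -> np.ndarray:
        mask = self.roi_mask.copy()
        mask[int(np.ceil(self.split_line_y)) :, :] = False
        return mask

    @cached_property
    def lower_mask(self) -> np.ndarray:
        return self.roi_mask & ~self.upper_mask

    def contains(self, x: float, y: float) -> bool:
        """ROI membership of a point, consistent with the rasterized mask."""
        w, h = self.frame_dims
        col = int(round(x))
        row = int(round(y))
        if not (0 <= col < w and 0 <= row < h):
            return False
        return bool(self.roi_mask[row, col])

    def region_of(self, y: float) -> str:
        """Region label for a centroid: ``upper`` iff y < split_line_y."""
        return UPPER if y < self.split_line_y else LOWER

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "polygon": [[float(x), float(y)] for x, y in self.polygon],
            "split_line_y": float(self.split_line_y),
            "frame_dims": [int(self.frame_dims[0]), int(self.frame_dims[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionGeometry":
        return cls(
            polygon=np.asarray(d["polygon"], dtype=float),
            split_line_y=float(d["split_line_y"]),
            frame_dims=tuple(d.get("frame_dims", (STANDARD_WIDTH, STANDARD_HEIGHT))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RegionGeometry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
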