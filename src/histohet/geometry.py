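"""Regions of interest and point patterns in micrometre coordinates.

Everything above raw pixel access works in µm, origin at the top-left
corner, x rightward, y downward.  A :class:`Region` is the physical
extent of a slide (or a synthetic window) together with an ROI polygon;
a :class:`PointPattern` is a set of nucleus locations inside that ROI.
The :class:`ROIMask` bridges the polygon world and binary rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

__all__ = ["Region", "PointPattern", "ROIMask", "apply_roi"]

_CONTAINMENT_TOL = 1e-6


@dataclass(frozen=True)
class Region:
    """Rectangular slide extent with an ROI polygon, all in µm.

    Parameters
    ----------
    width, height : float
        Extent of the rectangular frame in µm; must be positive.
    roi_polygon : shapely.Polygon, optional
        Region of interest.  Defaults to the full rectangle.  Must have
        positive area and lie inside the frame (small numerical
        overshoot is tolerated).
    """

    width: float
    height: float
    roi_polygon: Polygon | None = None

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("Region width and height must be positive")
        if self.roi_polygon is None:
            object.__setattr__(self, "roi_polygon", box(0.0, 0.0, self.width, self.height))
        poly = self.roi_polygon
        if not isinstance(poly, BaseGeometry) or poly.is_empty or poly.area <= 0:
            raise ValueError("roi_polygon must have positive area")
        frame = box(0.0, 0.0, self.width, self.height)
        if poly.difference(frame.buffer(_CONTAINMENT_TOL)).area > _CONTAINMENT_TOL * poly.area:
            raise ValueError("roi_polygon must be contained in the region rectangle")

    @property
    def frame(self) -> Polygon:
        return box(0.0, 0.0, self.width, self.height)

    @property
    def roi_area_um2(self) -> float:
        return float(self.roi_polygon.area)

    @property
    def roi_area_mm2(self) -> float:
        return self.roi_area_um2 / 1e6


@dataclass(frozen=True)
class PointPattern:
    """Nucleus centroids (µm) inside a region's ROI.

    ``truth_label`` records the generating process for synthetic
    patterns ("csr", "clustered") or "observed" for detections.
    """

    points: np.ndarray  # (n, 2) float, columns x_um, y_um
    region: Region
    truth_label: str = "observed"
    seed: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if pts.size:
            inside = shapely.contains_xy(
                self.region.roi_polygon.buffer(_CONTAINMENT_TOL), pts[:, 0], pts[:, 1]
            )
            if not inside.all():
                raise ValueError("all points must lie inside the ROI polygon")

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.points, columns=["x_um", "y_um"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, region: Region, truth_label: str = "observed") -> "PointPattern":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["x_um", "y_um"]].to_numpy(float), region, truth_label)


class ROIMask:
    """ROI as a polygon (µm) convertible to/from a binary raster.

    A raster mask at resolution r marks pixel (row i, col j) as
    foreground when the pixel centre ((j+0.5)r, (i+0.5)r) lies inside
    the polygon, so polygon→raster→polygon round-trips are consistent
    up to one pixel at the boundary.
    """

    def __init__(self, polygon: BaseGeometry):
        if polygon.is_empty or polygon.area <= 0:
            raise ValueError("ROI mask must have nonempty foreground")
        self.polygon = polygon

    @classmethod
    def from_raster(cls, mask: np.ndarray, resolution_um: float) -> "ROIMask":
        """Build the polygon as the union of foreground pixel squares."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("ROI mask must have nonempty foreground")
        rows, cols = np.nonzero(mask)
        r = float(resolution_um)
        boxes = shapely.box(cols * r, rows * r, (cols + 1) * r, (rows + 1) * r)
        return cls(shapely.unary_union(boxes))

    @classmethod
    def from_polygon_csv(cls, path) -> "ROIMask":
        """Read a closed polygon from a two-column (x_um, y_um) CSV."""
        import pandas as pd

        df = pd.read_csv(path)
        return cls(Polygon(df.iloc[:, :2].to_numpy(float)))

    def to_raster(self, shape: tuple[int, int], resolution_um: float) -> np.ndarray:
        h, w = shape
        r = float(resolution_um)
        xs = (np.arange(w) + 0.5) * r
        ys = (np.arange(h) + 0.5) * r
        gx, gy = np.meshgrid(xs, ys)
        return shapely.contains_xy(self.polygon, gx.ravel(), gy.ravel()).reshape(h, w)

    @classmethod
    def read(cls, path, resolution_um: float | None = None) -> "ROIMask":
        """Read from a binary PNG/TIFF raster or a polygon CSV."""
        import os

        ext = os.path.splitext(str(path))[1].lower()
        if ext == ".csv":
            return cls.from_polygon_csv(path)
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        if resolution_um is None:
            raise ValueError("resolution_um is required for raster masks")
        return cls.from_raster(arr > 0, resolution_um)


def apply_roi(obj, mask: ROIMask):
    """Restrict a point pattern or a slide to an ROI.

    Points outside the ROI are removed; slide pixels outside the ROI
    are set to the white background sentinel (255) and flagged via the
    slide's ``roi_raster`` so downstream statistics exclude them.
    Raises if the ROI does not intersect the data extent.
    """
    from .imaging import VirtualSlide  # local import avoids a cycle

    if isinstance(obj, PointPattern):
        frame = obj.region.frame
        if not mask.polygon.intersects(frame):
            raise ValueError("ROI does not intersect the pattern's region")
        clipped = mask.polygon.intersection(obj.region.roi_polygon)
        if clipped.is_empty or clipped.area <= 0:
            raise ValueError("ROI intersection with pattern region is empty")
        region = Region(obj.region.width, obj.region.height, clipped)
        pts = obj.points
        if len(pts):
            keep = shapely.contains_xy(
                clipped.buffer(_CONTAINMENT_TOL), pts[:, 0], pts[:, 1]
            )
            pts = pts[keep]
        return PointPattern(pts, region, obj.truth_label, obj.seed)
    if isinstance(obj, VirtualSlide):
        raster = mask.to_raster(obj.pixels.shape[:2], obj.resolution_um)
        if not raster.any():
            raise ValueError("ROI does not intersect the slide extent")
        pixels = obj.pixels.copy()
        pixels[~raster] = 255
        return VirtualSlide(pixels, obj.resolution_um, roi_raster=raster)
    raise TypeError(f"cannot apply ROI to {type(obj).__name__}")
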