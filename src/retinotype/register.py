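"""Field stitching, landmark-based alignment, ROI transfer and trace extraction.

Confocal images of immunostained retinae and in-vitro two-photon calcium
movies live in different coordinate frames.  Blood-vessel landmarks visible in
both are used to estimate a similarity transform (rotation + isotropic scale +
translation) mapping the confocal frame onto the two-photon frame; ROIs drawn
on the stained image are then transferred and used to pull per-soma traces out
of the movie.

Coordinate conventions: everything is in µm.  Image rasters use the usual
top-left origin with x rightward and y downward; the transform itself is plain
mathematical 2-D geometry (counter-clockwise rotation, y-up).  Tests pin both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .core import FieldGeometry, TrialResponse

__all__ = [
    "SimilarityTransform",
    "LandmarkPairs",
    "ROI",
    "TiledField",
    "estimate_similarity_transform",
    "stitch_fields",
    "transfer_rois",
    "rasterize_polygon",
    "extract_traces",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """p ↦ scale · R(rotation) · p + translation, with R counter-clockwise."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return self.scale * np.array([[c, -s], [s, c]])

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation_deg
        th = np.deg2rad(inv_rot)
        c, s = np.cos(th), np.sin(th)
        tx, ty = self.translation
        it = -inv_scale * np.array([[c, -s], [s, c]]) @ np.array([tx, ty])
        return SimilarityTransform(inv_rot, inv_scale, (float(it[0]), float(it[1])))

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
            "tx_um": self.translation[0],
            "ty_um": self.translation[1],
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SimilarityTransform":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(d["rotation_deg"], d["scale"], (d["tx_um"], d["ty_um"]))


@dataclass
class LandmarkPairs:
    """Index-paired landmark coordinates in the source and target frames (µm)."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 2)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 2)
        if self.source.shape != self.target.shape:
            raise ValueError("source and target landmark lists differ in length")
        if len(self.source) < 2:
            raise ValueError("at least 2 landmark pairs are required")
        if not (np.all(np.isfinite(self.source)) and np.all(np.isfinite(self.target))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.source)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "src_x": self.source[:, 0],
                "src_y": self.source[:, 1],
                "dst_x": self.target[:, 0],
                "dst_y": self.target[:, 1],
            }
        ).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkPairs":
        df = pd.read_csv(path)
        return cls(df[["src_x", "src_y"]].to_numpy(), df[["dst_x", "dst_y"]].to_numpy())


def estimate_similarity_transform(
    pairs: LandmarkPairs,
) -> tuple[SimilarityTransform, float]:
    """Closed-form least-squares similarity fit (Procrustes/Umeyama).

    Minimizes ``Σ ‖s·R·source_i + t − target_i‖²`` and returns the transform
    together with the RMS residual in µm.
    """
    src, dst = pairs.source, pairs.target
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    var_s = float(np.sum(sc**2)) / len(src)
    if var_s == 0:
        raise ValueError("degenerate landmark configuration: source points coincide")
    cov = dc.T @ sc / len(src)
    u, svals, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    s_diag = np.array([1.0, d])
    rot = u @ np.diag(s_diag) @ vt
    scale = float(np.sum(svals * s_diag)) / var_s
    t = mu_d - scale * rot @ mu_s
    rotation_deg = float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0]))) % 360.0
    transform = SimilarityTransform(rotation_deg, scale, (float(t[0]), float(t[1])))
    residuals = transform(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, rms


@dataclass
class TiledField:
    """One imaging field: intensity raster plus its stage offset in µm."""

    image: np.ndarray
    stage_offset: tuple[float, float]
    pixel_size: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("TiledField.image must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")


def stitch_fields(fields: list[TiledField]) -> tuple[np.ndarray, tuple[float, float]]:
    """Mosaic tiled fields by stage coordinates onto a common canvas.

    Overlapping pixels are averaged; pixels covered by no field are NaN.
    Returns the composite image and the µm coordinates of its top-left pixel.
    Stage offsets are snapped to the nearest whole pixel.
    """
    if not fields:
        raise ValueError("stitch_fields requires at least one field")
    ps = fields[0].pixel_size
    if any(f.pixel_size != ps for f in fields):
        raise ValueError("all fields must share the same pixel_size")

    cols = [int(round(f.stage_offset[0] / ps)) for f in fields]
    rows = [int(round(f.stage_offset[1] / ps)) for f in fields]
    col0 = min(cols)
    row0 = min(rows)
    n_rows = max(r + f.image.shape[0] for r, f in zip(rows, fields)) - row0
    n_cols = max(c + f.image.shape[1] for c, f in zip(cols, fields)) - col0

    total = np.zeros((n_rows, n_cols))
    count = np.zeros((n_rows, n_cols), dtype=int)
    for f, r, c in zip(fields, rows, cols):
        h, w = f.image.shape
        total[r - row0 : r - row0 + h, c - col0 : c - col0 + w] += f.image
        count[r - row0 : r - row0 + h, c - col0 : c - col0 + w] += 1
    with np.errstate(invalid="ignore"):
        composite = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return composite, (col0 * ps, row0 * ps)


@dataclass
class ROI:
    """A region of interest: polygon in µm and/or a rasterized pixel mask."""

    id: str
    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None
    frame: str = "confocal"

    def __post_init__(self) -> None:
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
            if len(self.polygon) >= 3 and not Polygon(self.polygon).is_valid:
                raise ValueError(f"ROI {self.id!r}: polygon is self-intersecting")
        if self.polygon is None and (self.mask is None or not np.any(self.mask)):
            raise ValueError(f"ROI {self.id!r}: needs a polygon or a non-empty mask")


def rasterize_polygon(vertices: np.ndarray, geometry: FieldGeometry) -> np.ndarray:
    """Boolean mask: a pixel belongs to the ROI iff its center lies inside.

    Pixel (row i, col j) has its center at ``((j + ½)·pixel_size, (i + ½)·pixel_size)``.
    """
    n_rows, n_cols = geometry.shape
    ps = geometry.pixel_size
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cx = (jj.ravel() + 0.5) * ps
    cy = (ii.ravel() + 0.5) * ps
    poly = Polygon(np.asarray(vertices, dtype=float))
    inside = shapely.contains_xy(poly, cx, cy)
    return inside.reshape(n_rows, n_cols)


def transfer_rois(
    rois: list[ROI],
    transform: SimilarityTransform,
    target_geometry: FieldGeometry,
) -> tuple[list[ROI], list[str]]:
    """Map ROI polygons into the target frame and rasterize onto its pixel grid.

    ROIs whose transformed footprint covers no target pixel are excluded and
    their ids returned, so the caller can report how many stained somas fell
    outside the imaged field — an expected outcome, not an error.
    """
    kept: list[ROI] = []
    excluded: list[str] = []
    for roi in rois:
        if roi.polygon is None:
            raise ValueError(f"ROI {roi.id!r} has no polygon to transfer")
        verts = transform(roi.polygon)
        mask = rasterize_polygon(verts, target_geometry)
        if not mask.any():
            excluded.append(roi.id)
            continue
        kept.append(ROI(roi.id, polygon=verts, mask=mask, frame="two-photon"))
    return kept, excluded


def extract_traces(
    movie: np.ndarray | str | Path,
    rois: list[ROI],
    sample_rate: float = 8.0,
    epochs: dict[str, tuple[float, float]] | None = None,
) -> list[TrialResponse]:
    """Per-ROI trace: mean intensity over mask pixels for every movie frame.

    ``movie`` is a (frames, rows, cols) array or a multi-page TIFF path; the
    default 8 Hz matches typical two-photon GCaMP acquisition.
    """
    if isinstance(movie, (str, Path)):
        movie = tifffile.imread(movie)
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, rows, cols) stack")
    traces = []
    for roi in rois:
        if roi.mask is None or not np.any(roi.mask):
            raise ValueError(f"ROI {roi.id!r} has an empty mask")
        if roi.mask.shape != movie.shape[1:]:
            raise ValueError(
                f"ROI {roi.id!r} mask shape {roi.mask.shape} does not match "
                f"movie frames {movie.shape[1:]}"
            )
        traces.append(
            TrialResponse(
                movie[:, roi.mask].mean(axis=1), sample_rate, dict(epochs or {})
            )
        )
    return traces
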