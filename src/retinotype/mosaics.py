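"""Mosaic spatial statistics: density recovery profiles (DRPs) and cell densities.

Retinal neurons of a single type form quasi-regular mosaics with an exclusion
zone around each soma.  The DRP measures the average density of like-type cells
in concentric annuli around every reference cell; a dip at short distances is
the signature of a single, regularly spaced type, while a mixture of types (or
an unrelated marker) yields a flat profile at the population density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.spatial.distance import cdist

from .core import FieldGeometry, PointSet

__all__ = [
    "DRProfile",
    "SigmoidFit",
    "density_recovery_profile",
    "normalize_profile",
    "cell_density",
    "fit_sigmoid",
]


@dataclass
class DRProfile:
    """Density recovery profile over uniform half-open annuli ``[kΔ, (k+1)Δ)``.

    ``density_per_bin`` is in cells/mm² unless ``normalized`` is set, in which
    case it is unitless (density relative to a reference density).
    """

    bin_width: float
    bin_edges: np.ndarray
    density_per_bin: np.ndarray
    n_reference_cells: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density_per_bin = np.asarray(self.density_per_bin, dtype=float)
        widths = np.diff(self.bin_edges)
        if not (widths.size and np.allclose(widths, self.bin_width)):
            raise ValueError("bin_edges must increase uniformly by bin_width")
        if np.any(self.density_per_bin < 0):
            raise ValueError("annulus densities must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path: str | Path) -> None:
        col = "density" if self.normalized else "density_per_mm2"
        pd.DataFrame(
            {"bin_center_um": self.bin_centers, col: self.density_per_bin}
        ).to_csv(path, index=False, float_format="%.9g")


@dataclass
class SigmoidFit:
    """4-parameter logistic fit to a DRP, for display only.

    ``f(r) = floor + (ceiling - floor) / (1 + exp(-(r - midpoint)/slope))``
    """

    floor: float
    ceiling: float
    midpoint: float
    slope: float
    rss: float
    converged: bool = True

    def predict(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-(r - self.midpoint) / self.slope)
        )


def density_recovery_profile(
    points: PointSet,
    bin_width: float = 15.0,
    max_radius: float = 300.0,
    edge_correction: str = "none",
) -> DRProfile:
    """Average like-type density in annuli of width ``bin_width`` around each cell.

    For every reference cell, distances to all other cells are binned into
    half-open annuli ``[kΔ, (k+1)Δ)``; counts per annulus are divided by the
    annulus area ``π((k+1)² - k²)Δ²`` and averaged over reference cells.

    Parameters
    ----------
    bin_width
        Annulus width Δ in µm (15 by default; 25 suits sparser mosaics).
    max_radius
        Outermost annulus edge; truncated down to a whole number of annuli.
    edge_correction
        ``"none"`` uses every cell as a reference with no window compensation,
        which underestimates density near the field border by roughly
        ``4r/(π·side)``.  ``"border"`` restricts the reference set to cells at
        least ``max_radius`` from every field edge, whose annuli are complete,
        giving an unbiased profile at the cost of fewer references.
    """
    xy = points.xy
    if len(points) < 2:
        raise ValueError("density_recovery_profile requires at least 2 points")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if max_radius < bin_width:
        raise ValueError("max_radius must be at least one bin_width")
    n_bins = int(max_radius / bin_width + 1e-9)
    edges = bin_width * np.arange(n_bins + 1)

    if edge_correction == "border":
        g = points.geometry
        r = edges[-1]
        ref_mask = (
            (xy[:, 0] >= r)
            & (xy[:, 0] <= g.width - r)
            & (xy[:, 1] >= r)
            & (xy[:, 1] <= g.height - r)
        )
        if not np.any(ref_mask):
            raise ValueError(
                "border edge correction leaves no reference cells; "
                "reduce max_radius or enlarge the field"
            )
    elif edge_correction == "none":
        ref_mask = np.ones(len(points), dtype=bool)
    else:
        raise ValueError(f"unknown edge_correction {edge_correction!r}")

    ref_idx = np.flatnonzero(ref_mask)
    d = cdist(xy[ref_idx], xy)
    # exclude self-pairs by index, not by zero distance (coincident somas stay)
    d[np.arange(ref_idx.size), ref_idx] = np.inf

    counts = np.stack([np.histogram(row, bins=edges)[0] for row in d])
    k = np.arange(n_bins)
    annulus_area_mm2 = np.pi * ((k + 1) ** 2 - k**2) * bin_width**2 * 1e-6
    density = counts.mean(axis=0) / annulus_area_mm2
    return DRProfile(
        bin_width=bin_width,
        bin_edges=edges,
        density_per_bin=density,
        n_reference_cells=int(ref_idx.size),
    )


def normalize_profile(drp: DRProfile, reference_density: float) -> DRProfile:
    """Divide the profile by a reference density (e.g. the whole-population density)."""
    if not reference_density > 0:
        raise ValueError("reference_density must be > 0")
    return replace(
        drp, density_per_bin=drp.density_per_bin / reference_density, normalized=True
    )


def cell_density(points: PointSet) -> float:
    """Cells per mm²: count divided by field area."""
    area = points.geometry.area_mm2
    if not area > 0:
        raise ValueError("field area must be > 0")
    return len(points) / area


def fit_sigmoid(drp: DRProfile) -> SigmoidFit:
    """Least-squares logistic fit over (bin center, density), for plotting.

    A constant profile returns ``floor == ceiling`` with zero residual; failure
    to converge is reported through ``converged=False`` rather than raised.
    """
    r = drp.bin_centers
    y = drp.density_per_bin
    if r.size < 4:
        raise ValueError("fit_sigmoid requires at least 4 annuli")
    if np.ptp(y) == 0:
        return SigmoidFit(float(y[0]), float(y[0]), float(r[0]), 1.0, 0.0)

    def logistic(x, floor, ceiling, midpoint, slope):
        with np.errstate(over="ignore"):  # saturated tails are fine
            return floor + (ceiling - floor) / (1.0 + np.exp(-(x - midpoint) / slope))

    p0 = (float(y.min()), float(y.max()), float(r[np.argmin(np.abs(y - y.mean()))]),
          float(drp.bin_width))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(logistic, r, y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    floor, ceiling, midpoint, slope = (float(v) for v in popt)
    if ceiling < floor:  # keep the reported orientation canonical
        floor, ceiling = ceiling, floor
        slope = -slope
    midpoint = float(np.clip(midpoint, r[0], r[-1]))
    rss = float(np.sum((logistic(r, floor, ceiling, midpoint, slope) - y) ** 2))
    return SigmoidFit(floor, ceiling, midpoint, slope, rss, converged)
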