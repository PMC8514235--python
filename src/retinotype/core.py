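"""Shared containers for the analysis pipeline.

Conventions used throughout the package:

* spatial coordinates are in micrometres (µm), densities in cells/mm²;
* angles are degrees at every public interface and radians only inside
  trigonometric kernels;
* time is in seconds, sampling rates in Hz;
* stimulus epochs are labeled half-open intervals ``[onset, offset)`` on the
  trace's own clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FieldGeometry",
    "PointSet",
    "TrialResponse",
    "EpochError",
]


class EpochError(KeyError):
    """A requested stimulus epoch is missing from a trace."""


@dataclass(frozen=True)
class FieldGeometry:
    """Rectangular imaging field: ``width`` × ``height`` µm, square pixels.

    The default pixel size of 1 µm makes a geometry usable for purely
    point-based analyses where no raster is ever built.
    """

    width: float
    height: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0 and self.pixel_size > 0):
            raise ValueError(
                "FieldGeometry requires width, height and pixel_size > 0, got "
                f"{self.width} x {self.height} @ {self.pixel_size}"
            )

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        return self.area_um2 * 1e-6

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols) covering the field."""
        return (
            int(np.ceil(self.height / self.pixel_size - 1e-9)),
            int(np.ceil(self.width / self.pixel_size - 1e-9)),
        )

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= 0)
            & (xy[..., 0] <= self.width)
            & (xy[..., 1] >= 0)
            & (xy[..., 1] <= self.height)
        )


@dataclass
class PointSet:
    """2-D soma coordinates (µm) inside a field.

    ``xy`` is an (n, 2) float array; rows may be empty.  All points must lie
    inside the geometry and be finite.
    """

    xy: np.ndarray
    geometry: FieldGeometry

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("PointSet coordinates must be finite")
        if xy.size and not np.all(self.geometry.contains(xy)):
            raise ValueError("PointSet contains points outside the field geometry")
        self.xy = xy

    def __len__(self) -> int:
        return self.xy.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write ``id,x_um,y_um`` with the field geometry in comment headers."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# width_um={self.geometry.width:g}\n")
            fh.write(f"# height_um={self.geometry.height:g}\n")
            fh.write(f"# pixel_size_um={self.geometry.pixel_size:g}\n")
            fh.write("id,x_um,y_um\n")
            for i, (x, y) in enumerate(self.xy):
                fh.write(f"{i},{x:.6f},{y:.6f}\n")

    @classmethod
    def from_csv(cls, path: str | Path, geometry: FieldGeometry | None = None) -> "PointSet":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
        df = pd.read_csv(path, comment="#")
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if geometry is None:
            if not {"width_um", "height_um"} <= meta.keys():
                raise ValueError(f"{path}: no geometry header and none supplied")
            geometry = FieldGeometry(
                meta["width_um"], meta["height_um"], meta.get("pixel_size_um", 1.0)
            )
        return cls(xy, geometry)


@dataclass
class TrialResponse:
    """One trial of a time-sampled signal with labeled stimulus epochs.

    Used for fluorescence traces (z-units after :func:`~retinotype.responses.zscore_trace`),
    loose-patch voltage (arbitrary units) and whole-cell current (pA).
    """

    values: np.ndarray
    sample_rate: float
    epochs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        dur = self.duration
        for label, (t0, t1) in self.epochs.items():
            if not (0 <= t0 < t1 <= dur + 0.5 / self.sample_rate):
                raise ValueError(
                    f"epoch {label!r} = ({t0}, {t1}) outside trace of duration {dur:.4f} s"
                )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def epoch_interval(self, label: str) -> tuple[float, float]:
        try:
            return self.epochs[label]
        except KeyError:
            raise EpochError(
                f"epoch {label!r} not found; available: {sorted(self.epochs)}"
            ) from None

    def epoch_mask(self, label: str, *, closed: bool = False) -> np.ndarray:
        """Boolean sample mask for ``[onset, offset)`` (``closed`` ⇒ ``[onset, offset]``)."""
        t0, t1 = self.epoch_interval(label)
        t = self.times
        eps = 0.25 / self.sample_rate
        if closed:
            return (t >= t0 - eps) & (t <= t1 + eps)
        return (t >= t0 - eps) & (t < t1 - eps)

    def epoch_values(self, label: str, *, closed: bool = False) -> np.ndarray:
        return self.values[self.epoch_mask(label, closed=closed)]

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s,value`` plus a JSON sidecar with rate and epochs."""
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False, float_format="%.9g"
        )
        sidecar = {
            "sample_rate_hz": self.sample_rate,
            "epochs": {k: list(v) for k, v in self.epochs.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialResponse":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            rate = float(sidecar["sample_rate_hz"])
            epochs = {k: tuple(v) for k, v in sidecar["epochs"].items()}
        else:
            t = df["time_s"].to_numpy()
            if len(t) < 2:
                raise ValueError(f"{path}: cannot infer sample rate from < 2 samples")
            rate = 1.0 / float(np.median(np.diff(t)))
            epochs = {}
        return cls(df["value"].to_numpy(dtype=float), rate, epochs)
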