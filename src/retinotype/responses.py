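"""Calcium-response feature statistics.

Per-cell descriptive statistics used to type retinal ganglion cells from
GCaMP trial traces:

* baseline z-scoring per trial,
* ON-OFF index ``(ON − OFF)/(ON + OFF)`` from full-field flash responses,
* direction/orientation selectivity via circular variance
  (``DSI = |Σ Respθ·e^{iθ}| / Σ Respθ``; OSI uses the second harmonic
  ``e^{2iθ}``),
* Baden-style trial-reliability quality index,
* cosine-similarity grouping of normalized traces against group means.

Responses are rectified at zero before index computation so that the indices
stay in their nominal ranges; the formulas implicitly assume non-negative
responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrialResponse

__all__ = [
    "TuningCurve",
    "SelectivityResult",
    "zscore_trace",
    "epoch_mean",
    "average_trials",
    "direction_epoch_label",
    "on_off_index",
    "peak_by_direction",
    "direction_selectivity",
    "orientation_selectivity",
    "quality_index",
    "cosine_similarity",
    "group_mean",
    "assign_groups",
]

def direction_epoch_label(angle_deg: float) -> str:
    """Epoch label under which a direction's moving-bar window is stored."""
    return f"bar_{angle_deg:g}"


@dataclass
class TuningCurve:
    """Scalar response per stimulus angle; angles in degrees, evenly spaced on [0, 360)."""

    angles_deg: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.angles_deg.size < 2:
            raise ValueError("TuningCurve requires at least 2 angles")
        if self.angles_deg.shape != self.responses.shape:
            raise ValueError("angles and responses differ in length")
        steps = np.diff(self.angles_deg)
        if not np.allclose(steps, steps[0]):
            raise ValueError("TuningCurve angles must be evenly spaced")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("TuningCurve responses must be finite")


@dataclass(frozen=True)
class SelectivityResult:
    index: float
    preferred_angle: float
    kind: str  # "direction" | "orientation"


def zscore_trace(trial: TrialResponse, baseline_label: str = "baseline") -> TrialResponse:
    """Express a trace in z-units of its own pre-stimulus baseline.

    Mean and SD come from the trial's baseline epoch, so each trial is
    normalized by its own noise floor before trials are combined.
    """
    base = trial.epoch_values(baseline_label)
    if base.size < 2:
        raise ValueError("baseline epoch must contain at least 2 samples")
    mu = base.mean()
    sd = base.std(ddof=0)
    if sd == 0:
        raise ValueError("baseline has zero variance; cannot z-score a flat baseline")
    return TrialResponse((trial.values - mu) / sd, trial.sample_rate, dict(trial.epochs))


def epoch_mean(trial: TrialResponse, label: str) -> float:
    """Arithmetic mean of samples whose timestamps fall in ``[onset, offset)``."""
    vals = trial.epoch_values(label)
    if vals.size == 0:
        raise ValueError(f"epoch {label!r} contains no samples")
    return float(vals.mean())


def on_off_index(on_resp: float, off_resp: float) -> float:
    """(ON − OFF)/(ON + OFF) of rectified mean responses; +1 pure ON, −1 pure OFF."""
    on = max(float(on_resp), 0.0)
    off = max(float(off_resp), 0.0)
    if on == 0 and off == 0:
        raise ValueError("both ON and OFF responses are zero: cell is unresponsive")
    return (on - off) / (on + off)


def average_trials(trials: list[TrialResponse]) -> TrialResponse:
    """Element-wise mean of same-length trials; epochs taken from the first."""
    if not trials:
        raise ValueError("no trials to average")
    n = trials[0].n_samples
    if any(t.n_samples != n for t in trials):
        raise ValueError("trials differ in length")
    mean = np.mean([t.values for t in trials], axis=0)
    return TrialResponse(mean, trials[0].sample_rate, dict(trials[0].epochs))


def peak_by_direction(
    trials: list[TrialResponse], directions: list[float] | None = None
) -> TuningCurve:
    """Respθ: maximum of the trial-averaged trace within each direction's bar epoch.

    Trials are averaged first, then the per-direction maximum is taken and
    rectified at zero.  Directions default to every ``bar_<angle>`` epoch
    present on the traces.
    """
    avg = average_trials(trials)
    if directions is None:
        directions = sorted(
            float(lbl.split("_", 1)[1])
            for lbl in avg.epochs
            if lbl.startswith("bar_") and lbl.count("_") == 1
        )
        if not directions:
            raise ValueError("no bar_<angle> epochs found on the traces")
    resp = []
    for theta in directions:
        vals = avg.epoch_values(direction_epoch_label(theta))
        if vals.size == 0:
            raise ValueError(f"direction {theta}° epoch contains no samples")
        resp.append(max(float(vals.max()), 0.0))
    return TuningCurve(np.asarray(directions, dtype=float), np.asarray(resp))


def _circular_index(tuning: TuningCurve, harmonic: int) -> tuple[float, float]:
    resp = tuning.responses
    if np.any(resp < 0):
        raise ValueError("tuning responses must be non-negative (rectify first)")
    total = resp.sum()
    if total <= 0:
        raise ValueError("all-zero tuning curve: selectivity undefined")
    z = np.sum(resp * np.exp(1j * harmonic * np.deg2rad(tuning.angles_deg)))
    index = float(np.abs(z) / total)
    angle = float(np.rad2deg(np.angle(z)))
    return index, angle


def _wrap(angle: float, period: float) -> float:
    # float modulo can land exactly on the period for arguments a hair below 0
    wrapped = angle % period
    return 0.0 if wrapped >= period else wrapped


def direction_selectivity(tuning: TuningCurve) -> SelectivityResult:
    """DSI = |Σ Respθ·e^{iθ}| / Σ Respθ; preferred direction is the resultant's argument."""
    index, angle = _circular_index(tuning, 1)
    return SelectivityResult(index, _wrap(angle, 360.0), "direction")


def orientation_selectivity(tuning: TuningCurve) -> SelectivityResult:
    """OSI from the second harmonic e^{2iθ}; preferred orientation = (arg/2) mod 180°."""
    index, angle = _circular_index(tuning, 2)
    return SelectivityResult(index, _wrap(angle / 2.0, 180.0), "orientation")


def quality_index(responses: np.ndarray) -> float:
    """Trial-reliability QI on a (trials × time) matrix of z-scored responses.

    Variance over time of the trial-averaged trace, divided by the trial
    average of each trial's variance over time.  1 for perfectly repeatable
    responses; ≈ 1/n_trials for independent noise.
    """
    m = np.asarray(responses, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("quality_index needs a (≥2 trials, ≥2 time points) matrix")
    denom = m.var(axis=1, ddof=0).mean()
    if denom == 0:
        raise ValueError("all trials are flat: quality index undefined")
    return float(m.mean(axis=0).var(ddof=0) / denom)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-norm trace")
    return v / n


def cosine_similarity(trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """Cosine between two Euclidean-normalized traces, in [−1, 1]."""
    a, b = _unit(trace_a), _unit(trace_b)
    if a.size != b.size:
        raise ValueError("traces differ in length")
    return float(np.clip(a @ b, -1.0, 1.0))


def group_mean(traces: np.ndarray) -> np.ndarray:
    """Shape template of a group: normalize each trace, average, re-normalize."""
    m = np.asarray(traces, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("group_mean needs a non-empty (traces × time) matrix")
    unit = np.stack([_unit(row) for row in m])
    return _unit(unit.mean(axis=0))


def assign_groups(
    traces: np.ndarray, group_means: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Label each trace with its most cosine-similar group mean.

    Returns ``(labels, similarity)`` where ``similarity`` is the full
    trace × group matrix.  Ties go to the lowest group index.
    """
    traces = np.asarray(traces, dtype=float)
    group_means = np.asarray(group_means, dtype=float)
    if group_means.ndim != 2 or group_means.shape[0] < 1:
        raise ValueError("at least one group mean is required")
    if traces.shape[1] != group_means.shape[1]:
        raise ValueError("traces and group means differ in length")
    t_unit = np.stack([_unit(row) for row in traces])
    g_unit = np.stack([_unit(row) for row in group_means])
    similarity = t_unit @ g_unit.T
    labels = np.argmax(similarity, axis=1)  # argmax takes the first on ties
    return labels, similarity
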