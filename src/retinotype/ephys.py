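"""Spike and synaptic-current analysis.

Loose-patch voltage traces are reduced to spike trains by robust peak
detection, binned into 50 ms peristimulus time histograms (PSTHs), and fed to
the same circular-variance tuning indices used for calcium data.  Whole-cell
currents are baseline-subtracted against the pre-stimulus gray period and
integrated trapezoidally over each stimulus epoch to give charge in pC;
per-cell orientation-tuning curves of charge are normalized to a control
reference, circularly aligned on their peaks, and averaged across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmax

from .core import TrialResponse
from .responses import TuningCurve

__all__ = [
    "SpikeTrain",
    "FiringRateHistogram",
    "ChargeResult",
    "detect_spikes",
    "psth",
    "tuning_from_psth",
    "integrate_charge",
    "normalized_orientation_tuning",
]


@dataclass
class SpikeTrain:
    """Strictly increasing spike times (s) within a trial of known duration."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float).ravel()
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class FiringRateHistogram:
    """Trial-averaged firing rate (Hz) in uniform bins tiling [0, duration)."""

    bin_width: float
    bin_edges: np.ndarray
    rates: np.ndarray
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ChargeResult:
    epoch: str
    peak_pa: float
    charge_pc: float
    baseline_pa: float


def detect_spikes(
    voltage: TrialResponse,
    threshold_k: float = 5.0,
    refractory: float = 0.002,
    baseline_label: str | None = None,
) -> SpikeTrain:
    """Peak-based spike detection with a robust, baseline-referenced threshold.

    Local maxima exceeding ``median + threshold_k · (1.4826·MAD)`` of the
    baseline (the whole trace when no baseline epoch is named) are candidate
    spikes; within any ``refractory`` window the earliest peak wins.  A flat
    trace yields an empty train rather than an error.
    """
    if not threshold_k > 0:
        raise ValueError("threshold_k must be > 0")
    v = voltage.values
    base = voltage.epoch_values(baseline_label) if baseline_label else v
    med = np.median(base)
    mad = np.median(np.abs(base - med))
    thr = med + threshold_k * 1.4826 * mad
    if mad == 0 and np.ptp(v) == 0:
        return SpikeTrain(np.empty(0), voltage.duration)

    peaks = argrelmax(v)[0]
    peaks = peaks[v[peaks] > thr]
    kept: list[int] = []
    min_gap = refractory * voltage.sample_rate
    for p in peaks:  # greedy: earliest peak in each refractory window wins
        if not kept or p - kept[-1] >= min_gap:
            kept.append(int(p))
    return SpikeTrain(np.asarray(kept, dtype=float) / voltage.sample_rate, voltage.duration)


def psth(
    trains: list[SpikeTrain], bin_width: float = 0.05, duration: float | None = None
) -> FiringRateHistogram:
    """Per-trial spike counts per bin divided by bin width, averaged over trials."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not trains:
        raise ValueError("psth requires at least one spike train")
    if duration is None:
        duration = trains[0].duration
    if any(abs(t.duration - duration) > 1e-9 for t in trains):
        raise ValueError("all trains must share the trial duration")
    n_bins = max(1, int(np.ceil(duration / bin_width - 1e-9)))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.stack(
        [np.histogram(t.spike_times, bins=edges)[0] for t in trains]
    ).astype(float)
    rates = counts.mean(axis=0) / bin_width
    return FiringRateHistogram(bin_width, edges, rates, len(trains))


def tuning_from_psth(
    histograms: dict[float, FiringRateHistogram],
    response_windows: dict[float, tuple[float, float]] | None = None,
) -> TuningCurve:
    """Respθ = maximum mean firing rate per direction, ready for DSI/OSI.

    ``histograms`` maps direction (degrees) to its PSTH; an optional response
    window ``(t0, t1)`` per direction restricts the maximum to the stimulus
    epoch (the full histogram is used otherwise).
    """
    if not histograms:
        raise ValueError("no per-direction histograms supplied")
    angles = sorted(histograms)
    resp = []
    for theta in angles:
        h = histograms[theta]
        rates = h.rates
        if response_windows is not None:
            if theta not in response_windows:
                raise ValueError(f"missing response window for direction {theta}°")
            t0, t1 = response_windows[theta]
            sel = (h.bin_centers >= t0) & (h.bin_centers < t1)
            if not sel.any():
                raise ValueError(f"response window for {theta}° covers no bins")
            rates = rates[sel]
        resp.append(float(rates.max()))
    return TuningCurve(np.asarray(angles, dtype=float), np.asarray(resp))


def integrate_charge(
    current: TrialResponse, epoch: str, baseline_window: str = "baseline"
) -> ChargeResult:
    """Trapezoidal integral of baseline-subtracted current over a stimulus epoch.

    The baseline is the median of the pre-stimulus window (robust to
    occasional spontaneous events).  Current in pA integrated over seconds
    gives charge directly in pC; the peak is the signed extremum of the
    baseline-subtracted current within the epoch.  The epoch interval is
    treated as closed so that a constant 10 pA step over 0.5 s integrates to
    exactly 5 pC.
    """
    base = current.epoch_values(baseline_window)
    if base.size == 0:
        raise ValueError(f"baseline window {baseline_window!r} contains no samples")
    baseline = float(np.median(base))
    mask = current.epoch_mask(epoch, closed=True)
    if not mask.any():
        raise ValueError(f"epoch {epoch!r} contains no samples")
    x = current.values[mask] - baseline
    t = current.times[mask]
    charge = float(np.trapezoid(x, t))
    peak = float(x[np.argmax(np.abs(x))]) if x.size else 0.0
    return ChargeResult(epoch, peak, charge, baseline)


def normalized_orientation_tuning(
    per_cell: dict[str, np.ndarray], control_reference: float
) -> tuple[np.ndarray, dict[str, np.ndarray], int]:
    """Control-normalized, peak-aligned mean orientation-tuning curve.

    Each cell's per-orientation integrated charges are divided by
    ``control_reference`` (the average maximum in control cells), circularly
    shifted so the cell's maximum sits at the center grid position (ties go to
    the earliest orientation), and averaged element-wise across cells.

    Returns ``(mean_curve, aligned per-cell curves, n_cells)``.
    """
    if not control_reference > 0:
        raise ValueError("control_reference must be > 0")
    if not per_cell:
        raise ValueError("no cells supplied")
    lengths = {np.asarray(v).size for v in per_cell.values()}
    if len(lengths) != 1:
        raise ValueError("all cells must share the orientation grid")
    n_ori = lengths.pop()
    center = n_ori // 2
    aligned: dict[str, np.ndarray] = {}
    for cell, curve in per_cell.items():
        c = np.asarray(curve, dtype=float) / control_reference
        aligned[cell] = np.roll(c, center - int(np.argmax(c)))
    mean_curve = np.mean(list(aligned.values()), axis=0)
    return mean_curve, aligned, len(per_cell)
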