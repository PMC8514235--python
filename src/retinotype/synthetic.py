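"""Synthetic-data generators with recorded ground truth.

Every input class the pipeline consumes can be generated here with its
generating parameters known, so downstream stages are testable by parameter
recovery:

* soma mosaics — complete spatial randomness or hard-core (exclusion-zone)
  point processes via random sequential adsorption;
* GCaMP-like trial traces — von Mises direction tuning driving leading/
  trailing-edge bar epochs and full-field flashes, convolved with a
  single-exponential calcium kernel, plus i.i.d. Gaussian noise;
* paired landmark fields related by a known similarity transform with jitter;
* inhomogeneous-Poisson spike trains (thinning);
* branched 3-D dendritic trees with bookkept total length and branch count;
* piecewise-constant synaptic-current traces.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FieldGeometry, PointSet, TrialResponse
from .ephys import SpikeTrain
from .morpho import Arbor
from .register import LandmarkPairs, SimilarityTransform
from .responses import direction_epoch_label

__all__ = [
    "MosaicParams",
    "CellTuningParams",
    "StimulusProtocol",
    "ArborTruth",
    "PackingInfeasibleError",
    "generate_mosaic",
    "generate_trial_responses",
    "generate_landmark_fields",
    "generate_spike_trains",
    "generate_arbor",
    "generate_current_trace",
    "generate_roi_movie",
]


class PackingInfeasibleError(RuntimeError):
    """The requested hard-core mosaic cannot be packed into the field."""


@dataclass(frozen=True)
class MosaicParams:
    """Ground truth for a simulated mosaic.

    ``exclusion_radius = 0`` gives complete spatial randomness (CSR); a
    positive radius enforces a hard core: no two somas closer than it.
    """

    intensity: float  # cells per mm²
    exclusion_radius: float = 0.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.exclusion_radius < 0:
            raise ValueError("intensity and exclusion_radius must be >= 0")


_MAX_ATTEMPTS_PER_POINT = 10_000


def generate_mosaic(params: MosaicParams, geometry: FieldGeometry) -> PointSet:
    """Random sequential adsorption (dart throwing) of a soma mosaic.

    The target count is Poisson(intensity × area); each point is drawn
    uniformly and rejected if it violates the exclusion radius, with a bounded
    number of attempts before the packing is declared infeasible.
    """
    rng = np.random.default_rng(params.seed)
    n_target = int(rng.poisson(params.intensity * geometry.area_mm2))
    if n_target == 0:
        return PointSet(np.empty((0, 2)), geometry)

    accepted = np.empty((n_target, 2))
    n_placed = 0
    r2 = params.exclusion_radius**2
    while n_placed < n_target:
        for attempt in range(_MAX_ATTEMPTS_PER_POINT):
            p = rng.uniform((0, 0), (geometry.width, geometry.height))
            if n_placed == 0 or r2 == 0:
                break
            d2 = np.sum((accepted[:n_placed] - p) ** 2, axis=1)
            if d2.min() >= r2:
                break
        else:
            raise PackingInfeasibleError(
                f"placed {n_placed}/{n_target} points; exclusion radius "
                f"{params.exclusion_radius} µm is too large for intensity "
                f"{params.intensity}/mm² in a {geometry.width}x{geometry.height} µm field"
            )
        accepted[n_placed] = p
        n_placed += 1
    return PointSet(accepted, geometry)


@dataclass(frozen=True)
class CellTuningParams:
    """Ground-truth response parameters of one simulated cell."""

    preferred_direction: float = 0.0  # degrees in [0, 360)
    kappa: float = 3.0  # von Mises concentration; 0 = untuned
    on_amplitude: float = 1.0
    off_amplitude: float = 0.5
    noise_sd: float = 0.1
    decay_tau: float = 0.2  # s, GCaMP6f-like single-exponential decay

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not self.decay_tau > 0:
            raise ValueError("decay_tau must be > 0")
        if min(self.on_amplitude, self.off_amplitude, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be >= 0")

    def tuning_weight(self, direction_deg: float) -> float:
        """Normalized von Mises tuning, 1 at the preferred direction."""
        d = np.deg2rad(direction_deg - self.preferred_direction)
        return float(np.exp(self.kappa * (np.cos(d) - 1.0)))


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus timing for one trial: baseline, full-field flashes, moving bars.

    ``epochs`` maps labels to ``(onset, offset)`` seconds: ``baseline``,
    ``full_on``, ``full_off``, and for each direction a whole-crossing epoch
    ``bar_<angle>`` with ``bar_<angle>_lead`` / ``bar_<angle>_trail``
    sub-epochs covering the passage of the leading and trailing bar edges over
    the imaged field.
    """

    directions: tuple[float, ...]
    bar_width: float
    bar_length: float
    speed: float
    field_width: float
    baseline_duration: float
    epochs: dict[str, tuple[float, float]]
    duration: float

    @classmethod
    def moving_bar(
        cls,
        directions: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315),
        bar_width: float = 1200.0,
        bar_length: float = 3200.0,
        speed: float = 240.0,
        field_width: float = 360.0,
        baseline_duration: float = 2.0,
        full_field_duration: float = 2.0,
        gap: float = 1.0,
    ) -> "StimulusProtocol":
        """Standard protocol: baseline, ON/OFF full-field flash, 8 bar directions.

        The bar moves along its long axis; the whole crossing takes
        ``(bar_length + field_width)/speed`` seconds, and each edge sweeps the
        field in ``field_width/speed`` seconds.  ``gap`` seconds of background
        separate consecutive stimulus epochs so indicator decay from one epoch
        does not bleed into the next.
        """
        if baseline_duration <= 0:
            raise ValueError("baseline_duration must be > 0")
        if not directions:
            raise ValueError("protocol needs at least one bar direction")
        epochs: dict[str, tuple[float, float]] = {}
        t = 0.0
        epochs["baseline"] = (t, t + baseline_duration)
        t += baseline_duration
        epochs["full_on"] = (t, t + full_field_duration)
        t += full_field_duration + gap
        epochs["full_off"] = (t, t + full_field_duration)
        t += full_field_duration + gap
        crossing = (bar_length + field_width) / speed
        edge = field_width / speed
        for theta in directions:
            label = direction_epoch_label(theta)
            epochs[label] = (t, t + crossing)
            epochs[label + "_lead"] = (t, t + edge)
            epochs[label + "_trail"] = (t + crossing - edge, t + crossing)
            t += crossing + gap
        return cls(
            tuple(float(d) for d in directions),
            bar_width,
            bar_length,
            speed,
            field_width,
            baseline_duration,
            epochs,
            t,
        )


def _calcium_kernel(tau: float, frame_rate: float) -> np.ndarray:
    """Single-exponential decay kernel, unit peak, truncated at 5·tau."""
    t = np.arange(0.0, 5.0 * tau, 1.0 / frame_rate)
    return np.exp(-t / tau)


def generate_trial_responses(
    cell: CellTuningParams,
    protocol: StimulusProtocol,
    n_trials: int = 5,
    frame_rate: float = 8.0,
    seed: int = 0,
) -> list[TrialResponse]:
    """Simulate GCaMP trial traces for one cell under a stimulus protocol.

    The stimulus drive is ``on_amplitude · vonMises(θ)`` during each
    direction's leading-edge epoch, ``off_amplitude · vonMises(θ)`` during the
    trailing-edge epoch, and the plain ON/OFF amplitudes during the full-field
    flashes.  The drive is convolved with the cell's calcium kernel and
    i.i.d. Gaussian noise of SD ``noise_sd`` is added per frame.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not frame_rate > 0:
        raise ValueError("frame_rate must be > 0")
    if not protocol.epochs:
        raise ValueError("protocol has no epochs")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(protocol.duration * frame_rate))
    t = np.arange(n) / frame_rate

    drive = np.zeros(n)

    def add(label: str, amp: float) -> None:
        t0, t1 = protocol.epochs[label]
        drive[(t >= t0) & (t < t1)] += amp

    add("full_on", cell.on_amplitude)
    add("full_off", cell.off_amplitude)
    for theta in protocol.directions:
        w = cell.tuning_weight(theta)
        add(direction_epoch_label(theta) + "_lead", cell.on_amplitude * w)
        add(direction_epoch_label(theta) + "_trail", cell.off_amplitude * w)

    kernel = _calcium_kernel(cell.decay_tau, frame_rate)
    clean = np.convolve(drive, kernel)[:n]
    trials = []
    for _ in range(n_trials):
        noise = rng.normal(0.0, cell.noise_sd, n) if cell.noise_sd > 0 else 0.0
        trials.append(TrialResponse(clean + noise, frame_rate, dict(protocol.epochs)))
    return trials


def generate_landmark_fields(
    n_landmarks: int,
    transform: SimilarityTransform,
    jitter_sd: float = 0.0,
    seed: int = 0,
    extent: float = 1000.0,
) -> LandmarkPairs:
    """Paired vessel-landmark coordinates: target = transform(source) + jitter."""
    if n_landmarks < 2:
        raise ValueError("at least 2 landmarks are required")
    rng = np.random.default_rng(seed)
    source = rng.uniform(0.0, extent, size=(n_landmarks, 2))
    target = transform(source)
    if jitter_sd > 0:
        target = target + rng.normal(0.0, jitter_sd, size=target.shape)
    return LandmarkPairs(source, target)


def generate_spike_trains(
    rate_fn,
    duration: float,
    n_trials: int = 1,
    seed: int = 0,
    rate_max: float | None = None,
) -> list[SpikeTrain]:
    """Inhomogeneous Poisson spike trains by thinning.

    ``rate_fn`` maps a time array (s) to instantaneous rate (Hz) and must be
    non-negative everywhere; ``rate_max`` bounds it (estimated on a dense grid
    when omitted).
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, duration, 2001)
    grid_rates = np.asarray(rate_fn(grid), dtype=float)
    if np.any(grid_rates < 0):
        raise ValueError("rate_fn must be non-negative everywhere")
    if rate_max is None:
        rate_max = float(grid_rates.max()) * 1.05
    trains = []
    for _ in range(n_trials):
        if rate_max <= 0:
            trains.append(SpikeTrain(np.empty(0), duration))
            continue
        n_cand = rng.poisson(rate_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        rates = np.asarray(rate_fn(cand), dtype=float)
        if np.any(rates < 0):
            raise ValueError("rate_fn must be non-negative everywhere")
        keep = rng.uniform(0.0, rate_max, n_cand) < rates
        times = cand[keep]
        times = times[np.concatenate(([True], np.diff(times) > 0))] if times.size else times
        trains.append(SpikeTrain(times, duration))
    return trains


@dataclass
class ArborTruth:
    """Generator bookkeeping for a simulated arbor."""

    total_length: float
    n_branch_points: int
    n_terminals: int


def generate_arbor(
    n_branch_events: int = 5,
    segment_length_mean: float = 20.0,
    seed: int = 0,
    steps_per_path: int = 5,
) -> tuple[Arbor, ArborTruth]:
    """Grow a rooted, binary-branching 3-D tree with recorded ground truth.

    An initial path of ``steps_per_path`` segments leaves the soma; each
    branch event picks a random pass-through node and attaches a fresh path,
    turning it into a branch point.  Segment step lengths are
    Exp(segment_length_mean) and directions drift smoothly.  Returns the arbor
    and its bookkept total length / branch count.
    """
    if n_branch_events < 0:
        raise ValueError("n_branch_events must be >= 0")
    if n_branch_events > 0 and steps_per_path < 2:
        raise ValueError("steps_per_path must be >= 2 when branching is requested")
    rng = np.random.default_rng(seed)
    xyz = [np.zeros(3)]
    parent = [-1]
    n_children = [0]
    total = 0.0

    def random_dir(near: np.ndarray | None = None) -> np.ndarray:
        v = rng.normal(size=3)
        v[2] *= 0.1  # quasi-planar, like a flat-mount arbor
        if near is not None:
            v = 0.7 * near + 0.5 * v
        return v / np.linalg.norm(v)

    def grow_path(start: int, direction: np.ndarray) -> None:
        nonlocal total
        node = start
        for _ in range(steps_per_path):
            step = rng.exponential(segment_length_mean) + 1e-3
            direction = random_dir(direction)
            xyz.append(xyz[node] + step * direction)
            parent.append(node)
            n_children[node] += 1
            n_children.append(0)
            total += step
            node = len(xyz) - 1

    grow_path(0, random_dir())
    for _ in range(n_branch_events):
        candidates = [
            i for i in range(1, len(xyz)) if n_children[i] == 1
        ]  # pass-through nodes become branch points
        node = int(rng.choice(candidates))
        away = xyz[node] - xyz[parent[node]]
        grow_path(node, random_dir(away / np.linalg.norm(away)))

    arbor = Arbor(
        np.asarray(xyz), np.full(len(xyz), 0.5), np.asarray(parent, dtype=int)
    )
    n_bp = sum(1 for c in n_children if c >= 2)
    n_term = sum(1 for i, c in enumerate(n_children) if c == 0 and i != 0)
    return arbor, ArborTruth(total, n_bp, n_term)


def generate_current_trace(
    epochs: dict[str, tuple[float, float]],
    amplitudes: dict[str, float],
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    sample_rate: float = 10_000.0,
    seed: int = 0,
    duration: float | None = None,
) -> TrialResponse:
    """Piecewise-constant current (pA): baseline + per-epoch amplitude + noise."""
    if not sample_rate > 0:
        raise ValueError("sample_rate must be > 0")
    if duration is None:
        duration = max(t1 for _, t1 in epochs.values()) + 0.1
    n = int(np.ceil(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    for label, (t0, t1) in epochs.items():
        if not (0 <= t0 < t1 <= duration):
            raise ValueError(f"epoch {label!r} = ({t0}, {t1}) outside trace duration {duration}")
    rng = np.random.default_rng(seed)
    values = np.full(n, float(baseline))
    for label, amp in amplitudes.items():
        if label not in epochs:
            raise ValueError(f"amplitude given for unknown epoch {label!r}")
        t0, t1 = epochs[label]
        values[(t >= t0) & (t <= t1)] += amp
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, n)
    return TrialResponse(values, sample_rate, dict(epochs))


def generate_roi_movie(
    masks: list[np.ndarray],
    traces: list[np.ndarray],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Paint known traces into ROI masks to make a (frames, rows, cols) movie."""
    if len(masks) != len(traces):
        raise ValueError("one trace per mask is required")
    if not masks:
        raise ValueError("at least one mask is required")
    n_frames = len(np.asarray(traces[0]))
    movie = np.zeros((n_frames,) + masks[0].shape)
    for mask, trace in zip(masks, traces):
        trace = np.asarray(trace, dtype=float)
        movie[:, mask] += trace[:, None]
    if noise_sd > 0:
        movie += np.random.default_rng(seed).normal(0.0, noise_sd, movie.shape)
    return movie
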