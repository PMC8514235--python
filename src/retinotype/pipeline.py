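"""End-to-end orchestration: simulate → analyze → report, with provenance.

A run is described by a JSON config naming the stages to execute and their
parameters.  Every stage writes plain-text outputs (CSV/JSON/SWC/TIFF) into
the run directory, and the run ends with a ``manifest.json`` listing the
config, the seeds actually used and a SHA-256 hash of every output, so a
rerun with the same config can be checked for bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import ephys, morpho, mosaics, register, responses, synthetic
from .core import FieldGeometry, PointSet, TrialResponse

__all__ = ["RunConfig", "run_pipeline", "demo_config", "PipelineError"]

log = logging.getLogger("retinotype")

_KNOWN_STAGES = ("mosaic", "registration", "responses", "ephys", "morphometry")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    stages: tuple[str, ...] = _KNOWN_STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "RunConfig":
        cfg = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        if not isinstance(cfg, dict):
            raise PipelineError("config must be a JSON object")
        seed = cfg.get("seed", 0)
        if not isinstance(seed, int):
            raise PipelineError("config 'seed' must be an integer")
        stages = tuple(cfg.get("stages", _KNOWN_STAGES))
        unknown = [s for s in stages if s not in _KNOWN_STAGES]
        if unknown:
            raise PipelineError(
                f"unknown stage(s) {unknown}; known stages: {list(_KNOWN_STAGES)}"
            )
        params = {k: v for k, v in cfg.items() if k in _KNOWN_STAGES}
        for stage, p in params.items():
            if not isinstance(p, dict):
                raise PipelineError(f"stage {stage!r}: parameters must be an object")
        # declared external inputs must exist up front
        traces_dir = params.get("responses", {}).get("traces_dir")
        if traces_dir is not None and not Path(traces_dir).is_dir():
            raise PipelineError(
                f"responses stage: traces directory not found: {traces_dir}"
            )
        points_csv = params.get("mosaic", {}).get("points_csv")
        if points_csv is not None and not Path(points_csv).is_file():
            raise PipelineError(f"mosaic stage: points file not found: {points_csv}")
        return cls(seed=seed, stages=stages, params=params)


def demo_config(seed: int = 0) -> dict:
    """A small configuration exercising every stage in well under a minute."""
    return {
        "seed": seed,
        "stages": list(_KNOWN_STAGES),
        "mosaic": {
            "intensity": 100.0,
            "exclusion_radius": 40.0,
            "field_um": [1000.0, 1000.0],
            "bin_width": 15.0,
            "max_radius": 150.0,
        },
        "registration": {
            "n_landmarks": 30,
            "rotation_deg": 30.0,
            "scale": 1.1,
            "translation": [10.0, 5.0],
            "jitter_sd": 1.0,
        },
        "responses": {"n_cells_per_group": 3, "n_trials": 5, "frame_rate": 8.0},
        "ephys": {"n_trials": 10, "peak_rate_hz": 40.0, "kappa": 3.0},
        "morphometry": {"n_branch_events": 6, "sholl_step": 10.0},
    }


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: str | Path | dict | RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_json(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    root_seq = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_KNOWN_STAGES, root_seq.spawn(len(_KNOWN_STAGES)))
    }

    runners = {
        "mosaic": _run_mosaic,
        "registration": _run_registration,
        "responses": _run_responses,
        "ephys": _run_ephys,
        "morphometry": _run_morphometry,
    }
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        try:
            outputs.extend(
                runners[stage](cfg.params.get(stage, {}), stage_seeds[stage], out)
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {
            "seed": cfg.seed,
            "stages": list(cfg.stages),
            **{k: v for k, v in cfg.params.items()},
        },
        "stage_seeds": stage_seeds,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


# ------------------------------------------------------------------- stages

def _run_mosaic(p: dict, seed: int, out: Path) -> list[Path]:
    field_um = p.get("field_um", [1000.0, 1000.0])
    geometry = FieldGeometry(field_um[0], field_um[1])
    if "points_csv" in p:
        points = PointSet.from_csv(p["points_csv"], geometry)
    else:
        params = synthetic.MosaicParams(
            intensity=p.get("intensity", 100.0),
            exclusion_radius=p.get("exclusion_radius", 40.0),
            seed=seed,
        )
        points = synthetic.generate_mosaic(params, geometry)
    drp = mosaics.density_recovery_profile(
        points,
        bin_width=p.get("bin_width", 15.0),
        max_radius=p.get("max_radius", 150.0),
        edge_correction=p.get("edge_correction", "none"),
    )
    fit = mosaics.fit_sigmoid(drp)
    points_path = out / "mosaic_points.csv"
    drp_path = out / "mosaic_drp.csv"
    summary_path = out / "mosaic_summary.json"
    points.to_csv(points_path)
    drp.to_csv(drp_path)
    _write_json(
        summary_path,
        {
            "density_per_mm2": mosaics.cell_density(points),
            "n_cells": len(points),
            "n_reference_cells": drp.n_reference_cells,
            "sigmoid": {
                "floor": fit.floor,
                "ceiling": fit.ceiling,
                "midpoint_um": fit.midpoint,
                "slope_um": fit.slope,
                "rss": fit.rss,
                "converged": fit.converged,
            },
        },
    )
    return [points_path, drp_path, summary_path]


def _run_registration(p: dict, seed: int, out: Path) -> list[Path]:
    true_t = register.SimilarityTransform(
        p.get("rotation_deg", 30.0),
        p.get("scale", 1.1),
        tuple(p.get("translation", [10.0, 5.0])),
    )
    pairs = synthetic.generate_landmark_fields(
        p.get("n_landmarks", 30), true_t, jitter_sd=p.get("jitter_sd", 1.0), seed=seed
    )
    est, rms = register.estimate_similarity_transform(pairs)

    # a toy two-ROI movie in the target frame exercises transfer + extraction
    geometry = FieldGeometry(64.0, 32.0, pixel_size=1.0)
    rois = [
        register.ROI("cell_a", polygon=[(5, 5), (15, 5), (15, 15), (5, 15)]),
        register.ROI("cell_b", polygon=[(40, 10), (55, 10), (55, 25), (40, 25)]),
    ]
    kept, excluded = register.transfer_rois(
        rois, register.SimilarityTransform(), geometry
    )
    rng = np.random.default_rng(seed)
    frames = 40
    true_traces = [
        2.0 + np.sin(2 * np.pi * np.arange(frames) / 16.0),
        1.0 + (np.arange(frames) >= 20) * 2.0,
    ]
    movie = synthetic.generate_roi_movie(
        [r.mask for r in kept], true_traces, noise_sd=0.05, seed=int(rng.integers(2**31))
    )
    movie_path = out / "registration_movie.tif"
    tifffile.imwrite(movie_path, movie.astype(np.float32))
    traces = register.extract_traces(movie, kept, sample_rate=8.0)

    pairs_path = out / "registration_landmarks.csv"
    transform_path = out / "registration_transform.json"
    traces_path = out / "registration_traces.csv"
    pairs.to_csv(pairs_path)
    _write_json(
        transform_path,
        {
            "estimated": est.to_json(),
            "true": true_t.to_json(),
            "rms_residual_um": rms,
            "rois_transferred": [r.id for r in kept],
            "rois_excluded": excluded,
        },
    )
    pd.DataFrame(
        {r.id: tr.values for r, tr in zip(kept, traces)}
    ).to_csv(traces_path, index=False, float_format="%.9g")
    return [pairs_path, transform_path, traces_path, movie_path]


def _run_responses(p: dict, seed: int, out: Path) -> list[Path]:
    protocol = synthetic.StimulusProtocol.moving_bar()
    n_per_group = int(p.get("n_cells_per_group", 3))
    n_trials = int(p.get("n_trials", 5))
    frame_rate = float(p.get("frame_rate", 8.0))
    archetypes = {
        "on_sustained": synthetic.CellTuningParams(0.0, 0.0, 1.2, 0.05, 0.1),
        "on_ds_ventral": synthetic.CellTuningParams(270.0, 3.0, 1.0, 0.1, 0.1),
        "on_ds_dorsal": synthetic.CellTuningParams(90.0, 3.0, 1.0, 0.1, 0.1),
        "on_off_local": synthetic.CellTuningParams(0.0, 0.5, 0.8, 0.8, 0.1),
    }
    rng = np.random.default_rng(seed)
    rows = []
    group_traces: dict[str, list[np.ndarray]] = {g: [] for g in archetypes}
    cell_traces: list[tuple[str, str, np.ndarray, list[TrialResponse]]] = []
    for group, base in archetypes.items():
        for i in range(n_per_group):
            trials = synthetic.generate_trial_responses(
                base, protocol, n_trials, frame_rate, seed=int(rng.integers(2**31))
            )
            z = [responses.zscore_trace(t) for t in trials]
            avg = responses.average_trials(z)
            group_traces[group].append(avg.values)
            cell_traces.append((f"{group}_{i}", group, avg.values, z))

    means = np.stack([responses.group_mean(np.stack(v)) for v in group_traces.values()])
    labels, sim = responses.assign_groups(
        np.stack([c[2] for c in cell_traces]), means
    )
    group_names = list(archetypes)
    for (cell_id, true_group, avg_values, z), lab, s in zip(cell_traces, labels, sim):
        trial_avg = responses.average_trials(z)
        tuning = responses.peak_by_direction(z)
        dsi = responses.direction_selectivity(tuning)
        osi = responses.orientation_selectivity(tuning)
        onoff = responses.on_off_index(
            responses.epoch_mean(trial_avg, "full_on"),
            responses.epoch_mean(trial_avg, "full_off"),
        )
        qi = responses.quality_index(np.stack([t.values for t in z]))
        rows.append(
            {
                "cell_id": cell_id,
                "true_group": true_group,
                "assigned_group": group_names[lab],
                "similarity": float(s[lab]),
                "onoff_index": onoff,
                "dsi": dsi.index,
                "pref_dir_deg": dsi.preferred_angle,
                "osi": osi.index,
                "pref_ori_deg": osi.preferred_angle,
                "qi": qi,
            }
        )
    metrics_path = out / "response_metrics.csv"
    pd.DataFrame(rows).to_csv(metrics_path, index=False, float_format="%.9g")
    return [metrics_path]


def _run_ephys(p: dict, seed: int, out: Path) -> list[Path]:
    n_trials = int(p.get("n_trials", 10))
    peak_rate = float(p.get("peak_rate_hz", 40.0))
    kappa = float(p.get("kappa", 3.0))
    preferred = float(p.get("preferred_direction", 90.0))
    directions = [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]
    rng = np.random.default_rng(seed)
    hists = {}
    for theta in directions:
        w = float(np.exp(kappa * (np.cos(np.deg2rad(theta - preferred)) - 1.0)))
        rate = 2.0 + peak_rate * w

        def rate_fn(t, r=rate):
            return np.where((np.asarray(t) >= 0.5) & (np.asarray(t) < 1.5), r, 2.0)

        trains = synthetic.generate_spike_trains(
            rate_fn, 2.0, n_trials, seed=int(rng.integers(2**31))
        )
        hists[theta] = ephys.psth(trains, bin_width=0.05)
    tuning = ephys.tuning_from_psth(hists, {th: (0.5, 1.5) for th in directions})
    dsi = responses.direction_selectivity(tuning)
    osi = responses.orientation_selectivity(tuning)

    # whole-cell charge over an oriented-bar flash
    epochs = {"baseline": (0.0, 0.5), "stim": (0.5, 1.0)}
    orientations = [0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5]
    per_cell = {}
    for cell in range(3):
        cell_curve = []
        shift = rng.integers(len(orientations))
        for k, _ori in enumerate(orientations):
            amp = -(20.0 + 60.0 * np.exp(-(((k - shift) % 8 - 4) ** 2) / 4.0))
            trace = synthetic.generate_current_trace(
                epochs, {"stim": amp}, baseline=-5.0, noise_sd=1.0,
                sample_rate=2000.0, seed=int(rng.integers(2**31)),
            )
            cell_curve.append(ephys.integrate_charge(trace, "stim").charge_pc)
        per_cell[f"cell_{cell}"] = np.abs(np.asarray(cell_curve))
    ref = float(np.mean([c.max() for c in per_cell.values()]))
    mean_curve, aligned, n_cells = ephys.normalized_orientation_tuning(per_cell, ref)

    tuning_path = out / "ephys_tuning.csv"
    charge_path = out / "ephys_charge_tuning.csv"
    summary_path = out / "ephys_summary.json"
    pd.DataFrame(
        {"direction_deg": tuning.angles_deg, "peak_rate_hz": tuning.responses}
    ).to_csv(tuning_path, index=False, float_format="%.9g")
    pd.DataFrame(
        {"orientation_index": np.arange(len(mean_curve)), "normalized_charge": mean_curve}
    ).to_csv(charge_path, index=False, float_format="%.9g")
    _write_json(
        summary_path,
        {
            "dsi": dsi.index,
            "preferred_direction_deg": dsi.preferred_angle,
            "osi": osi.index,
            "n_cells_charge": n_cells,
            "control_reference_pc": ref,
        },
    )
    return [tuning_path, charge_path, summary_path]


def _run_morphometry(p: dict, seed: int, out: Path) -> list[Path]:
    arbor, truth = synthetic.generate_arbor(
        n_branch_events=int(p.get("n_branch_events", 6)), seed=seed
    )
    swc_path = out / "morphometry_arbor.swc"
    morpho.write_swc(arbor, swc_path)
    stats = morpho.branch_statistics(arbor)
    profile = morpho.sholl(arbor, radius_step=float(p.get("sholl_step", 10.0)))
    metrics_path = out / "morphometry_metrics.csv"
    sholl_path = out / "morphometry_sholl.csv"
    pd.DataFrame(
        [
            {
                "cell_id": "sim_0",
                "total_length_um": morpho.total_length(arbor),
                "truth_total_length_um": truth.total_length,
                "n_branchpoints": stats.n_branch_points,
                "truth_n_branchpoints": truth.n_branch_points,
                "n_terminals": stats.n_terminals,
                "n_segments": len(stats.segment_lengths),
                "hull_area_um2": morpho.arbor_area(arbor),
            }
        ]
    ).to_csv(metrics_path, index=False, float_format="%.9g")
    pd.DataFrame(
        {"radius_um": profile.radii, "intersections": profile.intersections}
    ).to_csv(sholl_path, index=False, float_format="%.9g")
    return [swc_path, metrics_path, sholl_path]
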