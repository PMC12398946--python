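"""Configuration-driven orchestration of the full analysis.

One entry point, :func:`run`, takes a :class:`PipelineConfig` (typically
loaded from a flat YAML file), generates or loads the data, runs each
analysis stage in isolation, writes tabular outputs (CSV) and summaries
(JSON) into the output directory, and finishes with a manifest listing
every output file with its SHA-256 checksum.  A stage failure is recorded
in the manifest and does not corrupt the outputs of other stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import channeling, fluctuation, gate, hydration, synthetic
from .errors import ConfigError
from .geometry import geometry_report
from .structure_io import TrajectoryEnsemble, read_structure, read_trajectory

log = logging.getLogger("putachannel")


@dataclass
class PipelineConfig:
    """Validated description of one pipeline run."""

    mode: str = "synthetic"                   # synthetic | trajectory | structure
    output_dir: str = "putachannel_out"
    seed: int = 0
    # synthetic mode
    n_replicates: int = 21
    n_frames: int = 2000
    time_step: float = 1.0
    # trajectory mode
    topology: Optional[str] = None
    frames: Optional[list] = None             # list of frame-source paths (replicates)
    dialect: str = "multi_model_pdb"
    ligand_resnames: Optional[list] = None
    # structure mode
    structures: Optional[list] = None         # list of coordinate files
    chain: str = "A"
    # analysis parameters
    active_site_radius: float = 10.0
    tunnel_end: float = 30.0
    distal_entrance: float = 32.0
    gate_closed_max: float = 5.0
    gate_semiopen_max: float = 8.0
    persistence_frames: int = 10
    min_protein_distance: float = 5.0
    docking_cutoff: float = 5.0
    histogram_bin_width: float = 0.5
    tunnel_csv: Optional[str] = None
    tunnel_length: float = 30.0
    tunnel_radius: float = 4.0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "trajectory", "structure"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "trajectory" and (self.topology is None or not self.frames):
            raise ConfigError("trajectory mode needs 'topology' and 'frames'")
        if self.mode == "structure" and not self.structures:
            raise ConfigError("structure mode needs 'structures'")
        if self.persistence_frames < 1:
            raise ConfigError("persistence_frames must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def zones(self) -> channeling.ZoneConfig:
        return channeling.ZoneConfig(
            active_site_radius=self.active_site_radius,
            tunnel_end=self.tunnel_end,
            distal_entrance=self.distal_entrance,
        )

    def thresholds(self) -> gate.GateThresholds:
        return gate.GateThresholds(
            closed_max=self.gate_closed_max, semiopen_max=self.gate_semiopen_max
        )

    def tunnel_path(self) -> hydration.TunnelPath:
        if self.tunnel_csv:
            return hydration.TunnelPath.from_csv(self.tunnel_csv, self.tunnel_radius)
        return hydration.TunnelPath.straight(self.tunnel_length, self.tunnel_radius)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_ensemble(config: PipelineConfig) -> TrajectoryEnsemble:
    reps = []
    for frames_path in config.frames or []:
        ens = read_trajectory(
            config.topology,
            frames_path,
            dialect=config.dialect,
            time_step=config.time_step,
            ligand_resnames=config.ligand_resnames,
        )
        reps.extend(ens.replicates)
    return TrajectoryEnsemble(replicates=reps)


def stage_channel(ensemble, config: PipelineConfig, outdir: Path) -> list[Path]:
    zones = config.zones()
    outcomes = channeling.ensemble_outcomes(
        ensemble, zones, config.persistence_frames, config.min_protein_distance
    )
    rows = []
    for r, track in enumerate(outcomes.tracks):
        for f in range(track.n_frames):
            rows.append(
                (r, f, f * track.time_step, track.displacement[f],
                 channeling.ZONES[track.zones[f]])
            )
    tracks_df = pd.DataFrame(
        rows, columns=["replicate", "frame", "time_ns", "displacement_A", "zone"]
    )
    _write_csv(tracks_df, outdir / "ligand_tracks.csv")

    events = [
        {
            "replicate": r,
            "outcome": e.outcome,
            "release_frame": e.release_frame,
            "dissociation_frame": e.dissociation_frame,
        }
        for r, e in enumerate(outcomes.events)
    ]
    _write_json({"events": events, "counts": outcomes.counts()}, outdir / "events.json")

    edges, counts = channeling.displacement_histogram(
        outcomes.tracks, config.histogram_bin_width
    )
    _write_csv(
        pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}),
        outdir / "displacement_histogram.csv",
    )

    contact_rows = []
    for r, traj in enumerate(ensemble):
        for resnum, freq in sorted(channeling.contact_residues(traj, cutoff=5.0).items()):
            contact_rows.append((r, resnum, freq))
    _write_csv(
        pd.DataFrame(contact_rows, columns=["replicate", "residue_number", "contact_fraction"]),
        outdir / "contact_residues.csv",
    )
    config._outcomes = outcomes  # cache for later stages in the same run
    return [
        outdir / "ligand_tracks.csv",
        outdir / "events.json",
        outdir / "displacement_histogram.csv",
        outdir / "contact_residues.csv",
    ]


def stage_gate(ensemble, config: PipelineConfig, outdir: Path) -> list[Path]:
    thresholds = config.thresholds()
    series = [gate.gate_series(t, thresholds=thresholds) for t in ensemble]
    rows = []
    for r, s in enumerate(series):
        for f in range(s.n_frames):
            rows.append((r, f, s.distances[f], gate.STATE_NAMES[s.states[f]]))
    _write_csv(
        pd.DataFrame(rows, columns=["replicate", "frame", "distance_A", "state"]),
        outdir / "gate_series.csv",
    )

    outcomes = getattr(config, "_outcomes", None)
    hist_rows = []
    conditions = [None] if outcomes is None else [None, "remained", "released"]
    for cond in conditions:
        try:
            edges, counts = gate.gate_distance_histogram(
                series,
                events=None if outcomes is None else outcomes.events,
                condition=cond,
                bin_width=config.histogram_bin_width,
            )
        except Exception:
            continue
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append((cond or "all", lo, hi, c))
    _write_csv(
        pd.DataFrame(hist_rows, columns=["condition", "bin_lo", "bin_hi", "count"]),
        outdir / "gate_histograms.csv",
    )

    outputs = [outdir / "gate_series.csv", outdir / "gate_histograms.csv"]
    if outcomes is not None:
        report = gate.necessity_sufficiency_report(outcomes.events, series)
        _write_json(
            {
                "n_replicates": report.n_replicates,
                "n_released": report.n_released,
                "necessity_fraction": report.necessity_fraction,
                "open_without_release_fraction": report.open_without_release_fraction,
                "closed_after_release_count": report.closed_after_release_count,
            },
            outdir / "gate_necessity.json",
        )
        outputs.append(outdir / "gate_necessity.json")
    return outputs


def stage_hydration(ensemble, config: PipelineConfig, outdir: Path) -> list[Path]:
    path = config.tunnel_path()
    summary = hydration.water_series_summary(ensemble, path)
    rows = []
    for r, counts in enumerate(summary.per_replicate_counts):
        for f, c in enumerate(counts):
            rows.append((r, f, c))
    _write_csv(
        pd.DataFrame(rows, columns=["replicate", "frame", "tunnel_waters"]),
        outdir / "water_counts.csv",
    )
    _write_json(
        {
            "mean": summary.mean,
            "p01": summary.p01,
            "p99": summary.p99,
            "min": summary.minimum,
            "max": summary.maximum,
        },
        outdir / "water_summary.json",
    )

    interval_rows = []
    for r, traj in enumerate(ensemble):
        try:
            intervals = hydration.docking_intervals(traj, cutoff=config.docking_cutoff)
        except Exception:
            continue
        for iv in intervals:
            interval_rows.append((r, iv.start_frame, iv.end_frame, iv.duration_ns))
    _write_csv(
        pd.DataFrame(
            interval_rows, columns=["replicate", "start_frame", "end_frame", "duration_ns"]
        ),
        outdir / "docking_intervals.csv",
    )
    return [
        outdir / "water_counts.csv",
        outdir / "water_summary.json",
        outdir / "docking_intervals.csv",
    ]


def stage_rmsf(ensemble, config: PipelineConfig, outdir: Path) -> list[Path]:
    profile = fluctuation.ensemble_rmsf(ensemble)
    _write_csv(
        pd.DataFrame(
            {"residue_number": profile.residue_numbers, "rmsf_A": profile.rmsf}
        ),
        outdir / "rmsf.csv",
    )
    return [outdir / "rmsf.csv"]


def stage_geometry(config: PipelineConfig, outdir: Path) -> list[Path]:
    reports = {}
    for path in config.structures or []:
        model = read_structure(path)
        reports[Path(path).name] = geometry_report(
            model, config.chain, ligand_resnames=config.ligand_resnames or ()
        )
    _write_json(reports, outdir / "geometry_report.json")
    return [outdir / "geometry_report.json"]


def run(config: PipelineConfig) -> dict:
    """Run all stages appropriate to the configured mode.

    Returns the manifest (also written to manifest.json).  Raises
    :class:`ConfigError` for invalid configuration; per-stage failures are
    captured in the manifest instead of aborting the run.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mode": config.mode, "seed": config.seed, "stages": {}, "outputs": {}}
    outputs: list[Path] = []

    ensemble = None
    truth = None
    if config.mode == "synthetic":
        syn = synthetic.SyntheticConfig(
            n_replicates=config.n_replicates,
            n_frames=config.n_frames,
            time_step=config.time_step,
            seed=config.seed,
        )
        log.info("simulate: %d replicates x %d frames, seed %d",
                 syn.n_replicates, syn.n_frames, syn.seed)
        ensemble, truth = synthetic.generate_ensemble(syn)
        truth.to_json(outdir / "ground_truth.json")
        outputs.append(outdir / "ground_truth.json")
        manifest["stages"]["simulate"] = "ok"
    elif config.mode == "trajectory":
        ensemble = load_ensemble(config)
        manifest["stages"]["load"] = "ok"

    if ensemble is not None:
        for name, fn in (
            ("channel", stage_channel),
            ("gate", stage_gate),
            ("hydration", stage_hydration),
            ("rmsf", stage_rmsf),
        ):
            try:
                outputs.extend(fn(ensemble, config, outdir))
                manifest["stages"][name] = "ok"
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                manifest["stages"][name] = f"failed: {type(exc).__name__}: {exc}"

    if config.mode == "structure":
        try:
            outputs.extend(stage_geometry(config, outdir))
            manifest["stages"]["geometry"] = "ok"
        except Exception as exc:
            manifest["stages"]["geometry"] = f"failed: {type(exc).__name__}: {exc}"

    for p in outputs:
        manifest["outputs"][p.name] = _sha256(p)
    manifest["complete"] = all(v == "ok" for v in manifest["stages"].values())
    _write_json(manifest, outdir / "manifest.json")
    return manifest
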