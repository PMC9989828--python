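"""Reproducible multi-stage runs: config, file I/O, manifests.

Stages (``simulate``, ``track``, ``kinetics``, ``geometry``, ``report``)
read and write plain files in an output directory and record a manifest
(parameters, seed, content hashes, package versions), so a rerun with the
same config is verifiably identical for deterministic stages. CSV outputs
carry a schema-version comment line; readers skip ``#`` comments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import LinkConfig, SegmentationConfig, detect_contacts, link_tracks, segment_stack
from .geometry import MonolayerTrace, compute_distance_map, heatmap, interpolate_surface
from .kinetics import detect_events, fit_events, summarize_cohort
from .stack import read_timelapse, write_timelapse
from .synthetic import GroundTruthEvent, SimulationConfig, StaticLD, generate_timelapse

__all__ = ["RunConfig", "run_pipeline", "COMMANDS"]

COMMANDS = ("simulate", "track", "kinetics", "geometry", "report")
log = logging.getLogger("ldtransfer")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``simulate`` holds :class:`~ldtransfer.synthetic.SimulationConfig`
    fields (events/static LDs as mappings); ``segmentation`` and
    ``linking`` the corresponding stage configs. Paths are resolved
    relative to the config file when loaded from YAML.
    """

    output_dir: Path = Path("ldtransfer_out")
    seed: int = 0
    log_level: str = "INFO"
    stack_path: Path | None = None
    trace_csv: Path | None = None
    surface_pairs: list[tuple[str, str]] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    linking: dict = field(default_factory=dict)
    filter_threshold: float = 0.4
    grid_spacing_nm: float = 2.0
    max_distance_nm: float = 50.0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.stack_path is not None:
            self.stack_path = Path(self.stack_path)
        if self.trace_csv is not None:
            self.trace_csv = Path(self.trace_csv)
        if self.filter_threshold <= 0:
            raise ValueError("filter_threshold must be positive")
        if self.grid_spacing_nm <= 0:
            raise ValueError("grid_spacing_nm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve inputs relative to the config file
        for attr in ("stack_path", "trace_csv"):
            p = getattr(cfg, attr)
            if p is not None and not p.is_absolute():
                setattr(cfg, attr, (path.parent / p).resolve())
        for attr in ("stack_path", "trace_csv"):
            p = getattr(cfg, attr)
            if p is not None and not p.exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        return cfg

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulate)
        events = [GroundTruthEvent(**e) for e in sim.pop("events", [])]
        statics = [StaticLD(**s) for s in sim.pop("static_lds", [])]
        sim.setdefault("rng_seed", self.seed)
        sim["image_shape"] = tuple(sim["image_shape"])
        return SimulationConfig(events=events, static_lds=statics, **sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ldtransfer {schema} schema v1\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _write_manifest(out: Path, command: str, config: RunConfig, files: list[Path]) -> Path:
    manifest = {
        "command": command,
        "ldtransfer_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "parameters": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_pipeline(config: RunConfig, command: str) -> list[Path]:
    """Run one stage; returns the files written (manifest last).

    On error, files written by the failing stage are removed so no partial
    stage output survives.
    """
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; one of {COMMANDS}")
    logging.basicConfig(level=config.log_level)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = {
            "simulate": _stage_simulate,
            "track": _stage_track,
            "kinetics": _stage_kinetics,
            "geometry": _stage_geometry,
            "report": _stage_report,
        }[command]
        written = stage(config, out)
        written.append(_write_manifest(out, command, config, written))
        return written
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    sim = config.simulation_config()
    stack, truth = generate_timelapse(sim)
    stack_path = out / "stack.tif"
    write_timelapse(stack, stack_path)
    truth_path = out / "truth.csv"
    _write_csv(truth, truth_path, "truth")
    log.info("simulated %d frames, %d truth rows", stack.n_frames, len(truth))
    return [stack_path, stack_path.with_suffix(".tif.json"), truth_path]


def _stage_track(config: RunConfig, out: Path) -> list[Path]:
    stack_path = config.stack_path or out / "stack.tif"
    stack = read_timelapse(stack_path)
    seg = SegmentationConfig(**config.segmentation)
    link = LinkConfig(**config.linking)
    detections, labels = segment_stack(stack, seg)
    tracks, summary = link_tracks(detections, link)
    contacts = detect_contacts(tracks, labels)
    files = []
    for df, name in [
        (detections, "detections"), (tracks, "tracks"),
        (summary, "track_summary"), (contacts, "contacts"),
    ]:
        p = out / f"{name}.csv"
        _write_csv(df, p, name)
        files.append(p)
    log.info("%d detections, %d tracks", len(detections), len(summary))
    return files


def _stage_kinetics(config: RunConfig, out: Path) -> list[Path]:
    tracks = _read_csv(out / "tracks.csv")
    summary = _read_csv(out / "track_summary.csv")
    contacts = _read_csv(out / "contacts.csv")
    events = detect_events(tracks, summary, contacts)
    table = fit_events(events)
    files = []
    p = out / "events.csv"
    _write_csv(table, p, "events")
    files.append(p)
    cohort = summarize_cohort(table[table.get("passes_filter", pd.Series(dtype=bool)) == True])  # noqa: E712
    pc = out / "cohort_summary.csv"
    _write_csv(cohort, pc, "cohort_summary")
    files.append(pc)
    diag = out / "fit_diagnostics.json"
    diag.write_text(json.dumps(
        {"n_events": len(events),
         "n_fit": int(len(table)),
         "n_pass_filter": int(table["passes_filter"].sum()) if len(table) else 0},
        indent=1))
    files.append(diag)
    log.info("%d events detected, %d fitted", len(events), len(table))
    return files


def _stage_geometry(config: RunConfig, out: Path) -> list[Path]:
    if config.trace_csv is None:
        raise ValueError("geometry stage needs trace_csv")
    df = _read_csv(config.trace_csv)
    pairs = config.surface_pairs or [tuple(sorted(df["surface_id"].unique())[:2])]
    stats_rows, dist_rows, files = [], [], []
    for ia, ib in pairs:
        sa = interpolate_surface(MonolayerTrace.from_dataframe(df, ia), config.grid_spacing_nm)
        sb = interpolate_surface(MonolayerTrace.from_dataframe(df, ib), config.grid_spacing_nm)
        dm = compute_distance_map(
            sa, sb, max_distance=config.max_distance_nm, interface_id=f"{ia}-{ib}"
        )
        stats_rows.append(dm.stats)
        gz, gs = np.nonzero(np.isfinite(dm.distances))
        dist_rows.append(pd.DataFrame({
            "interface_id": f"{ia}-{ib}", "grid_z": gz, "grid_s": gs,
            "distance_nm": dm.distances[gz, gs],
        }))
        png = out / f"heatmap_{ia}-{ib}.png"
        heatmap(dm, png)
        files.append(png)
    ps = out / "interface_stats.csv"
    _write_csv(pd.DataFrame(stats_rows), ps, "interface_stats")
    pdist = out / "distances.csv"
    _write_csv(pd.concat(dist_rows, ignore_index=True), pdist, "distances")
    return [ps, pdist] + files


def _stage_report(config: RunConfig, out: Path) -> list[Path]:
    events_path = out / "events.csv"
    events = _read_csv(events_path) if events_path.exists() else pd.DataFrame()
    if len(events):
        kept = events[events["passes_filter"]]
        cohort = summarize_cohort(kept)
    else:
        cohort = pd.DataFrame()
    p = out / "cohort_summary.csv"
    _write_csv(cohort, p, "cohort_summary")
    return [p]
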