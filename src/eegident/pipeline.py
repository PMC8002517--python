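"""End-to-end orchestration: one run configuration drives cohort input,
the (filter order x band) sweep, the openness simulation, per-cell
evaluation and the final self-relative report, leaving replayable
intermediates (feature CSVs, accuracy CSVs, simulation JSON) behind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import (
    ConfigError,
    PipelineConfig,
    SweepSpec,
    expand_sweep,
    load_sweep,
)
from .evaluation import run_openness, write_results
from .features import build_feature_space
from .openness import OpennessConfig, simulate_openness
from .metrics import grid_report
from .preprocessing import load_edf
from .synthetic import SyntheticCohortSpec, generate_cohort, read_cohort

__all__ = ["RunConfig", "RunManifest", "load_run_config", "run_all"]

_TOP_KEYS = {"seed", "pipeline", "sweep", "openness", "cohort", "input_dir"}


@dataclass
class RunConfig:
    """A full run: pipeline base, sweep grid, openness plan and input."""

    seed: int
    pipeline: PipelineConfig
    sweep: SweepSpec
    openness: dict
    cohort: SyntheticCohortSpec | None = None
    input_dir: Path | None = None


@dataclass
class RunManifest:
    """What a run produced, sufficient to replay any stage."""

    seed: int
    config: dict
    version: str
    simulation_path: str
    feature_paths: list[str]
    accuracy_paths: list[str]
    report_dir: str

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"run config not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"run config {path} does not contain a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for key in ("pipeline", "sweep", "openness"):
        if key not in data:
            raise ConfigError(f"run config is missing the '{key}' block")
    if ("cohort" in data) == ("input_dir" in data):
        raise ConfigError("provide exactly one of 'cohort' (synthetic) or 'input_dir'")
    cohort = (
        SyntheticCohortSpec.from_dict(data["cohort"]) if "cohort" in data else None
    )
    input_dir = Path(data["input_dir"]) if "input_dir" in data else None
    return RunConfig(
        seed=int(data.get("seed", 0)),
        pipeline=PipelineConfig.from_dict(data["pipeline"]),
        sweep=load_sweep(data["sweep"]),
        openness=dict(data["openness"]),
        cohort=cohort,
        input_dir=input_dir,
    )


def _load_input_cohort(input_dir: Path, channels) -> list:
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    edf_files = sorted(input_dir.glob("*.edf"))
    if edf_files:
        return [
            load_edf(p, subject_label=i + 1, channels=channels)
            for i, p in enumerate(edf_files)
        ]
    return read_cohort(input_dir)


def run_all(config_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Execute the full self-relative evaluation described by one config.

    Deterministic given the config's seed: sub-seeds for cohort
    generation, enrollment simulation and evaluation are spawned from the
    master seed, and a rerun writes byte-identical outputs.
    """
    cfg = load_run_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(cfg.seed)
    cohort_seed, openness_seed, eval_seed = (
        int(s) for s in master.generate_state(3) % (2**31)
    )

    if cfg.cohort is not None:
        spec = SyntheticCohortSpec.from_dict({**cfg.cohort.to_dict(), "seed": cohort_seed})
        recordings = generate_cohort(spec).recordings
    else:
        recordings = _load_input_cohort(cfg.input_dir, cfg.pipeline.channel_set)

    open_cfg = OpennessConfig(
        n_subjects=len(recordings), seed=openness_seed, **cfg.openness
    )
    sim = simulate_openness(open_cfg)
    sim_path = out_dir / "openness_simulation.json"
    sim.to_json(sim_path)

    feature_paths: list[str] = []
    accuracy_paths: list[str] = []
    results = {}
    for cell in expand_sweep(cfg.pipeline, cfg.sweep):
        space = build_feature_space(recordings, cell)
        fpath = out_dir / f"features_{space.config_id}.csv"
        space.to_csv(fpath)
        feature_paths.append(str(fpath))
        oa = run_openness(space, sim, cell.classifier, cell.kfold, seed=eval_seed)
        apath = write_results(oa, sim, space.config_id, out_dir)
        accuracy_paths.append(str(apath))
        results[space.config_id] = oa

    report = grid_report(results, cfg.sweep)
    report_dir = out_dir / "report"
    report.write(report_dir)

    manifest = RunManifest(
        seed=cfg.seed,
        config={
            "pipeline": cfg.pipeline.to_dict(),
            "sweep": {
                "orders": list(cfg.sweep.orders),
                "bands": [list(b) for b in cfg.sweep.bands],
            },
            "openness": cfg.openness,
            "cohort": cfg.cohort.to_dict() if cfg.cohort else None,
            "input_dir": str(cfg.input_dir) if cfg.input_dir else None,
        },
        version=__version__,
        simulation_path=str(sim_path),
        feature_paths=feature_paths,
        accuracy_paths=accuracy_paths,
        report_dir=str(report_dir),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
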