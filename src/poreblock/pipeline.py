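"""Configuration-driven orchestration over one or more conditions.

A run configuration lists conditions (each either a synthetic generator
configuration or real topology/trajectory paths), the analysis cylinder and
grid, window fractions and permeation thresholds.  ``run_pipeline`` computes
hydration, cavity volume and water density per condition, windowed summaries,
the pairwise Cohen's d table, and permeation events, writing CSV/JSON
atomically under the output directory together with a manifest (config hash,
seed, version).  Identical config + seed reruns produce byte-identical
outputs: per-condition seeds are derived from the global seed by the counter
scheme ``child = (seed * 100003 + index) mod 2^31``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import CylinderSpec, FrameSeries, GridSpec, cavity_volume, count_pore_waters, water_density
from .model import SelectionConfig, Trajectory, build_selections, load_topology, load_trajectory
from .permeation import count_permeation_events, ion_axial_traces, traces_to_csv
from .stats import cohens_d, window_summary
from .synthetic import SyntheticPoreConfig, generate_pore_trajectory

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration failed schema validation."""


@dataclass
class ConditionSpec:
    """One condition: a label plus either a synthetic config or real input paths."""

    label: str
    synthetic: SyntheticPoreConfig | None = None
    topology_path: str | None = None
    trajectory_paths: list[str] = field(default_factory=list)

    def validate(self) -> None:
        has_synth = self.synthetic is not None
        has_real = self.topology_path is not None or bool(self.trajectory_paths)
        if has_synth == has_real:
            raise ConfigError(
                f"condition {self.label!r}: provide either a synthetic config or "
                "real topology/trajectory paths, not both/neither"
            )


@dataclass
class RunConfig:
    conditions: list[ConditionSpec]
    cylinder: CylinderSpec = field(default_factory=CylinderSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    window_fraction: float = 0.25  # final fraction of frames summarised
    z_top: float = 20.0
    z_bottom: float = -20.0
    radial_cutoff: float = 10.0
    out_dir: str = "poreblock_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        labels = [c.label for c in self.conditions]
        problems = []
        if not self.conditions:
            problems.append("conditions: empty")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            problems.append(f"conditions: duplicate labels {dupes}")
        if not 0 < self.window_fraction <= 1:
            problems.append(f"window_fraction: {self.window_fraction} outside (0, 1]")
        if self.z_top <= self.z_bottom:
            problems.append(f"z_top ({self.z_top}) must exceed z_bottom ({self.z_bottom})")
        if problems:
            raise ConfigError("invalid run configuration: " + "; ".join(problems))
        for c in self.conditions:
            c.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        conditions = []
        for item in data.get("conditions", []):
            synth = item.get("synthetic")
            conditions.append(
                ConditionSpec(
                    label=item["label"],
                    synthetic=SyntheticPoreConfig(**synth) if synth is not None else None,
                    topology_path=item.get("topology_path"),
                    trajectory_paths=list(item.get("trajectory_paths", [])),
                )
            )
        kwargs = {k: v for k, v in data.items() if k not in {"conditions", "cylinder", "grid"}}
        if "cylinder" in data:
            kwargs["cylinder"] = CylinderSpec(**data["cylinder"])
        if "grid" in data:
            kwargs["grid"] = GridSpec(**data["grid"])
        return cls(conditions=conditions, **kwargs)

    def to_canonical_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return clean(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class ConditionReport:
    label: str
    files: dict[str, str]
    summaries: dict[str, object]
    n_events: int | None


def condition_seed(seed: int, index: int) -> int:
    """Deterministic per-condition seed stream."""
    return (seed * 100003 + index) % (2**31)


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def run_pipeline(config: RunConfig) -> dict[str, ConditionReport]:
    """Run every analysis stage over every condition and write outputs.

    Per-condition failures are logged and marked in the manifest; remaining
    conditions proceed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    logging.getLogger().addHandler(handler)

    window = (1.0 - config.window_fraction, 1.0)
    reports: dict[str, ConditionReport] = {}
    failures: dict[str, str] = {}
    hydration_summaries: dict[str, object] = {}

    try:
        for idx, cond in enumerate(config.conditions):
            try:
                reports[cond.label] = _run_condition(
                    cond, idx, config, out, window, hydration_summaries
                )
            except Exception as exc:  # noqa: BLE001 - isolate per-condition failures
                logger.error("condition %s failed: %s", cond.label, exc)
                failures[cond.label] = str(exc)

        # pairwise effect sizes on hydration window summaries
        rows = []
        for (la, sa), (lb, sb) in combinations(sorted(hydration_summaries.items()), 2):
            try:
                es = cohens_d(sa, sb)
                rows.append((la, lb, es.d, es.sd_pooled, es.label))
            except Exception as exc:  # noqa: BLE001
                rows.append((la, lb, float("nan"), float("nan"), f"undefined ({exc})"))
        if rows:
            df = pd.DataFrame(rows, columns=["condition_a", "condition_b", "d", "sd_pooled", "label"])
            _atomic_write(out / "effect_sizes.csv", lambda p: df.to_csv(p, index=False, float_format="%.6f"))

        manifest = {
            "config": config.to_canonical_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "conditions_completed": sorted(reports),
            "conditions_failed": failures,
        }
        _atomic_write(
            out / "manifest.json",
            lambda p: p.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n"),
        )
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()
    return reports


def _run_condition(
    cond: ConditionSpec,
    idx: int,
    config: RunConfig,
    out: Path,
    window: tuple[float, float],
    hydration_summaries: dict,
) -> ConditionReport:
    if cond.synthetic is not None:
        synth = dataclasses.replace(cond.synthetic, seed=condition_seed(config.seed, idx))
        topology, traj, _ = generate_pore_trajectory(synth)
        sel = build_selections(topology)
    else:
        sel_config = SelectionConfig()
        topology = load_topology(cond.topology_path, sel_config)
        traj = load_trajectory(topology, cond.trajectory_paths)
        sel = build_selections(topology, sel_config)

    files: dict[str, str] = {}
    counts = count_pore_waters(traj, sel, config.cylinder)
    volumes = cavity_volume(traj, sel, config.cylinder, config.grid)
    density = water_density(counts, volumes)
    for series, tag in ((counts, "hydration"), (volumes, "volume"), (density, "density")):
        path = out / f"{cond.label}_{tag}.csv"
        _atomic_write(path, series.to_csv)
        files[tag] = path.name

    summaries = {}
    for series, tag in ((counts, "hydration"), (volumes, "volume"), (density, "density")):
        summaries[tag] = window_summary(series, window)
    hydration_summaries[cond.label] = summaries["hydration"]
    summary_df = pd.DataFrame(
        [
            (tag, s.n_frames_used, s.mean, s.sd)
            for tag, s in summaries.items()
        ],
        columns=["metric", "n_frames_used", "mean", "sd"],
    )
    summary_path = out / f"{cond.label}_window_summary.csv"
    _atomic_write(summary_path, lambda p: summary_df.to_csv(p, index=False, float_format="%.6f"))
    files["window_summary"] = summary_path.name

    n_events: int | None = None
    traces = ion_axial_traces(traj, sel, config.cylinder)
    if traces:
        result = count_permeation_events(
            traces, z_top=config.z_top, z_bottom=config.z_bottom, radial_cutoff=config.radial_cutoff
        )
        n_events = result.n_events
        events_path = out / f"{cond.label}_permeation.json"
        _atomic_write(events_path, result.to_json)
        traces_path = out / f"{cond.label}_ion_traces.csv"
        _atomic_write(traces_path, lambda p: traces_to_csv(traces, p))
        files["permeation"] = events_path.name
        files["ion_traces"] = traces_path.name

    return ConditionReport(label=cond.label, files=files, summaries=summaries, n_events=n_events)


def default_condition_grid(
    n_frames: int = 500,
    field_strength: float = 10.0,
    waters_by_copies: dict[int, int] | None = None,
) -> list[ConditionSpec]:
    """The standard 0/1/2/4-ligand-copy synthetic grid.

    Inside-water occupancies default to the copy-number ladder 43/38/17/12
    (the mean pore occupancies of the corresponding simulated conditions) with
    a per-frame occupancy fluctuation of sd 4 waters.
    """
    waters = waters_by_copies or {0: 43, 1: 38, 2: 17, 4: 12}
    return [
        ConditionSpec(
            label=f"ligx{copies}",
            synthetic=SyntheticPoreConfig(
                n_frames=n_frames,
                n_ligand_copies=copies,
                n_waters_inside=n_inside,
                water_count_sd=4.0,
                field_strength=field_strength,
            ),
        )
        for copies, n_inside in sorted(waters.items())
    ]
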