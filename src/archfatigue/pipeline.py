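"""End-to-end pipeline: generate -> segment -> metrics -> fit -> stats.

Every stage reads and writes CSV so externally measured data can enter at the
trace or cycle-table level.  All tabular outputs carry a comment header with
the master seed and a hash of the run configuration; a JSON run manifest
records inputs, outputs and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fatigue import DEFAULT_ORDERS, fit_specimens
from .metrics import compute_deltas, cycle_metrics
from .segmentation import DEFAULT_WB_THRESHOLD_N, checkpoint_series, default_checkpoints, segment_cycles
from .stats import cohort_stats
from .synthgen import (
    GeneratorParams,
    default_group_params,
    params_from_yaml,
    params_to_yaml,
    read_trace,
    simulate_cohort,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("generate", "segment", "metrics", "fit", "stats")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending specimen."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "archfatigue_run"
    #: directory with externally supplied traces + manifest.csv (skips generate)
    input_dir: str | None = None
    n_per_group: int = 6
    master_seed: int = 0
    total_cycles: int = 10_000
    checkpoints: tuple[int, ...] | None = None
    orders: tuple[int, ...] = DEFAULT_ORDERS
    alpha: float = 0.05
    ci_method: str = "t"
    #: "cycles" fits every recorded cycle; "checkpoints" fits the grid only
    fit_grid: str = "cycles"
    wb_threshold_n: float = DEFAULT_WB_THRESHOLD_N
    stages: tuple[str, ...] = STAGES
    generator_config: str | None = None  # YAML with per-group GeneratorParams

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.checkpoints is None:
            self.checkpoints = default_checkpoints(self.total_cycles, max(1, self.total_cycles // 10))
        self.checkpoints = tuple(int(c) for c in self.checkpoints)
        self.orders = tuple(int(p) for p in self.orders)

    def group_params(self) -> dict[str, GeneratorParams]:
        if self.generator_config:
            return params_from_yaml(self.generator_config)
        return default_group_params(total_cycles=self.total_cycles)

    def config_hash(self) -> str:
        # identifies the scientific configuration; storage locations excluded
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("outdir", "input_dir")
        }
        return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# archfatigue {__version__} seed={cfg.master_seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _manifest(cfg: RunConfig, base: Path) -> pd.DataFrame:
    src = Path(cfg.input_dir) if cfg.input_dir else base / "traces"
    manifest_path = src / "manifest.csv"
    if not manifest_path.exists():
        raise PipelineError(f"stage segment: manifest not found at {manifest_path}")
    return pd.read_csv(manifest_path, comment="#")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Returns a dict with the in-memory stage outputs (cycle tables, metric
    tables, fit report, stats report) and the output paths.
    """
    cfg = config
    base = Path(cfg.outdir)
    base.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    results: dict = {"outdir": str(base)}
    outputs: list[str] = []

    def record(path: Path) -> None:
        outputs.append(str(path.relative_to(base)))

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if "generate" in cfg.stages:
            traces_dir = base / "traces"
            group_params = cfg.group_params()
            params_to_yaml(group_params, base / "generator_params.yaml")
            record(base / "generator_params.yaml")
            traces, manifest = simulate_cohort(
                group_params, cfg.n_per_group, cfg.master_seed, outdir=traces_dir
            )
            for t in traces:
                record(traces_dir / f"{t.specimen_id}.csv")
            record(traces_dir / "manifest.csv")
            log.info("generate: %d traces written to %s", len(traces), traces_dir)

        if "segment" in cfg.stages:
            manifest = _manifest(cfg, base)
            src = Path(cfg.input_dir) if cfg.input_dir else base / "traces"
            cycles_dir = base / "cycles"
            for row in manifest.itertuples():
                try:
                    trace = read_trace(
                        src / f"{row.specimen_id}.csv",
                        specimen_id=row.specimen_id,
                        group=row.group,
                        foot_length_mm=row.foot_length_mm,
                        peak_load_n=row.peak_load_N,
                    )
                    cycles = segment_cycles(trace, cfg.wb_threshold_n)
                except Exception as exc:
                    raise PipelineError(
                        f"stage segment failed for specimen {row.specimen_id}: {exc}"
                    ) from exc
                _write_csv(cycles, cycles_dir / f"{row.specimen_id}.csv", cfg)
                record(cycles_dir / f"{row.specimen_id}.csv")
                log.info("segment: %s -> %d cycles", row.specimen_id, len(cycles))

        if "metrics" in cfg.stages:
            manifest = _manifest(cfg, base)
            metrics_dir = base / "metrics"
            for row in manifest.itertuples():
                try:
                    cycles = _read_csv(base / "cycles" / f"{row.specimen_id}.csv")
                    m = cycle_metrics(cycles, row.foot_length_mm)
                except Exception as exc:
                    raise PipelineError(
                        f"stage metrics failed for specimen {row.specimen_id}: {exc}"
                    ) from exc
                _write_csv(m, metrics_dir / f"{row.specimen_id}.csv", cfg)
                record(metrics_dir / f"{row.specimen_id}.csv")

        metrics_by_specimen: dict[str, pd.DataFrame] = {}
        if "fit" in cfg.stages or "stats" in cfg.stages:
            manifest = _manifest(cfg, base)
            for row in manifest.itertuples():
                metrics_by_specimen[row.specimen_id] = _read_csv(
                    base / "metrics" / f"{row.specimen_id}.csv"
                )

        if "fit" in cfg.stages:
            try:
                fits, report = fit_specimens(
                    metrics_by_specimen, cfg.checkpoints, cfg.orders, fit_grid=cfg.fit_grid
                )
            except Exception as exc:
                raise PipelineError(f"stage fit failed: {exc}") from exc
            _write_csv(report, base / "fits" / "fit_report.csv", cfg)
            record(base / "fits" / "fit_report.csv")
            group_of = dict(zip(manifest["specimen_id"], manifest["group"]))
            inflections = pd.DataFrame(
                [
                    {
                        "specimen_id": sid,
                        "group": group_of.get(sid, ""),
                        "selected_order": fit.selected_order,
                        "r2": fit.selected.r2,
                        "inflection_cycle": fit.inflection_cycle,
                    }
                    for sid, fit in fits.items()
                ]
            )
            _write_csv(inflections, base / "fits" / "inflections.csv", cfg)
            record(base / "fits" / "inflections.csv")
            results["fits"] = fits
            results["fit_report"] = report
            results["inflections"] = inflections

        if "stats" in cfg.stages:
            manifest = _manifest(cfg, base)
            group_of = dict(zip(manifest["specimen_id"], manifest["group"]))
            rows = []
            delta_rows = []
            first_cp, last_cp = min(cfg.checkpoints), max(cfg.checkpoints)
            for sid, m in metrics_by_specimen.items():
                try:
                    cp = checkpoint_series(m, cfg.checkpoints)
                except Exception as exc:
                    raise PipelineError(f"stage stats failed for specimen {sid}: {exc}") from exc
                cp = cp.assign(specimen_id=sid, group=group_of.get(sid, ""))
                rows.append(cp)
                deltas = compute_deltas(m, first_cp, last_cp, specimen_id=sid)
                delta_rows.append({"specimen_id": sid, "group": group_of.get(sid, ""), **deltas})
            checkpoint_table = pd.concat(rows, ignore_index=True)
            deltas = pd.DataFrame(delta_rows)
            inflections = results.get("inflections")
            if inflections is None:
                inf_path = base / "fits" / "inflections.csv"
                inflections = _read_csv(inf_path) if inf_path.exists() else None
            report = cohort_stats(
                checkpoint_table,
                deltas=deltas,
                inflections=inflections,
                alpha=cfg.alpha,
                ci_method=cfg.ci_method,
                first_cycle=first_cp,
            )
            stats_dir = base / "stats"
            _write_csv(checkpoint_table, stats_dir / "checkpoint_table.csv", cfg)
            _write_csv(deltas, stats_dir / "deltas.csv", cfg)
            _write_csv(report["summaries"], stats_dir / "group_summary.csv", cfg)
            _write_csv(report["tests"], stats_dir / "tests.csv", cfg)
            _write_csv(report["normality"], stats_dir / "normality.csv", cfg)
            _write_csv(report["low_arch_onset"], stats_dir / "low_arch_onset.csv", cfg)
            for name in ("checkpoint_table", "deltas", "group_summary", "tests",
                         "normality", "low_arch_onset"):
                record(stats_dir / f"{name}.csv")
            if report["inflection_summary"] is not None:
                _write_csv(report["inflection_summary"], stats_dir / "inflection_summary.csv", cfg)
                record(stats_dir / "inflection_summary.csv")
            (stats_dir / "report.txt").write_text(_text_report(cfg, report))
            record(stats_dir / "report.txt")
            results["stats"] = report
            results["checkpoint_table"] = checkpoint_table
            results["deltas"] = deltas

        caught = [str(w.message) for w in wlist]

    run_manifest = {
        "version": __version__,
        "seed": cfg.master_seed,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "stages": list(cfg.stages),
        "outputs": outputs,
        "warnings": caught,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (base / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, default=str))
    results["run_manifest"] = run_manifest
    return results


def _text_report(cfg: RunConfig, report: dict) -> str:
    lines = [
        f"archfatigue {__version__} statistical report",
        f"seed={cfg.master_seed} config={cfg.config_hash()} "
        f"alpha={cfg.alpha} ci_method={cfg.ci_method}",
        "",
        "Low-arch onset (earliest checkpoint with CI upper bound < 0.21):",
    ]
    for row in report["low_arch_onset"].itertuples():
        onset = "never" if pd.isna(row.low_arch_onset_cycle) else f"cycle {int(row.low_arch_onset_cycle)}"
        lines.append(f"  {row.group}: {onset}")
    if report["inflection_summary"] is not None:
        lines += ["", "Inflection cycles (stage II -> III transition), per group:"]
        for row in report["inflection_summary"].itertuples():
            lines.append(
                f"  {row.group}: mean {row.mean:.0f}, SD {row.sd:.1f}, n={row.n}"
            )
    lines += ["", "Hypothesis tests:"]
    for row in report["tests"].itertuples():
        lines.append(
            f"  {row.test} [{row.metric}] {row.comparison}: "
            f"stat={row.statistic:.4g}, p={row.p_adjusted:.4g}"
            f"{' *' if row.significant else ''}"
        )
    return "\n".join(lines) + "\n"
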