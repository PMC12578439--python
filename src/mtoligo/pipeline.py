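"""End-to-end driver: YAML config in, tidy tables + report out.

Stages run in a fixed order — ingest or simulate, resample, optional
cleaning (dedup / score filter / polarity harmonization), pairs, classes,
chains, histograms, densities, angular extents — with per-stage particle
counts logged and echoed into the report.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import seeding
from .coords_io import read_filament_trace, read_particle_table
from .errors import ConfigurationError
from .filament import resample_path
from .model import AnalysisParams, OligomerChainModel
from .synth import make_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (one YAML document)."""

    rng_seed: int = 0
    out_dir: str = "mtoligo_out"
    simulate: dict | None = None  # preset, n_filaments, filament_length, overrides
    inputs: dict | None = None  # particles, dialect, voxel_size, traces, spacing, polarities
    clean: dict = field(default_factory=dict)  # enabled, min_dist, score_threshold
    analysis: dict = field(default_factory=dict)  # AnalysisParams overrides
    plots: bool = False

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "config must contain exactly one of 'simulate' or 'inputs'"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def analysis_params(self) -> AnalysisParams:
        kw = dict(self.analysis)
        if "dist_window" in kw:
            kw["dist_window"] = tuple(kw["dist_window"])
        if "chain_classes" in kw:
            kw["chain_classes"] = tuple(kw["chain_classes"])
        return AnalysisParams(**kw)


@dataclass
class RunReport:
    """Summary statistics and file manifest of one pipeline run."""

    theta_mode: float | None
    max_copy_number: int | None
    pooled_density: float
    max_angular_extent: float
    n_particles: int
    n_pairs: int
    n_chains: int
    stage_counts: dict
    manifest: dict

    def to_dict(self) -> dict:
        return {
            "theta_mode_deg": self.theta_mode,
            "max_copy_number": self.max_copy_number,
            "pooled_density_per_nm": round(self.pooled_density, 9),
            "max_angular_extent_deg": (
                None if self.max_angular_extent is None
                else round(self.max_angular_extent, 6)
            ),
            "n_particles": self.n_particles,
            "n_pairs": self.n_pairs,
            "n_chains": self.n_chains,
            "stage_counts": self.stage_counts,
            "files": {k: str(v) for k, v in self.manifest.items()},
        }


def _ingest(config: RunConfig):
    """Returns (table, paths, stage_counts)."""
    counts = {}
    if config.simulate is not None:
        sim = dict(config.simulate)
        bundle = make_fixture(
            preset=sim.get("preset", "paper-like"),
            n_filaments=int(sim.get("n_filaments", 20)),
            rng_seed=int(sim.get("rng_seed", config.rng_seed)),
            filament_length=float(sim.get("filament_length", 500.0)),
            spec_overrides=sim.get("overrides"),
        )
        counts["simulated"] = len(bundle.table)
        return bundle.table, bundle.paths, counts
    inp = dict(config.inputs)
    table = read_particle_table(
        inp["particles"], inp.get("dialect", "dynamo-table"),
        float(inp.get("voxel_size", 10.0)),
    )
    counts["ingested"] = len(table)
    raw_traces = read_filament_trace(inp["traces"])
    spacing = float(inp.get("spacing", 7.0))
    polarities = {int(k): v for k, v in (inp.get("polarities") or {}).items()}
    paths = {
        fid: resample_path(raw, spacing,
                           polarity=polarities.get(fid, "unknown"),
                           filament_id=fid)
        for fid, raw in enumerate(raw_traces)
    }
    return table, paths, counts


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        table, paths, counts = _ingest(config)

        stage = "clean"
        if config.clean.get("enabled", False):
            table = seeding.remove_duplicates(
                table, float(config.clean.get("min_dist", 7.0))
            )
            counts["after_dedup"] = len(table)
            if not np.all(np.isnan(table.scores)):
                table = seeding.filter_by_score(
                    table, float(config.clean.get("score_threshold", 0.32))
                )
                counts["after_score_filter"] = len(table)
            pol = config.clean.get("polarities")
            if pol:
                table = seeding.flip_polarity(
                    table, {int(k): v for k, v in pol.items()}
                )

        stage = "analysis"
        model = OligomerChainModel(table, paths, config.analysis_params())
        results = model.fit()
        counts["pairs"] = results.n_pairs
        counts["chains"] = results.n_chains

        stage = "export"
        manifest = results.to_csv(out_dir)
        with open(out_dir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
        manifest["config_echo.yaml"] = out_dir / "config_echo.yaml"
        if config.plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            if results.theta_hist is not None:
                ax = results.plot_theta()
                ax.figure.savefig(out_dir / "theta_histogram.png", dpi=120)
                plt.close(ax.figure)
            if len(results.chain_hist):
                ax = results.plot_chain_lengths()
                ax.figure.savefig(out_dir / "chain_lengths.png", dpi=120)
                plt.close(ax.figure)

        report = RunReport(
            theta_mode=results.theta_mode,
            max_copy_number=results.max_copy_number,
            pooled_density=results.pooled_density,
            max_angular_extent=results.max_angular_extent,
            n_particles=len(table),
            n_pairs=results.n_pairs,
            n_chains=results.n_chains,
            stage_counts=counts,
            manifest=manifest,
        )
        with open(out_dir / "report.yaml", "w") as fh:
            yaml.safe_dump(report.to_dict(), fh, sort_keys=True)
        report.manifest["report.yaml"] = out_dir / "report.yaml"
        return report
    except Exception:
        logger.error("pipeline failed at stage %r (out_dir=%s)", stage, out_dir)
        raise
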