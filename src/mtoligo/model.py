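"""Model/Results interface for the oligomer-chain analysis.

`OligomerChainModel` bundles a particle table, the filament paths and the
analysis parameters; `fit()` runs the full geometric analysis (pairs →
orientation classes → chains → histograms → densities → angular extents)
and returns an `OligomerChainResults` carrying tidy DataFrames, the summary
statistics and plotting/export helpers — the same shape statsmodels gives a
fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import geometry as geo
from .coords_io import ParticleTable
from .errors import ValidationError
from .filament import FilamentPath


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable windows of the geometric analysis (all config-exposed).

    max_dist bounds which pairs are considered at all; dist_window and
    tol_perp select the chain edges; tol_par defines the parallel class;
    theta_bin_width sets the θ histogram resolution.
    """

    max_dist: float = geo.DEFAULT_MAX_DIST  # nm
    dist_window: tuple = geo.DEFAULT_DIST_WINDOW  # nm
    tol_perp: float = geo.DEFAULT_TOL_PERP  # degrees
    tol_par: float = geo.DEFAULT_TOL_PAR  # degrees
    theta_bin_width: float = 10.0  # degrees
    capture_radius: float = 40.0  # nm
    # orientation classes whose pairs become chain edges; ring-like
    # decoration chains through perpendicular pairs, a pitched helix
    # through "other"-class pairs
    chain_classes: tuple = (geo.PERPENDICULAR,)


class OligomerChainModel:
    """Geometric model of dimer-chain decoration on filaments.

    Parameters
    ----------
    table : particle table (positions nm, orientations, filament ids).
    paths : mapping filament_id -> FilamentPath (resampled, with polarity).
    params : analysis windows; defaults bracket one dimer footprint.
    """

    def __init__(
        self,
        table: ParticleTable,
        paths: Mapping[int, FilamentPath],
        params: AnalysisParams | None = None,
    ):
        self.table = table
        self.paths = dict(paths)
        self.params = params or AnalysisParams()

    @classmethod
    def from_files(
        cls,
        particle_path,
        trace_path,
        dialect: str = "dynamo-table",
        voxel_size: float = 10.0,
        spacing: float = 7.0,
        params: AnalysisParams | None = None,
        polarities: Mapping[int, str] | None = None,
    ) -> "OligomerChainModel":
        """Build the model straight from a particle table and a trace file.

        Traces are resampled at ``spacing`` nm and numbered 0.. in file
        order; particle filament ids must use the same numbering.
        """
        from .coords_io import read_filament_trace, read_particle_table
        from .filament import resample_path

        table = read_particle_table(particle_path, dialect, voxel_size)
        raw_traces = read_filament_trace(trace_path)
        paths = {}
        for fid, raw in enumerate(raw_traces):
            pol = (polarities or {}).get(fid, "unknown")
            paths[fid] = resample_path(raw, spacing, polarity=pol, filament_id=fid)
        return cls(table, paths, params)

    def fit(self) -> "OligomerChainResults":
        """Run the analysis and return the results object."""
        par = self.params
        table = self.table
        pairs = geo.compute_pairs(table, self.paths, par.max_dist)
        geo.classify_pairs(pairs, par.tol_perp, par.tol_par)

        # cylindrical coordinates of every assigned particle on its filament
        azimuth_of: dict[int, float] = {}
        s_of: dict[int, float] = {}
        assigned: list[int] = []
        for fid, path in self.paths.items():
            idx = np.flatnonzero(table.filament_ids == fid)
            if len(idx) == 0:
                continue
            coords = path.cylindrical_coords(table.positions[idx], par.capture_radius)
            for k, i in enumerate(idx):
                if not np.isnan(coords[k, 0]):
                    assigned.append(int(i))
                    s_of[int(i)] = float(coords[k, 0])
                    azimuth_of[int(i)] = float(coords[k, 2])

        filament_of = {int(i): int(table.filament_ids[i]) for i in assigned}
        chains = geo.group_chains(
            pairs,
            classes=frozenset(par.chain_classes),
            dist_window=par.dist_window,
            particle_ids=assigned,
            filament_of=filament_of,
            azimuth_of=azimuth_of,
        )
        chain_hist, max_copy = geo.chain_length_frequency(chains)
        theta_hist = geo.theta_histogram(pairs, par.theta_bin_width) if pairs else None
        per_density, pooled_density = geo.linear_density_summary(table, self.paths)
        return OligomerChainResults(
            model=self,
            pairs=pairs,
            chains=chains,
            theta_hist=theta_hist,
            chain_hist=chain_hist,
            max_copy_number=max_copy,
            density_per_filament=per_density,
            pooled_density=pooled_density,
            azimuth_of=azimuth_of,
            arc_of=s_of,
        )


class OligomerChainResults:
    """Fitted decoration statistics with export and plotting helpers."""

    def __init__(
        self,
        model: OligomerChainModel,
        pairs,
        chains,
        theta_hist,
        chain_hist,
        max_copy_number,
        density_per_filament,
        pooled_density,
        azimuth_of,
        arc_of,
    ):
        self.model = model
        self.pairs = pairs
        self.chains = chains
        self.theta_hist = theta_hist
        self.chain_hist = chain_hist
        self.max_copy_number = max_copy_number
        self.density_per_filament = density_per_filament
        self.pooled_density = pooled_density
        self.azimuth_of = azimuth_of
        self.arc_of = arc_of

    # -- headline statistics ---------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def theta_mode(self) -> float | None:
        """Center of the most populated θ bin (None without pairs)."""
        if self.theta_hist is None:
            return None
        return geo.histogram_mode(self.theta_hist)

    @property
    def max_angular_extent(self) -> float:
        """Largest azimuth arc (degrees) any chain spans; 0 without chains."""
        extents = [c.angular_extent for c in self.chains if not np.isnan(c.angular_extent)]
        return float(max(extents)) if extents else 0.0

    # -- tidy views -------------------------------------------------------

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id_a": [p.id_a for p in self.pairs],
                "id_b": [p.id_b for p in self.pairs],
                "distance_nm": [p.distance for p in self.pairs],
                "theta_deg": [p.theta for p in self.pairs],
                "pair_class": [p.pair_class for p in self.pairs],
                "filament_id": [p.filament_id for p in self.pairs],
            }
        )

    def chains_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": np.arange(len(self.chains)),
                "copy_number": [c.copy_number for c in self.chains],
                "angular_extent_deg": [c.angular_extent for c in self.chains],
                "filament_id": [c.filament_id for c in self.chains],
                "member_ids": ["+".join(map(str, c.member_ids)) for c in self.chains],
            }
        )

    def density_frame(self) -> pd.DataFrame:
        fids = sorted(self.density_per_filament)
        rows = pd.DataFrame(
            {
                "filament_id": fids,
                "length_nm": [self.model.paths[f].length for f in fids],
                "particles_per_nm": [self.density_per_filament[f] for f in fids],
            }
        )
        return rows

    @staticmethod
    def _hist_frame(h: geo.Histogram) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": h.bin_centers, "count": h.counts, "density": h.densities}
        )

    # -- summary / export -------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Oligomer chain analysis",
            "=" * 55,
            f"particles              {len(self.model.table):>8d}",
            f"filaments              {len(self.model.paths):>8d}",
            f"pairs (<= {self.model.params.max_dist:g} nm)      {self.n_pairs:>8d}",
            f"chains                 {self.n_chains:>8d}",
            f"theta mode [deg]       {self.theta_mode if self.theta_mode is not None else 'n/a':>8}",
            f"max copy number        {self.max_copy_number if self.max_copy_number is not None else 'n/a':>8}",
            f"max angular extent [deg] {self.max_angular_extent:>8.1f}",
            f"pooled density [1/nm]  {self.pooled_density:>8.4f}",
        ]
        return "\n".join(lines)

    def to_csv(self, out_dir) -> dict[str, Path]:
        """Write the tidy tables and histograms; returns the file manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {}

        def _write(name: str, df: pd.DataFrame):
            p = out_dir / name
            df.to_csv(p, index=False)
            manifest[name] = p

        _write("pairs.csv", self.pairs_frame())
        _write("chains.csv", self.chains_frame())
        _write("density.csv", self.density_frame())
        if self.theta_hist is not None:
            _write("theta_histogram.csv", self._hist_frame(self.theta_hist))
        if len(self.chain_hist):
            _write("chain_length_histogram.csv", self._hist_frame(self.chain_hist))
        return manifest

    # -- plots -------------------------------------------------------------

    def plot_theta(self, ax=None):
        """Bar plot of the θ-angle distribution (Fig.-style frequency plot)."""
        import matplotlib.pyplot as plt

        if self.theta_hist is None:
            raise ValidationError("no pairs; nothing to plot")
        if ax is None:
            _, ax = plt.subplots()
        h = self.theta_hist
        ax.bar(h.bin_centers, h.counts, width=h.bin_width * 0.9)
        ax.set_xlabel("theta angle [deg]")
        ax.set_ylabel("pair count")
        ax.set_xlim(-5, 185)
        return ax

    def plot_chain_lengths(self, ax=None):
        """Frequency plot of chain copy numbers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.chain_hist
        ax.bar(h.bin_centers, h.counts, width=0.8)
        ax.set_xlabel("dimers per chain")
        ax.set_ylabel("chain count")
        return ax
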