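"""Synthetic decorated-microtubule coordinate sets with ground truth.

Everything here works purely in coordinate/orientation space — no density,
no images.  The generator emulates the statistical structure of
LRRK2-decorated microtubules seen in cryo-ET tomograms:

* a tubulin lattice on a cylinder (11–16 protofilaments; the 13-pf lattice
  has twist −27.7° and rise 9.4 Å per subunit along the 1-start helix);
* dimer decoration at ~23 nm radius that is either circumferential
  ("ring-perpendicular" mode, pair θ ≈ 90°, short sparse chains of 1–6
  dimers) or an axially pitched right-handed helix ("helical" mode,
  θ ≈ 33°, near-continuous);
* nuisance structure: orientation noise, positional jitter, spurious
  unattached particles, and per-filament polarity flips mimicking traces
  digitized against the growth direction.

Ground truth (chain memberships and the polarity map) is returned with the
particles so every analysis stage can be validated exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .coords_io import (
    ParticleTable,
    write_filament_trace,
    write_particle_table,
)
from .errors import ConfigurationError, ValidationError
from .filament import FilamentPath, resample_path
from .seeding import _outward_orientation

ANGSTROM_PER_NM = 10.0

_POLARITY_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg about particle x


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a protofilament lattice on a cylinder.

    twist/rise are per subunit along the 1-start helix.  ``tube_radius``
    places the subunit centers; it is deliberately smaller than the
    decoration radius so bound particles sit outside the wall.
    """

    n_protofilaments: int = 13
    twist: float = -27.7  # degrees per subunit
    rise: float = 9.4  # Å per subunit
    tube_radius: float = 11.5  # nm, subunit centers
    n_subunits: int = 200
    rng_seed: int = 0

    def __post_init__(self):
        if not (11 <= self.n_protofilaments <= 16):
            raise ValidationError("protofilament presets cover 11-16")
        if self.rise <= 0:
            raise ValidationError("rise must be positive")


def lattice_preset(n_protofilaments: int = 13, **overrides) -> LatticeSpec:
    """Preset lattice for a given protofilament count.

    The 13-pf preset uses the refined helical parameters (−27.7°, 9.4 Å);
    other counts use the ideal 1-start twist −360/N at the same rise
    (supertwist is not modeled).
    """
    twist = -27.7 if n_protofilaments == 13 else -360.0 / n_protofilaments
    return LatticeSpec(n_protofilaments=n_protofilaments, twist=twist, **overrides)


def straight_path(length: float, spacing: float = 7.0, filament_id: int = 0,
                  polarity: str = "plus") -> FilamentPath:
    """A straight z-axis filament of the given length (nm)."""
    return resample_path(
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(length)]]),
        spacing, polarity=polarity, filament_id=filament_id,
    )


def make_microtubule_lattice(
    spec: LatticeSpec, path: FilamentPath | None = None
) -> ParticleTable:
    """Subunit positions/orientations of the 1-start lattice helix.

    Subunit n sits at axial position n·rise and azimuth n·twist on a
    cylinder of ``tube_radius``; with a ``path`` the lattice is bent onto
    the centerline using its transported frames.  Table rows are in lattice
    order (required by :func:`estimate_helical_params`).
    """
    n = spec.n_subunits
    idx = np.arange(n)
    phis = idx * spec.twist  # degrees, unwrapped
    zs = idx * spec.rise / ANGSTROM_PER_NM  # nm
    if path is None:
        # extend past the last subunit so arc-length lookups never clip
        spacing = 7.0
        length = (np.floor(zs[-1] / spacing) + 2) * spacing if n > 1 else 2 * spacing
        path = straight_path(length, spacing=spacing)
    positions = np.empty((n, 3))
    rotations = np.empty((n, 3, 3))
    for k in range(n):
        i = int(np.clip(round(zs[k] / path.spacing), 0, path.n_points - 1))
        t, nvec, b = path.local_frame(i)
        ds = zs[k] - i * path.spacing
        phi = np.radians(phis[k])
        radial = np.cos(phi) * nvec + np.sin(phi) * b
        positions[k] = path.points[i] + ds * t + spec.tube_radius * radial
        rotations[k] = _outward_orientation(t, radial)
    return ParticleTable(
        positions,
        rotations,
        filament_ids=np.full(n, path.filament_id, dtype=int),
        provenance=f"lattice pf={spec.n_protofilaments} twist={spec.twist} rise={spec.rise}",
    )


def estimate_helical_params(
    subunits: ParticleTable, path: FilamentPath
) -> tuple[float, float]:
    """Recover (twist °/subunit, rise Å/subunit) from a lattice in table order.

    Twist is the circular mean of consecutive azimuth increments, rise the
    mean consecutive axial increment; both are exact on noise-free lattices.
    """
    if len(subunits) < 2:
        raise ValidationError("need at least 2 subunits to estimate helical parameters")
    coords = path.cylindrical_coords(subunits.positions)
    if np.any(np.isnan(coords)):
        raise ValidationError("subunit beyond path capture radius")
    s, _, phi = coords.T
    dphi = np.diff(phi)
    dphi = (dphi + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    ang = np.radians(dphi)
    twist = float(np.degrees(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))))
    rise = float(np.mean(np.diff(s)) * ANGSTROM_PER_NM)
    return twist, rise


def _truncated_geometric_law(p: float = 0.5, max_len: int = 6) -> dict[int, float]:
    w = np.array([(1 - p) ** (k - 1) * p for k in range(1, max_len + 1)])
    w /= w.sum()
    return {k + 1: float(w[k]) for k in range(max_len)}


@dataclass(frozen=True)
class DecorationSpec:
    """Generative parameters for dimer decoration of one filament.

    ``ring-perpendicular`` mode grows chains circumferentially on isolated
    rings (short, sparse oligomers); ``helical`` mode lays one continuous
    right-handed helix whose consecutive-member displacement makes
    ``target_helical_angle`` with the filament axis.
    """

    mode: str = "ring-perpendicular"
    deco_radius: float = 23.0  # nm
    ring_spacing: float = 7.0  # nm
    sites_per_ring: int = 18
    chain_length_law: dict = field(default_factory=_truncated_geometric_law)
    target_helical_angle: float = 33.0  # degrees (helical mode)
    occupancy: float = 0.3  # fraction of rings (ring mode) / sites (helical) seeded
    orientation_noise_sigma: float = 8.0  # degrees
    position_jitter_sigma: float = 1.0  # nm
    spurious_rate: float = 1.0  # particles per 100 nm of filament
    polarity_flip_prob: float = 0.5  # per filament
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError("occupancy must be in [0, 1]")
        total = sum(self.chain_length_law.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("chain_length_law must sum to 1")
        if self.mode not in ("ring-perpendicular", "helical"):
            raise ConfigurationError(f"unknown decoration mode {self.mode!r}")

    def noise_free(self) -> "DecorationSpec":
        """Copy with all nuisance processes switched off."""
        return dataclasses.replace(
            self,
            orientation_noise_sigma=0.0,
            position_jitter_sigma=0.0,
            spurious_rate=0.0,
            polarity_flip_prob=0.0,
        )


@dataclass
class GroundTruth:
    """Generator-side labels: who belongs to which chain, and trace polarity."""

    chain_label: np.ndarray  # per-particle chain index; -1 = spurious
    chains: list  # list of member-index lists, table order
    polarity: dict  # filament_id -> "plus" | "minus"

    @staticmethod
    def merge(parts: list["GroundTruth"], offsets: list[int]) -> "GroundTruth":
        labels = []
        chains = []
        polarity = {}
        chain_off = 0
        for gt, off in zip(parts, offsets):
            lab = gt.chain_label.copy()
            lab[lab >= 0] += chain_off
            labels.append(lab)
            chains.extend([[m + off for m in ch] for ch in gt.chains])
            polarity.update(gt.polarity)
            chain_off += len(gt.chains)
        return GroundTruth(
            np.concatenate(labels) if labels else np.zeros(0, dtype=int),
            chains,
            polarity,
        )


def _draw_chain_length(rng: np.random.Generator, law: dict[int, float]) -> int:
    ks = sorted(law)
    probs = np.array([law[k] for k in ks])
    return int(rng.choice(ks, p=probs / probs.sum()))


def decorate_filament(
    path: FilamentPath, spec: DecorationSpec, rng: np.random.Generator | None = None
) -> tuple[ParticleTable, GroundTruth]:
    """Decorate one filament with dimer chains plus nuisance particles.

    Returns the particle table (scores drawn uniform on [0.32, 1), i.e.
    already above the usual cross-correlation cut) and the ground truth.
    The filament's polarity is drawn here; when it comes out minus, every
    particle orientation is flipped 180° about its x-axis exactly as the
    polarity-harmonization step would (and can therefore be undone by it).
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    if abs(path.spacing - spec.ring_spacing) > 1e-9:
        path = resample_path(path.points, spec.ring_spacing,
                             polarity=path.polarity, filament_id=path.filament_id)
    dphi_site = 360.0 / spec.sites_per_ring

    positions: list[np.ndarray] = []
    rotations: list[np.ndarray] = []
    chain_label: list[int] = []
    chains: list[list[int]] = []

    def _add_member(s: float, phi_deg: float, label: int):
        i = int(np.clip(round(s / path.spacing), 0, path.n_points - 1))
        t, nvec, b = path.local_frame(i)
        phi = np.radians(phi_deg)
        radial = np.cos(phi) * nvec + np.sin(phi) * b
        pos = path.points[i] + (s - i * path.spacing) * t + spec.deco_radius * radial
        positions.append(pos)
        rotations.append(_outward_orientation(t, radial))
        chain_label.append(label)

    if spec.mode == "ring-perpendicular":
        max_law = max(spec.chain_length_law)
        if max_law > spec.sites_per_ring:
            raise ValidationError(
                f"chain length {max_law} exceeds sites_per_ring {spec.sites_per_ring}"
            )
        for ring in range(path.n_points):
            if rng.uniform() >= spec.occupancy:
                continue
            length = _draw_chain_length(rng, spec.chain_length_law)
            start_site = int(rng.integers(spec.sites_per_ring))
            members = []
            s = ring * path.spacing
            for m in range(length):
                members.append(len(positions))
                _add_member(s, (start_site + m) * dphi_site, len(chains))
            chains.append(members)
    else:  # helical
        chord = 2.0 * spec.deco_radius * np.sin(np.radians(dphi_site / 2.0))
        ds = chord / np.tan(np.radians(spec.target_helical_angle))
        n_steps = int(np.floor(path.length / ds)) + 1
        phi0 = rng.uniform(0.0, 360.0)
        current: list[int] = []
        for k in range(n_steps):
            if rng.uniform() < spec.occupancy:
                current.append(len(positions))
                _add_member(k * ds, phi0 + k * dphi_site, len(chains))
            elif current:
                chains.append(current)
                current = []
        if current:
            chains.append(current)
        # re-label members by final chain index
        chain_label = list(chain_label)
        for ci, ch in enumerate(chains):
            for m in ch:
                chain_label[m] = ci

    n_real = len(positions)

    # nuisance: spurious particles uniform on the decoration cylinder
    n_spurious = rng.poisson(spec.spurious_rate * path.length / 100.0)
    for _ in range(n_spurious):
        s = rng.uniform(0.0, path.length)
        phi = rng.uniform(0.0, 360.0)
        _add_member(s, phi, -1)
        rotations[-1] = Rotation.random(rng=rng).as_matrix()

    pos_arr = np.array(positions) if positions else np.zeros((0, 3))
    rot_arr = np.array(rotations) if rotations else np.zeros((0, 3, 3))
    n = len(pos_arr)

    if spec.position_jitter_sigma > 0 and n:
        pos_arr = pos_arr + rng.normal(0.0, spec.position_jitter_sigma, size=(n, 3))
    if spec.orientation_noise_sigma > 0 and n:
        rotvecs = rng.normal(0.0, np.radians(spec.orientation_noise_sigma), size=(n, 3))
        wobble = Rotation.from_rotvec(rotvecs).as_matrix()
        rot_arr = np.einsum("nij,njk->nik", rot_arr, wobble)

    polarity = "minus" if rng.uniform() < spec.polarity_flip_prob else "plus"
    if polarity == "minus" and n:
        rot_arr = np.einsum("nij,jk->nik", rot_arr, _POLARITY_FLIP)

    scores = rng.uniform(0.32, 1.0, size=n)
    table = ParticleTable(
        pos_arr,
        rot_arr,
        scores=scores,
        filament_ids=np.full(n, path.filament_id, dtype=int),
        provenance=f"synthetic decoration mode={spec.mode}",
    )
    gt = GroundTruth(
        chain_label=np.asarray(chain_label, dtype=int),
        chains=chains,
        polarity={path.filament_id: polarity},
    )
    return table, gt


# ---------------------------------------------------------------------------
# tilt-scheme metadata


@dataclass(frozen=True)
class TiltScheme:
    """Dose-symmetric tilt-series acquisition metadata (no image content)."""

    min_angle: float
    max_angle: float
    increment: float
    ordering: tuple
    n_tilts: int


def make_tilt_scheme(
    min_angle: float = -54.0, max_angle: float = 54.0, increment: float = 3.0
) -> TiltScheme:
    """Dose-symmetric ordering 0, +i, −i, +2i, −2i, … of the tilt angles."""
    if increment <= 0:
        raise ValidationError("increment must be positive")
    span = max_angle - min_angle
    n_float = span / increment
    if abs(n_float - round(n_float)) > 1e-9:
        raise ValidationError(
            f"increment {increment} does not divide the range [{min_angle}, {max_angle}]"
        )
    angles = min_angle + increment * np.arange(int(round(n_float)) + 1)
    ordering: list[float] = []
    zero = angles[np.argmin(np.abs(angles))]
    ordering.append(float(zero))
    k = 1
    while len(ordering) < len(angles):
        for cand in (zero + k * increment, zero - k * increment):
            if min_angle - 1e-9 <= cand <= max_angle + 1e-9:
                ordering.append(float(cand))
        k += 1
    return TiltScheme(
        float(min_angle), float(max_angle), float(increment),
        tuple(ordering), len(angles),
    )


# ---------------------------------------------------------------------------
# fixtures


PRESETS = {
    # short sparse circumferential chains, as in the autoinhibited samples
    "paper-like": DecorationSpec(mode="ring-perpendicular"),
    # near-continuous right-handed 33-degree helix, as in active-like samples
    "active-like": DecorationSpec(
        mode="helical", target_helical_angle=33.0, occupancy=0.95
    ),
}


def preset_spec(preset: str, **overrides) -> DecorationSpec:
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[preset], **overrides)


@dataclass
class FixtureBundle:
    """A complete synthetic dataset: traces, particles, truth, config echo."""

    traces: list  # raw trace point arrays, nm
    paths: dict  # filament_id -> FilamentPath (resampled, polarity from truth)
    table: ParticleTable
    ground_truth: GroundTruth
    config: dict


def _random_trace(
    rng: np.random.Generator, length: float, n_ctrl: int = 12
) -> np.ndarray:
    """A gently curved centerline: a circular arc of 5-20 um radius in a
    random plane, sampled at n_ctrl control points."""
    radius = rng.uniform(5000.0, 20000.0)  # nm
    arc = length / radius
    t = np.linspace(0.0, arc, n_ctrl)
    pts = np.column_stack(
        [radius * np.sin(t), radius * (1.0 - np.cos(t)), np.zeros_like(t)]
    )
    frame = Rotation.random(rng=rng).as_matrix()
    offset = rng.uniform(-1000.0, 1000.0, size=3)
    return pts @ frame.T + offset


def make_fixture(
    preset: str = "paper-like",
    n_filaments: int = 20,
    rng_seed: int = 42,
    filament_length: float = 500.0,
    out_dir=None,
    spec_overrides: dict | None = None,
) -> FixtureBundle:
    """Generate a multi-filament decorated dataset with ground truth.

    Deterministic for a fixed ``rng_seed``.  With ``out_dir`` the bundle is
    written to disk: traces (plain text), the particle table (both
    dialects), a ground-truth CSV and a YAML echo of the configuration.
    """
    spec = preset_spec(preset, **(spec_overrides or {}))
    rng = np.random.default_rng(rng_seed)
    traces, paths, tables, gts, offsets = [], {}, [], [], []
    offset = 0
    for fid in range(n_filaments):
        raw = _random_trace(rng, filament_length)
        path = resample_path(raw, spec.ring_spacing, filament_id=fid)
        tbl, gt = decorate_filament(path, spec, rng=rng)
        path.polarity = gt.polarity[fid]
        traces.append(raw)
        paths[fid] = path
        tables.append(tbl)
        gts.append(gt)
        offsets.append(offset)
        offset += len(tbl)
    table = ParticleTable.concatenate(tables) if tables else ParticleTable(np.zeros((0, 3)))
    truth = GroundTruth.merge(gts, offsets)
    config = {
        "preset": preset,
        "n_filaments": n_filaments,
        "rng_seed": rng_seed,
        "filament_length": filament_length,
        "decoration": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(spec).items()
        },
    }
    bundle = FixtureBundle(traces, paths, table, truth, config)
    if out_dir is not None:
        _write_fixture(bundle, Path(out_dir))
    return bundle


def _write_fixture(bundle: FixtureBundle, out_dir: Path) -> None:
    import pandas as pd
    import yaml

    out_dir.mkdir(parents=True, exist_ok=True)
    write_filament_trace(bundle.traces, out_dir / "traces.txt",
                         provenance="synthetic fixture")
    write_particle_table(bundle.table, out_dir / "particles.tbl", "dynamo-table")
    write_particle_table(bundle.table, out_dir / "particles.star", "star")
    pd.DataFrame(
        {
            "particle": np.arange(len(bundle.table)),
            "filament_id": bundle.table.filament_ids,
            "chain_label": bundle.ground_truth.chain_label,
        }
    ).to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame(
        {
            "filament_id": sorted(bundle.ground_truth.polarity),
            "polarity": [bundle.ground_truth.polarity[k]
                         for k in sorted(bundle.ground_truth.polarity)],
        }
    ).to_csv(out_dir / "polarity.csv", index=False)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
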