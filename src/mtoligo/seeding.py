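"""Oversampled ring seeding around filaments and the cleaning steps applied
to picked subtomograms: azimuth randomization, distance-based duplicate
removal, cross-correlation score filtering and polarity harmonization.

The seeding geometry mirrors the standard tubular-surface picking recipe:
rings orthogonal to the traced path, seeds pointing outwards, oversampled so
that a later alignment + cleaning pass keeps only real particles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .coords_io import FLAG_DEDUP, FLAG_FLIPPED, FLAG_SEED, ParticleTable
from .errors import ValidationError
from .filament import FilamentPath, resample_path


@dataclass(frozen=True)
class SeedSpec:
    """Ring-seeding parameters.

    Defaults are the tubular picking geometry used for microtubule-bound
    LRRK2: seeds at 23 nm from the filament axis, rings every 7 nm, 18
    seeds per ring.
    """

    radius: float = 23.0  # nm, seed distance from the centerline
    ring_spacing: float = 7.0  # nm between consecutive rings
    per_ring: int = 18  # seeds per ring
    rng_seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.ring_spacing <= 0 or self.per_ring < 1:
            raise ValidationError("SeedSpec requires radius>0, ring_spacing>0, per_ring>=1")


def _outward_orientation(tangent: np.ndarray, radial: np.ndarray) -> np.ndarray:
    """Rotation matrix with particle z along the outward radial direction.

    Columns are the particle axes in the tomogram frame: x completes the
    right-handed set, y lies along the filament tangent, z points outwards.
    """
    z = radial
    y = tangent
    x = np.cross(y, z)
    return np.column_stack([x, y, z])


def generate_ring_seeds(path: FilamentPath, spec: SeedSpec) -> ParticleTable:
    """Place oversampled seeds in rings orthogonal to the path.

    One ring per path point (the path is resampled at ``spec.ring_spacing``
    first if its spacing differs), ``spec.per_ring`` seeds per ring,
    azimuthally equispaced starting at the transported normal (φ = 0),
    each at ``spec.radius`` from the ring center with its z-axis pointing
    outwards and its y-axis along the path tangent.
    """
    if abs(path.spacing - spec.ring_spacing) > 1e-9 * max(1.0, spec.ring_spacing):
        path = resample_path(path.points, spec.ring_spacing,
                             polarity=path.polarity, filament_id=path.filament_id)
    n_rings = path.n_points
    phis = np.arange(spec.per_ring) * (360.0 / spec.per_ring)
    positions = np.empty((n_rings * spec.per_ring, 3))
    rotations = np.empty((n_rings * spec.per_ring, 3, 3))
    k = 0
    for i in range(n_rings):
        t, n, b = path.local_frame(i)
        c = path.points[i]
        for phi in np.radians(phis):
            radial = np.cos(phi) * n + np.sin(phi) * b
            positions[k] = c + spec.radius * radial
            rotations[k] = _outward_orientation(t, radial)
            k += 1
    fid = path.filament_id
    return ParticleTable(
        positions,
        rotations,
        filament_ids=np.full(len(positions), fid, dtype=int),
        flags=[{FLAG_SEED} for _ in range(len(positions))],
        provenance=f"ring seeds r={spec.radius} d={spec.ring_spacing} n={spec.per_ring}",
    )


def randomize_azimuth(table: ParticleTable, rng_seed: int = 0) -> ParticleTable:
    """Spin each particle about its own z-axis by an independent U[0, 360) angle.

    Positions are untouched; the rotation is applied in the particle frame
    (post-multiplication), so the outward z-axis is preserved.  This is the
    metadata-level counterpart of the missing-wedge-mitigation step used
    when picking on tubular surfaces.
    """
    rng = np.random.default_rng(rng_seed)
    out = table.copy()
    angles = rng.uniform(0.0, 360.0, size=len(table))
    spins = Rotation.from_euler("z", angles[:, None], degrees=True).as_matrix()
    if len(table):
        out.rotations = np.einsum("nij,njk->nik", table.rotations, spins)
    return out


def remove_duplicates(table: ParticleTable, min_dist: float = 7.0) -> ParticleTable:
    """Greedy distance-based deduplication.

    Particles are scanned in descending score order (missing scores count
    as 0; original order breaks ties); a particle is kept iff no previously
    kept particle lies within ``min_dist`` nm.
    """
    if min_dist <= 0:
        raise ValidationError("min_dist must be positive")
    n = len(table)
    if n == 0:
        return table.copy()
    scores = np.nan_to_num(table.scores, nan=0.0)
    order = np.lexsort((np.arange(n), -scores))  # score desc, index asc
    tree = cKDTree(table.positions)
    neighbors = tree.query_ball_point(table.positions, r=min_dist)
    kept = np.zeros(n, dtype=bool)
    for i in order:
        if not any(kept[j] for j in neighbors[i] if j != i):
            kept[i] = True
    out = table.select(kept)
    for f in out.flags:
        f.add(FLAG_DEDUP)
    return out


def filter_by_score(table: ParticleTable, threshold: float = 0.32) -> ParticleTable:
    """Drop particles scoring below the cross-correlation threshold.

    Particles with score exactly at the threshold are retained (only
    strictly lower scores are removed).  A particle without a score is a
    validation error — silently keeping or dropping unscored particles
    would bias the decoration statistics.
    """
    if np.any(np.isnan(table.scores)):
        bad = int(np.flatnonzero(np.isnan(table.scores))[0])
        raise ValidationError(
            f"particle {bad} has no score; filter_by_score requires scored particles"
        )
    return table.select(table.scores >= threshold)


def flip_polarity(table: ParticleTable, filament_polarity: dict) -> ParticleTable:
    """Harmonize particle orientations across filaments traced in either direction.

    Particles on minus-polarity filaments are post-rotated 180° about their
    own x-axis, inverting the particle's y (axial) and z senses; positions
    are unchanged and the ``flipped`` flag is set.  Filaments missing from
    the map (or mapped to ``"unknown"``) are left untouched with a warning.
    """
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    out = table.copy()
    unknown = set()
    for fid in np.unique(table.filament_ids):
        pol = filament_polarity.get(int(fid))
        if pol is None or pol == "unknown":
            unknown.add(int(fid))
            continue
        if pol == "minus":
            idx = np.flatnonzero(table.filament_ids == fid)
            out.rotations[idx] = np.einsum("nij,jk->nik", table.rotations[idx], flip)
            for i in idx:
                out.flags[i] ^= {FLAG_FLIPPED}
    if unknown:
        warnings.warn(f"no polarity for filament(s) {sorted(unknown)}; left unflipped")
    return out
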