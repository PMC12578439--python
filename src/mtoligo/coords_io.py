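"""Particle-table and filament-trace I/O in the Dynamo and STAR dialects.

Internally every position is in nanometres in the tomogram frame and every
orientation is stored as a proper rotation matrix mapping particle-frame
vectors into the tomogram frame.  Euler triplets exist only at the file
boundary: Dynamo tables carry intrinsic ZXZ angles (tdrot, tilt, narot),
STAR files carry intrinsic ZYZ angles (rot, tilt, psi).

Coordinate conventions: Dynamo pixel coordinates are taken as the reference
frame, so ``nm = px * voxel_size / 10``.  STAR coordinates are 0-based, one
voxel below the Dynamo convention, and the readers/writers add or subtract
one voxel accordingly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, FormatError, ParseError, ValidationError

ANGSTROM_PER_NM = 10.0

#: Euler conventions understood by :func:`convert_euler`.  Values are the
#: scipy axis strings (uppercase = intrinsic).
CONVENTIONS = {
    "dynamo-zxz": "ZXZ",
    "relion-zyz": "ZYZ",
}

# particle flags
FLAG_SEED = "seed"
FLAG_FLIPPED = "flipped"
FLAG_DEDUP = "duplicate-removed"


@dataclass(frozen=True)
class EulerTriplet:
    """Three Euler angles in degrees tagged with their convention."""

    a1: float
    a2: float
    a3: float
    convention: str = "dynamo-zxz"

    def as_matrix(self) -> np.ndarray:
        return euler_to_matrix(
            np.array([self.a1, self.a2, self.a3]), self.convention
        )


@dataclass(frozen=True)
class Particle:
    """A single subtomogram's coordinate-space metadata (read-only view)."""

    position: np.ndarray  # (3,) nm, tomogram frame
    rotation: np.ndarray  # (3,3) particle frame -> tomogram frame
    score: float  # NaN when absent
    filament_id: int  # -1 when absent
    tomo_id: str
    flags: frozenset


def _check_convention(convention: str) -> str:
    try:
        return CONVENTIONS[convention]
    except KeyError:
        raise ConfigurationError(
            f"unknown Euler convention {convention!r}; "
            f"supported: {sorted(CONVENTIONS)}"
        ) from None


def euler_to_matrix(angles, convention: str) -> np.ndarray:
    """Expand Euler angles (degrees) to rotation matrices.

    ``angles`` is ``(3,)`` or ``(n, 3)``; the result matches with shape
    ``(3, 3)`` or ``(n, 3, 3)``.
    """
    seq = _check_convention(convention)
    return Rotation.from_euler(seq, np.asarray(angles, float), degrees=True).as_matrix()


def matrix_to_euler(matrices, convention: str) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix` (up to gimbal-equivalent triplets).

    Extraction is done directly with atan2 on matrix elements rather than
    through a quaternion, which keeps the round-trip error at the 1e-12
    level even close to the gimbal-locked configurations (second angle near
    0 or 180 degrees), where the third angle is set to zero.
    """
    _check_convention(convention)
    R = np.asarray(matrices, float)
    single = R.ndim == 2
    R = R.reshape(-1, 3, 3)
    if convention == "dynamo-zxz":
        # R = Rz(a1) Rx(a2) Rz(a3):  R[0,2]=s1*s2, R[1,2]=-c1*s2,
        # R[2,0]=s2*s3, R[2,1]=s2*c3, R[2,2]=c2
        s2 = np.hypot(R[:, 2, 0], R[:, 2, 1])
        a2 = np.arctan2(s2, R[:, 2, 2])
        a1 = np.arctan2(R[:, 0, 2], -R[:, 1, 2])
        a3 = np.arctan2(R[:, 2, 0], R[:, 2, 1])
    else:  # relion-zyz
        # R = Rz(a1) Ry(a2) Rz(a3):  R[0,2]=c1*s2, R[1,2]=s1*s2,
        # R[2,0]=-s2*c3, R[2,1]=s2*s3, R[2,2]=c2
        s2 = np.hypot(R[:, 2, 0], R[:, 2, 1])
        a2 = np.arctan2(s2, R[:, 2, 2])
        a1 = np.arctan2(R[:, 1, 2], R[:, 0, 2])
        a3 = np.arctan2(R[:, 2, 1], -R[:, 2, 0])
    gimbal = s2 < 1e-12
    if np.any(gimbal):
        # second rotation vanishes (or is 180 deg): only a1-/+a3 is defined;
        # convention: a3 = 0 and a1 carries the whole in-plane rotation
        r00 = R[gimbal, 0, 0]
        r10 = R[gimbal, 1, 0]
        if convention == "relion-zyz":
            flip = R[gimbal, 2, 2] < 0
            r00 = np.where(flip, -r00, r00)
            r10 = np.where(flip, -r10, r10)
        a1 = a1.copy()
        a3 = a3.copy()
        a1[gimbal] = np.arctan2(r10, r00)
        a3[gimbal] = 0.0
    out = np.degrees(np.stack([a1, a2, a3], axis=1))
    return out[0] if single else out


def convert_euler(e: EulerTriplet, target_convention: str) -> EulerTriplet:
    """Re-express an Euler triplet in another convention.

    The rotation matrix is preserved exactly; the angle values themselves may
    differ even for identical conventions when the source triplet is not the
    canonical representative.
    """
    m = e.as_matrix()
    a1, a2, a3 = matrix_to_euler(m, target_convention)
    return EulerTriplet(float(a1), float(a2), float(a3), target_convention)


class ParticleTable:
    """Column-oriented container for subtomogram coordinate metadata.

    Parameters
    ----------
    positions : (n, 3) array, nm, tomogram frame.
    rotations : (n, 3, 3) array of proper rotation matrices.
    scores : (n,) array; NaN marks an absent score.
    filament_ids : (n,) int array; -1 marks an unassigned particle.
    tomo_ids : sequence of str.
    flags : sequence of sets drawn from {seed, flipped, duplicate-removed}.
    voxel_size : Å per pixel used for dialect conversion.
    provenance : free-text history line.
    """

    def __init__(
        self,
        positions,
        rotations=None,
        scores=None,
        filament_ids=None,
        tomo_ids=None,
        flags=None,
        voxel_size: float = 10.0,
        provenance: str = "",
    ):
        self.positions = np.atleast_2d(np.asarray(positions, float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValidationError(f"positions must be (n, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("particle positions must be finite")
        if rotations is None:
            rotations = np.broadcast_to(np.eye(3), (n, 3, 3))
        self.rotations = np.asarray(rotations, float).reshape(n, 3, 3).copy()
        dets = np.linalg.det(self.rotations)
        if n and not np.allclose(dets, 1.0, atol=1e-6):
            raise ValidationError("orientations must be proper rotations (det +1)")
        self.scores = (
            np.full(n, np.nan) if scores is None else np.asarray(scores, float).reshape(n)
        )
        self.filament_ids = (
            np.full(n, -1, dtype=int)
            if filament_ids is None
            else np.asarray(filament_ids, int).reshape(n)
        )
        self.tomo_ids = (
            ["" for _ in range(n)] if tomo_ids is None else [str(t) for t in tomo_ids]
        )
        self.flags = (
            [set() for _ in range(n)] if flags is None else [set(f) for f in flags]
        )
        if not (len(self.tomo_ids) == len(self.flags) == n == len(self.scores)):
            raise ValidationError("column lengths disagree")
        self.voxel_size = float(voxel_size)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> Particle:
        return Particle(
            position=self.positions[i].copy(),
            rotation=self.rotations[i].copy(),
            score=float(self.scores[i]),
            filament_id=int(self.filament_ids[i]),
            tomo_id=self.tomo_ids[i],
            flags=frozenset(self.flags[i]),
        )

    def copy(self) -> "ParticleTable":
        return ParticleTable(
            self.positions.copy(),
            self.rotations.copy(),
            self.scores.copy(),
            self.filament_ids.copy(),
            list(self.tomo_ids),
            [set(f) for f in self.flags],
            self.voxel_size,
            self.provenance,
        )

    def select(self, mask) -> "ParticleTable":
        """Row subset (boolean mask or index array); metadata preserved."""
        idx = np.arange(len(self))[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return ParticleTable(
            self.positions[idx],
            self.rotations[idx],
            self.scores[idx],
            self.filament_ids[idx],
            [self.tomo_ids[i] for i in idx],
            [set(self.flags[i]) for i in idx],
            self.voxel_size,
            self.provenance,
        )

    @staticmethod
    def concatenate(tables: Sequence["ParticleTable"]) -> "ParticleTable":
        tables = list(tables)
        if not tables:
            return ParticleTable(np.zeros((0, 3)))
        return ParticleTable(
            np.concatenate([t.positions for t in tables]),
            np.concatenate([t.rotations for t in tables]),
            np.concatenate([t.scores for t in tables]),
            np.concatenate([t.filament_ids for t in tables]),
            sum(([*t.tomo_ids] for t in tables), []),
            sum(([set(f) for f in t.flags] for t in tables), []),
            tables[0].voxel_size,
            tables[0].provenance,
        )

    def to_dataframe(self):
        """Tidy per-particle view (positions nm, Euler angles dynamo-zxz)."""
        import pandas as pd

        ang = (
            matrix_to_euler(self.rotations, "dynamo-zxz")
            if len(self)
            else np.zeros((0, 3))
        )
        return pd.DataFrame(
            {
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "z_nm": self.positions[:, 2],
                "tdrot": ang[:, 0],
                "tilt": ang[:, 1],
                "narot": ang[:, 2],
                "score": self.scores,
                "filament_id": self.filament_ids,
                "tomo_id": self.tomo_ids,
                "flags": ["+".join(sorted(f)) for f in self.flags],
            }
        )


@dataclass(frozen=True)
class DynamoColumns:
    """1-based column indices of the common 35-column Dynamo table layout.

    The score column is configurable because tables in the wild disagree on
    where the cross-correlation value lives.
    """

    tag: int = 1
    dx: int = 4
    dy: int = 5
    dz: int = 6
    tdrot: int = 7
    tilt: int = 8
    narot: int = 9
    score: int = 10
    tomo: int = 20
    filament: int = 21
    x: int = 24
    y: int = 25
    z: int = 26
    n_columns: int = 35


# STAR tags written/required by this package
_STAR_COORD_TAGS = ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ")
_STAR_ANGLE_TAGS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
_STAR_SCORE_TAG = "_rlnAutopickFigureOfMerit"
_STAR_FILAMENT_TAG = "_rlnHelicalTubeID"
_STAR_TOMO_TAG = "_rlnTomoName"


def _parse_float(token: str, row: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"non-numeric {what} value {token!r} at row {row}") from None


def read_particle_table(
    path,
    dialect: str,
    voxel_size: float = 10.0,
    columns: DynamoColumns | None = None,
) -> ParticleTable:
    """Read a particle table, converting positions to nm on ingest.

    Parameters
    ----------
    dialect : ``"dynamo-table"`` or ``"star"``.
    voxel_size : Å per pixel of the coordinate values in the file.
    columns : Dynamo column layout override (1-based indices).
    """
    path = Path(path)
    if dialect == "dynamo-table":
        return _read_dynamo(path, voxel_size, columns or DynamoColumns())
    if dialect == "star":
        return _read_star(path, voxel_size)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def _read_dynamo(path: Path, voxel_size: float, cols: DynamoColumns) -> ParticleTable:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split()))
    need = max(cols.x, cols.y, cols.z, cols.tdrot, cols.tilt, cols.narot)
    n = len(rows)
    pos = np.zeros((n, 3))
    ang = np.zeros((n, 3))
    scores = np.full(n, np.nan)
    fil = np.full(n, -1, dtype=int)
    tomo = []
    for i, (lineno, tok) in enumerate(rows):
        if len(tok) < need:
            raise FormatError(
                f"dynamo table row {lineno} has {len(tok)} columns; "
                f"column {need} (position z) required"
            )
        xyz = [
            _parse_float(tok[c - 1], lineno, name)
            for c, name in ((cols.x, "x"), (cols.y, "y"), (cols.z, "z"))
        ]
        shifts = [
            _parse_float(tok[c - 1], lineno, name) if len(tok) >= c else 0.0
            for c, name in ((cols.dx, "dx"), (cols.dy, "dy"), (cols.dz, "dz"))
        ]
        pos[i] = (np.array(xyz) + np.array(shifts)) * voxel_size / ANGSTROM_PER_NM
        ang[i] = [
            _parse_float(tok[c - 1], lineno, name)
            for c, name in ((cols.tdrot, "tdrot"), (cols.tilt, "tilt"), (cols.narot, "narot"))
        ]
        if len(tok) >= cols.score:
            scores[i] = _parse_float(tok[cols.score - 1], lineno, "score")
        if len(tok) >= cols.filament:
            fil[i] = int(_parse_float(tok[cols.filament - 1], lineno, "filament"))
        tomo.append(tok[cols.tomo - 1] if len(tok) >= cols.tomo else "")
    rot = euler_to_matrix(ang, "dynamo-zxz") if n else np.zeros((0, 3, 3))
    return ParticleTable(
        pos, rot, scores, fil, tomo,
        voxel_size=voxel_size,
        provenance=f"read dynamo-table {path.name}",
    )


def _read_star(path: Path, voxel_size: float) -> ParticleTable:
    tags: list[str] = []
    data_rows: list[tuple[int, list[str]]] = []
    in_loop = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                tags = []
                data_rows = []
                continue
            if line.startswith("_"):
                if in_loop:
                    tags.append(line.split()[0])
                continue
            if in_loop:
                data_rows.append((lineno, line.split()))
    if not tags:
        raise FormatError(f"{path.name}: no loop_ block found")
    for tag in _STAR_COORD_TAGS:
        if tag not in tags:
            raise FormatError(f"{path.name}: missing mandatory column {tag}")
    idx = {t: i for i, t in enumerate(tags)}
    have_angles = all(t in idx for t in _STAR_ANGLE_TAGS)
    n = len(data_rows)
    pos = np.zeros((n, 3))
    ang = np.zeros((n, 3))
    scores = np.full(n, np.nan)
    fil = np.full(n, -1, dtype=int)
    tomo = []
    for i, (lineno, tok) in enumerate(data_rows):
        if len(tok) != len(tags):
            raise FormatError(
                f"{path.name} row {lineno}: {len(tok)} values for {len(tags)} tags"
            )
        pos[i] = [
            _parse_float(tok[idx[t]], lineno, t) for t in _STAR_COORD_TAGS
        ]
        if have_angles:
            ang[i] = [
                _parse_float(tok[idx[t]], lineno, t) for t in _STAR_ANGLE_TAGS
            ]
        if _STAR_SCORE_TAG in idx:
            scores[i] = _parse_float(tok[idx[_STAR_SCORE_TAG]], lineno, "score")
        if _STAR_FILAMENT_TAG in idx:
            fil[i] = int(_parse_float(tok[idx[_STAR_FILAMENT_TAG]], lineno, "filament"))
        tomo.append(tok[idx[_STAR_TOMO_TAG]] if _STAR_TOMO_TAG in idx else "")
    # STAR coordinates are 0-based: add one voxel to land in the internal
    # (Dynamo pixel-center) frame, then scale to nm.
    pos = (pos + 1.0) * voxel_size / ANGSTROM_PER_NM
    rot = euler_to_matrix(ang, "relion-zyz") if n else np.zeros((0, 3, 3))
    return ParticleTable(
        pos, rot, scores, fil, tomo,
        voxel_size=voxel_size,
        provenance=f"read star {path.name}",
    )


def write_particle_table(
    table: ParticleTable,
    path,
    dialect: str,
    columns: DynamoColumns | None = None,
) -> Path:
    """Write a table so that :func:`read_particle_table` reproduces it.

    Scores stored as NaN are written as 0 (both dialects are all-numeric).
    """
    path = Path(path)
    if dialect == "dynamo-table":
        _write_dynamo(table, path, columns or DynamoColumns())
    elif dialect == "star":
        _write_star(table, path)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    return path


def _write_dynamo(table: ParticleTable, path: Path, cols: DynamoColumns) -> None:
    n = len(table)
    ang = matrix_to_euler(table.rotations, "dynamo-zxz") if n else np.zeros((0, 3))
    px = table.positions * ANGSTROM_PER_NM / table.voxel_size
    out = np.zeros((n, cols.n_columns))
    out[:, cols.tag - 1] = np.arange(1, n + 1)
    out[:, cols.tdrot - 1] = ang[:, 0]
    out[:, cols.tilt - 1] = ang[:, 1]
    out[:, cols.narot - 1] = ang[:, 2]
    out[:, cols.score - 1] = np.nan_to_num(table.scores)
    out[:, cols.filament - 1] = table.filament_ids
    out[:, cols.x - 1] = px[:, 0]
    out[:, cols.y - 1] = px[:, 1]
    out[:, cols.z - 1] = px[:, 2]
    with open(path, "w") as fh:
        fh.write(f"# mtoligo dynamo-table | voxel_size={table.voxel_size} A/px"
                 f" | {table.provenance}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6f}".rstrip("0").rstrip(".") if v == int(v)
                              else f"{v:.6f}" for v in row) + "\n")


def _write_star(table: ParticleTable, path: Path) -> None:
    n = len(table)
    ang = matrix_to_euler(table.rotations, "relion-zyz") if n else np.zeros((0, 3))
    px = table.positions * ANGSTROM_PER_NM / table.voxel_size - 1.0  # to 0-based
    with open(path, "w") as fh:
        fh.write(f"# mtoligo star | voxel_size={table.voxel_size} A/px"
                 f" | {table.provenance}\n\ndata_particles\n\nloop_\n")
        tags = (
            list(_STAR_COORD_TAGS)
            + list(_STAR_ANGLE_TAGS)
            + [_STAR_SCORE_TAG, _STAR_FILAMENT_TAG, _STAR_TOMO_TAG]
        )
        for i, t in enumerate(tags, 1):
            fh.write(f"{t} #{i}\n")
        for i in range(n):
            vals = [
                f"{px[i, 0]:.6f}", f"{px[i, 1]:.6f}", f"{px[i, 2]:.6f}",
                f"{ang[i, 0]:.6f}", f"{ang[i, 1]:.6f}", f"{ang[i, 2]:.6f}",
                f"{np.nan_to_num(table.scores[i]):.6f}",
                str(int(table.filament_ids[i])),
                table.tomo_ids[i] or "tomo_unknown",
            ]
            fh.write(" ".join(vals) + "\n")


def read_filament_trace(path, voxel_size: float | None = None) -> list[np.ndarray]:
    """Read traced centerlines from a plain-text point file.

    Two layouts are accepted: three columns ``x y z`` with blank lines
    separating filaments, or four columns ``object_id x y z``.  Coordinates
    are nm unless ``voxel_size`` (Å/px) is given, in which case they are
    pixels and converted.

    Returns a list of ``(n_i, 3)`` arrays in input order; every filament must
    have at least two points.
    """
    path = Path(path)
    groups: dict[object, list] = {}
    order: list[object] = []
    current = 0
    saw_point = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                if saw_point:
                    current += 1
                    saw_point = False
                continue
            tok = line.split()
            if len(tok) == 3:
                key = current
                pt = tok
            elif len(tok) == 4:
                key = tok[0]
                pt = tok[1:]
            else:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 3 or 4 columns, got {len(tok)}"
                )
            xyz = [_parse_float(v, lineno, "coordinate") for v in pt]
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(xyz)
            saw_point = True
    scale = 1.0 if voxel_size is None else voxel_size / ANGSTROM_PER_NM
    result = []
    for key in order:
        pts = np.asarray(groups[key], float) * scale
        if len(pts) < 2:
            raise ValidationError(
                f"filament {key!r} in {path.name} has {len(pts)} point(s); need >= 2"
            )
        result.append(pts)
    return result


def write_filament_trace(traces: Iterable[np.ndarray], path, provenance: str = "") -> Path:
    """Write centerlines (nm) as blank-line-separated x y z blocks."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mtoligo filament trace (nm) | {provenance}\n")
        for k, pts in enumerate(traces):
            if k:
                fh.write("\n")
            for p in np.asarray(pts, float):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    return path
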