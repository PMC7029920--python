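"""Readers/writers for meshes, landmark configurations and factor tables.

The on-disk landmark dialect is a long-format CSV with header
``specimen,point,x,y,z`` (``z`` omitted for 2D data) accompanied by a
sidecar YAML describing point roles (fixed / curve / surface) and the
bilateral-symmetry pairing.  TPS-format landmark files (``LM=``/``LM3=``
records) can be imported for interoperability with classical
morphometrics tools.  Meshes are PLY or OBJ, handled by :mod:`trimesh`.

Coordinates are stored in micrometres; meshes without unit metadata are
assumed to be in micrometres and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh
import yaml

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ("population", "temperature", "line", "structure", "replicate_id")


class FormatError(ValueError):
    """Raised when a file cannot be parsed in its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Triangle surface of one specimen, in physical units (µm by default).

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Ordered vertex-index triples.
    scale_unit : str
        Physical unit of the vertex coordinates.
    """

    vertices: np.ndarray
    faces: np.ndarray
    scale_unit: str = "um"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if len(self.vertices) < 4:
            raise ValidationError("mesh needs at least 4 vertices")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError("face index out of range")

    def drop_degenerate_faces(self, area_tol: float = 0.0) -> "Mesh":
        """Return a copy without zero-area (or below-tolerance) triangles."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        area2 = np.linalg.norm(cross, axis=1)
        keep = area2 > 2.0 * area_tol
        return replace(self, faces=f[keep])

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), self.faces.copy(), self.scale_unit)


@dataclass(frozen=True)
class PointRole:
    """Role of a landmark point: anatomical (fixed) or sliding semilandmark.

    Curve semilandmarks carry a ``curve_id`` and a 0-based
    ``order_in_curve``; both must be absent for fixed and surface points.
    """

    role: str
    curve_id: int | None = None
    order_in_curve: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("fixed", "curve", "surface"):
            raise ValidationError(f"unknown point role {self.role!r}")
        has_curve = self.curve_id is not None and self.order_in_curve is not None
        if (self.role == "curve") != has_curve:
            raise ValidationError(
                "curve_id/order_in_curve present iff role is 'curve'"
            )


@dataclass
class LandmarkSample:
    """A set of landmark configurations with metadata.

    Attributes
    ----------
    coords : (n, k, d) float array
        n specimens, k points, d in {2, 3}.
    specimen_ids : list of str
    roles : list of :class:`PointRole`, length k
    pairing : list of (left_index, right_index) pairs
    midline : list of point indices lying on the symmetry plane
    factors : DataFrame indexed by specimen id
        Columns ``population, temperature, line, structure, replicate_id``
        (missing ones filled with NA).
    """

    coords: np.ndarray
    specimen_ids: list[str]
    roles: list[PointRole] = field(default_factory=list)
    pairing: list[tuple[int, int]] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)
    factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValidationError("coords must be (n, k, d)")
        n, k, d = self.coords.shape
        if n < 1 or d not in (2, 3):
            raise ValidationError("need n >= 1 specimens and d in {2, 3}")
        self.specimen_ids = [str(s) for s in self.specimen_ids]
        if len(self.specimen_ids) != n:
            raise ValidationError("specimen_ids length mismatch")
        if len(set(self.specimen_ids)) != n:
            raise ValidationError("duplicate specimen id")
        if self.roles:
            if len(self.roles) != k:
                raise ValidationError("roles length mismatch")
            _validate_curve_orders(self.roles)
        if self.pairing or self.midline:
            _validate_pairing(self.pairing, self.midline, k)
        if self.factors is not None:
            self.factors = _normalize_factors(self.factors, self.specimen_ids)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    @property
    def n_dim(self) -> int:
        return self.coords.shape[2]

    def subset(self, indices: Sequence[int]) -> "LandmarkSample":
        idx = list(indices)
        ids = [self.specimen_ids[i] for i in idx]
        factors = self.factors.loc[ids] if self.factors is not None else None
        return LandmarkSample(
            self.coords[idx], ids, list(self.roles), list(self.pairing),
            list(self.midline), factors,
        )

    def factor(self, name: str) -> np.ndarray:
        """Per-specimen values of one factor column, in specimen order."""
        if self.factors is None:
            raise ValidationError("sample has no factor table")
        return self.factors.loc[self.specimen_ids, name].to_numpy()


@dataclass
class FactorDesign:
    """The experimental design: factor levels and per-cell sample sizes.

    ``temperature_levels`` carry an explicit (developmental) order.  The
    design may be unbalanced; ``group_sizes`` maps
    ``(population, temperature)`` to a specimen count.
    """

    populations: tuple[str, ...] = ("Paris", "Sapporo", "Dayton")
    temperature_levels: tuple[int, ...] = (16, 22, 28)
    group_sizes: dict[tuple[str, int], int] | None = None
    lines_per_population: int = 10
    structures: tuple[str, ...] = ("ovipositor", "wing")

    def sizes(self) -> dict[tuple[str, int], int]:
        if self.group_sizes is not None:
            return dict(self.group_sizes)
        return dict(DEFAULT_GROUP_SIZES)

    @property
    def n_total(self) -> int:
        return sum(self.sizes().values())


#: Per-group sample sizes of the reference study design
#: (population x developmental temperature, three levels each).
DEFAULT_GROUP_SIZES: dict[tuple[str, int], int] = {
    ("Paris", 16): 20, ("Paris", 22): 11, ("Paris", 28): 13,
    ("Sapporo", 16): 19, ("Sapporo", 22): 20, ("Sapporo", 28): 23,
    ("Dayton", 16): 14, ("Dayton", 22): 6, ("Dayton", 28): 13,
}


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _validate_curve_orders(roles: Sequence[PointRole]) -> None:
    curves: dict[int, list[int]] = {}
    for r in roles:
        if r.role == "curve":
            curves.setdefault(r.curve_id, []).append(r.order_in_curve)
    for cid, orders in curves.items():
        if sorted(orders) != list(range(len(orders))):
            raise ValidationError(
                f"curve {cid}: orders must be consecutive from 0, got {sorted(orders)}"
            )


def _validate_pairing(
    pairing: Iterable[tuple[int, int]], midline: Iterable[int], k: int
) -> None:
    seen: set[int] = set()
    for left, right in pairing:
        if left == right:
            raise ValidationError(f"pairing is irreflexive, got ({left},{right})")
        for i in (left, right):
            if not 0 <= i < k:
                raise ValidationError(f"pairing index {i} out of range")
            if i in seen:
                raise ValidationError(f"point {i} appears twice in pairing/midline")
            seen.add(i)
    for i in midline:
        if not 0 <= i < k:
            raise ValidationError(f"midline index {i} out of range")
        if i in seen:
            raise ValidationError(f"point {i} appears twice in pairing/midline")
        seen.add(i)
    if seen and seen != set(range(k)):
        missing = sorted(set(range(k)) - seen)
        raise ValidationError(f"points {missing[:5]}... missing from pairing/midline")


def _normalize_factors(factors: pd.DataFrame, specimen_ids: Sequence[str]) -> pd.DataFrame:
    f = factors.copy()
    if "specimen" in f.columns:
        f = f.set_index("specimen")
    f.index = f.index.astype(str)
    if f.index.has_duplicates:
        raise ValidationError("duplicate specimen id in factor table")
    missing = set(specimen_ids) - set(f.index)
    if missing:
        raise ValidationError(f"factor table missing specimens: {sorted(missing)[:5]}")
    for col in FACTOR_COLUMNS:
        if col not in f.columns:
            f[col] = pd.NA
    extra = [c for c in f.columns if c not in FACTOR_COLUMNS]
    return f.loc[list(specimen_ids), list(FACTOR_COLUMNS) + extra]


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path, scale_unit: str | None = None) -> Mesh:
    """Read a PLY or OBJ triangle mesh.

    Degenerate (zero-area) triangles are dropped after loading.  If no
    unit is given the coordinates are assumed to be micrometres and a
    warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # trimesh raises a zoo of types
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValidationError(f"{path}: empty geometry")
        tm = geoms[0]
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=int)
    if vertices.size == 0 or faces.size == 0:
        raise ValidationError(f"{path}: empty geometry")
    if scale_unit is None:
        logger.warning("%s: no unit metadata, assuming micrometres", path)
        scale_unit = "um"
    return Mesh(vertices, faces, scale_unit).drop_degenerate_faces()


def write_mesh(mesh: Mesh, path: str | Path) -> None:
    """Write a mesh as PLY (ascii or binary little-endian) or OBJ by extension."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data)
    elif suffix == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(tm, include_texture=False))
    else:
        raise FormatError(f"unsupported mesh format: {suffix}")


def scale_mesh(mesh: Mesh, measured_length: float, model_length: float) -> Mesh:
    """Rescale a mesh so a known anatomical length matches its measured value.

    All vertices are multiplied by ``measured_length / model_length``, so
    every Euclidean inter-vertex distance scales by exactly that ratio.
    """
    if measured_length <= 0 or model_length <= 0:
        raise ValidationError("lengths must be positive")
    factor = measured_length / model_length
    return Mesh(mesh.vertices * factor, mesh.faces.copy(), mesh.scale_unit)


# ---------------------------------------------------------------------------
# landmark I/O: long-format CSV + sidecar YAML
# ---------------------------------------------------------------------------


def write_landmarks(
    sample: LandmarkSample,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
    factors_path: str | Path | None = None,
) -> None:
    """Write a sample in the long-format CSV dialect (plus sidecar YAML).

    The CSV has header ``specimen,point,x,y,z`` (no ``z`` column in 2D)
    with specimens in sample order and points in index order, which makes
    the output deterministic and diffable.
    """
    n, k, d = sample.coords.shape
    cols = ["x", "y", "z"][:d]
    rows = []
    for i, sid in enumerate(sample.specimen_ids):
        for j in range(k):
            rows.append([sid, j, *sample.coords[i, j]])
    df = pd.DataFrame(rows, columns=["specimen", "point", *cols])
    df.to_csv(csv_path, index=False, float_format="%.12g")
    if sidecar_path is not None:
        payload: dict = {}
        if sample.roles:
            payload["roles"] = [
                {"role": r.role}
                | (
                    {"curve_id": int(r.curve_id), "order_in_curve": int(r.order_in_curve)}
                    if r.role == "curve"
                    else {}
                )
                for r in sample.roles
            ]
        payload["pairing"] = {
            "pairs": [[int(a), int(b)] for a, b in sample.pairing],
            "midline": [int(i) for i in sample.midline],
        }
        Path(sidecar_path).write_text(yaml.safe_dump(payload, sort_keys=False))
    if factors_path is not None and sample.factors is not None:
        sample.factors.rename_axis("specimen").to_csv(factors_path)


def read_landmarks(
    paths: str | Path | Sequence[str | Path],
    dialect: str = "csv",
    sidecar: str | Path | None = None,
    factors: str | Path | None = None,
) -> LandmarkSample:
    """Read landmark configurations from CSV (long format) or TPS files.

    Parameters
    ----------
    paths : one path or a sequence of paths
        For ``csv``: one long-format file or several (concatenated).
        For ``tps``: files of ``LM=``/``LM3=`` records.
    sidecar : optional YAML with point roles and symmetry pairing.
    factors : optional CSV factor table (``specimen`` column + factors).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if dialect == "csv":
        frames = [pd.read_csv(p) for p in paths]
        df = pd.concat(frames, ignore_index=True)
        sample = _sample_from_long(df)
    elif dialect == "tps":
        configs: list[tuple[str, np.ndarray]] = []
        for p in paths:
            configs.extend(_parse_tps(Path(p)))
        ids = [c[0] for c in configs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate specimen id across TPS records")
        ks = {c[1].shape for c in configs}
        if len(ks) > 1:
            raise ValidationError(f"inconsistent point counts across specimens: {ks}")
        sample = LandmarkSample(np.stack([c[1] for c in configs]), ids)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    if sidecar is not None:
        roles, pairing, midline = _parse_sidecar(Path(sidecar))
        sample = LandmarkSample(
            sample.coords, sample.specimen_ids, roles, pairing, midline, sample.factors
        )
    if factors is not None:
        table = pd.read_csv(factors)
        sample = LandmarkSample(
            sample.coords, sample.specimen_ids, sample.roles,
            sample.pairing, sample.midline, table,
        )
    return sample


def _sample_from_long(df: pd.DataFrame) -> LandmarkSample:
    required = {"specimen", "point", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"landmark CSV needs columns {sorted(required)}")
    cols = ["x", "y", "z"] if "z" in df.columns else ["x", "y"]
    # keyed by specimen id so input row order does not matter
    ids = sorted(df["specimen"].astype(str).unique())
    grouped = df.assign(specimen=df["specimen"].astype(str)).groupby("specimen")
    ks = {len(g) for _, g in grouped}
    if len(ks) > 1:
        raise ValidationError(f"specimens differ in point count: {sorted(ks)}")
    k = ks.pop()
    coords = np.empty((len(ids), k, len(cols)))
    for i, sid in enumerate(ids):
        g = grouped.get_group(sid).sort_values("point")
        if list(g["point"]) != list(range(k)):
            raise ValidationError(f"specimen {sid}: point indices not 0..{k - 1}")
        coords[i] = g[cols].to_numpy(dtype=float)
    return LandmarkSample(coords, ids)


def _parse_sidecar(path: Path):
    payload = yaml.safe_load(path.read_text()) or {}
    roles = [
        PointRole(
            r["role"],
            r.get("curve_id"),
            r.get("order_in_curve"),
        )
        for r in payload.get("roles", [])
    ]
    pairing_block = payload.get("pairing", {})
    pairs = [tuple(int(v) for v in p) for p in pairing_block.get("pairs", [])]
    midline = [int(i) for i in pairing_block.get("midline", [])]
    return roles, pairs, midline


def _parse_tps(path: Path) -> list[tuple[str, np.ndarray]]:
    """Parse LM=/LM3= records from a TPS file.

    IMAGE= lines name the specimen (falling back to ID= or a counter);
    SCALE= is noted but not applied — rescaling is handled explicitly by
    :func:`scale_mesh` and its landmark analogues.
    """
    configs: list[tuple[str, np.ndarray]] = []
    lines = path.read_text().splitlines()
    i, counter = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        up = line.upper()
        if up.startswith("LM3=") or up.startswith("LM="):
            k = int(line.split("=", 1)[1])
            d = 3 if up.startswith("LM3=") else 2
            pts = []
            i += 1
            while len(pts) < k:
                if i >= len(lines):
                    raise FormatError(f"{path}: truncated TPS record")
                vals = lines[i].split()
                if len(vals) != d:
                    raise FormatError(f"{path}: expected {d} coordinates per row")
                pts.append([float(v) for v in vals])
                i += 1
            name = f"tps_{counter}"
            # trailing metadata until next LM record
            while i < len(lines) and not lines[i].strip().upper().startswith(("LM=", "LM3=")):
                meta = lines[i].strip()
                if meta.upper().startswith("ID="):
                    name = meta.split("=", 1)[1].strip() or name
                elif meta.upper().startswith("IMAGE="):
                    name = Path(meta.split("=", 1)[1].strip()).stem or name
                elif meta.upper().startswith("SCALE="):
                    logger.info("%s: SCALE record ignored (apply scaling explicitly)", path)
                i += 1
            configs.append((name, np.asarray(pts)))
            counter += 1
        else:
            i += 1
    if not configs:
        raise FormatError(f"{path}: no LM=/LM3= records found")
    return configs
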