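"""Readers and writers for STL meshes, point/landmark tables, transforms,
and region-label sidecars.

STL carries no region information, so labels live in a JSON sidecar mapping
region names to inclusive face-index ranges.  All tabular formats are
tab-separated text with a header row; coordinates are millimetres in the
scanner frame and are read as-is (no RAS/LPS conversion).  Readers reject
malformed input with a diagnostic naming the offending line rather than
coercing it.
"""

from __future__ import annotations

import io as _stdio
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .exceptions import MeshFormatError, ValidationError
from .geometry import PointSet, RigidTransform

__all__ = [
    "TriMesh",
    "read_stl", "write_stl",
    "read_labels", "write_labels",
    "read_points", "write_points",
    "read_landmarks", "write_landmarks",
    "read_transform", "write_transform",
    "read_deviation_table", "write_deviation_table",
]

#: Vertices closer than this (mm) are merged on STL read.
VERTEX_MERGE_TOL = 1e-6


@dataclass
class TriMesh:
    """Labeled triangle mesh: vertices (N, 3) mm, faces (M, 3) indices,
    optional region name per face."""

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("mesh vertices contain NaN/Inf")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of vertex range")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, dtype=object)
            if len(self.face_labels) != len(self.faces):
                raise ValidationError(
                    f"{len(self.face_labels)} labels for {len(self.faces)} faces"
                )

    # -- region access -----------------------------------------------------

    def labels(self) -> list[str]:
        if self.face_labels is None:
            return []
        return sorted(set(self.face_labels))

    def region_faces(self, label: str) -> np.ndarray:
        if self.face_labels is None:
            raise ValidationError("mesh has no face labels")
        mask = self.face_labels == label
        if not mask.any():
            raise ValidationError(
                f"region {label!r} not found; available: {self.labels()}")
        return self.faces[mask]

    def region_vertex_indices(self, label: str) -> np.ndarray:
        return np.unique(self.region_faces(label))

    def region_vertices(self, label: str) -> np.ndarray:
        return self.vertices[self.region_vertex_indices(label)]

    def submesh(self, label: str) -> "TriMesh":
        """Extract a region as a standalone mesh (vertices reindexed)."""
        faces = self.region_faces(label)
        idx = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        return TriMesh(self.vertices[idx], remap[faces],
                       np.full(len(faces), label, dtype=object))

    def transformed(self, t: RigidTransform,
                    region: str | None = None) -> "TriMesh":
        """Copy with all vertices — or only a region's vertices — moved by *t*."""
        v = self.vertices.copy()
        if region is None:
            v = t.apply(v)
        else:
            idx = self.region_vertex_indices(region)
            v[idx] = t.apply(v[idx])
        return TriMesh(v, self.faces.copy(),
                       None if self.face_labels is None else self.face_labels.copy())

    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                                process=False)


# ---------------------------------------------------------------------------
# STL


def _merge_vertices(vertices: np.ndarray, faces: np.ndarray,
                    tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices within *tol* by snapping to a grid (STL stores each
    facet's vertices independently)."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    return vertices[first], inverse[faces]


def read_stl(path, *, merge_tol: float = VERTEX_MERGE_TOL) -> TriMesh:
    """Read a binary or ASCII STL file into a :class:`TriMesh`.

    Duplicate per-facet vertices are merged with tolerance *merge_tol* mm.
    Truncated files, inconsistent facet counts and non-STL content raise
    :class:`MeshFormatError` with distinct diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    raw = path.read_bytes()
    if len(raw) < 15:
        raise MeshFormatError(f"{path}: too short to be an STL file")
    is_ascii = raw.lstrip()[:5] == b"solid" and b"facet" in raw[:2048]
    if not is_ascii:
        if len(raw) < 84:
            raise MeshFormatError(f"{path}: truncated binary STL header")
        (n_facets,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * n_facets
        if len(raw) < expected:
            raise MeshFormatError(
                f"{path}: truncated binary STL "
                f"(header declares {n_facets} facets, needs {expected} bytes, "
                f"file has {len(raw)})")
    try:
        mesh = _trimesh.load(_stdio.BytesIO(raw), file_type="stl",
                             process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"{path}: not parseable as STL ({exc})") from exc
    if not isinstance(mesh, _trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path}: no triangles found (not STL content?)")
    v, f = _merge_vertices(np.asarray(mesh.vertices, dtype=float),
                           np.asarray(mesh.faces, dtype=np.int64), merge_tol)
    return TriMesh(v, f)


def write_stl(mesh: TriMesh, path, dialect: str = "binary") -> None:
    """Write *mesh* as binary or ASCII STL (labels go to a sidecar, not STL)."""
    if dialect not in ("binary", "ascii"):
        raise ValidationError(f"unknown STL dialect {dialect!r}")
    tm = mesh.as_trimesh()
    data = tm.export(file_type="stl" if dialect == "binary" else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# Region-label sidecars


def write_labels(mesh: TriMesh, path) -> None:
    """Write face labels as JSON {region: [[start, stop], ...]} inclusive
    face-index ranges."""
    if mesh.face_labels is None:
        raise ValidationError("mesh has no labels to write")
    out: dict[str, list[list[int]]] = {}
    for label in mesh.labels():
        idx = np.flatnonzero(mesh.face_labels == label)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks, [len(idx) - 1]))
        out[label] = [[int(idx[a]), int(idx[b])] for a, b in zip(starts, stops)]
    Path(path).write_text(json.dumps({"face_ranges": out}, indent=1) + "\n")


def read_labels(path, n_faces: int) -> np.ndarray:
    """Read a label sidecar back into a per-face label array; the ranges must
    cover all *n_faces* faces exactly once."""
    try:
        doc = json.loads(Path(path).read_text())
        ranges = doc["face_ranges"]
    except (json.JSONDecodeError, KeyError, OSError) as exc:
        raise ValidationError(f"{path}: not a label sidecar ({exc})") from exc
    labels = np.full(n_faces, None, dtype=object)
    for name, spans in ranges.items():
        for a, b in spans:
            if not (0 <= a <= b < n_faces):
                raise ValidationError(
                    f"{path}: face range [{a}, {b}] outside 0..{n_faces - 1}")
            if (labels[a:b + 1] != None).any():  # noqa: E711 - elementwise
                raise ValidationError(f"{path}: overlapping label ranges")
            labels[a:b + 1] = name
    if (labels == None).any():  # noqa: E711
        raise ValidationError(f"{path}: labels do not cover all faces")
    return labels


# ---------------------------------------------------------------------------
# Tabular text


def _parse_table(path, columns: list[str]) -> list[list[str]]:
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ValidationError(f"cannot read {path}: {exc}") from exc
    rows = [(i, ln) for i, ln in enumerate(lines, start=1)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise ValidationError(f"{path}: empty table")
    header = rows[0][1].split("\t")
    if [h.strip() for h in header] != columns:
        raise ValidationError(
            f"{path}: line {rows[0][0]}: expected header "
            f"{chr(9).join(columns)!r}, got {rows[0][1]!r}")
    parsed = []
    for lineno, ln in rows[1:]:
        fields = ln.split("\t")
        if len(fields) != len(columns):
            raise ValidationError(
                f"{path}: line {lineno}: expected {len(columns)} fields, "
                f"got {len(fields)}")
        parsed.append(fields)
    return parsed


def _floats(fields: list[str], path, label: str) -> list[float]:
    try:
        vals = [float(x) for x in fields]
    except ValueError as exc:
        raise ValidationError(f"{path}: {label}: non-numeric value ({exc})") from exc
    if not all(np.isfinite(vals)):
        raise ValidationError(f"{path}: {label}: non-finite value")
    return vals


def read_points(path) -> PointSet:
    """Read a named point table (columns name, x, y, z; mm)."""
    rows = _parse_table(path, ["name", "x", "y", "z"])
    names = [r[0] for r in rows]
    coords = [_floats(r[1:], path, f"point {r[0]!r}") for r in rows]
    return PointSet(np.array(coords).reshape(-1, 3), names=names)


def write_points(points: PointSet, path) -> None:
    names = points.names or [f"p{i}" for i in range(len(points))]
    with open(path, "w") as fh:
        fh.write("name\tx\ty\tz\n")
        for name, (x, y, z) in zip(names, points.coordinates):
            fh.write(f"{name}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


def read_landmarks(path) -> tuple[PointSet, PointSet]:
    """Read paired landmarks (columns name, xs, ys, zs, xt, yt, zt) as
    (source, target) point sets."""
    rows = _parse_table(path, ["name", "xs", "ys", "zs", "xt", "yt", "zt"])
    names = [r[0] for r in rows]
    vals = np.array([_floats(r[1:], path, f"landmark {r[0]!r}") for r in rows])
    vals = vals.reshape(-1, 6)
    return (PointSet(vals[:, :3], names=names), PointSet(vals[:, 3:], names=names))


def write_landmarks(source: PointSet, target: PointSet, path) -> None:
    if len(source) != len(target):
        raise ValidationError("source and target landmark counts differ")
    names = source.names or [f"lm{i}" for i in range(len(source))]
    with open(path, "w") as fh:
        fh.write("name\txs\tys\tzs\txt\tyt\tzt\n")
        for name, s, t in zip(names, source.coordinates, target.coordinates):
            fh.write(name + "\t" + "\t".join(f"{v:.17g}" for v in (*s, *t)) + "\n")


def read_transform(path) -> RigidTransform:
    """Read a plain-text 4x4 transform (4 rows of 4 floats); validates
    rigidity on read."""
    path = Path(path)
    try:
        m = np.loadtxt(path, dtype=float)
    except (OSError, ValueError) as exc:
        raise ValidationError(f"{path}: not a numeric matrix ({exc})") from exc
    if m.shape != (4, 4):
        raise ValidationError(f"{path}: expected 4 rows x 4 columns, got {m.shape}")
    return RigidTransform(m)


def write_transform(t: RigidTransform, path) -> None:
    np.savetxt(path, t.matrix, fmt="%.17g")


def read_deviation_table(path) -> pd.DataFrame:
    """Read a drilling-deviation table (columns site, hole, deviation_mm)."""
    rows = _parse_table(path, ["site", "hole", "deviation_mm"])
    recs = []
    for site, hole, dev in rows:
        (d,) = _floats([dev], path, f"site {site} hole {hole}")
        if d < 0:
            raise ValidationError(f"{path}: negative deviation for site {site}")
        try:
            recs.append((int(site), int(hole), d))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: site/hole must be integers ({exc})") from exc
    return pd.DataFrame(recs, columns=["site", "hole", "deviation_mm"])


def write_deviation_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("site\thole\tdeviation_mm\n")
        for _, r in table.iterrows():
            fh.write(f"{int(r.site)}\t{int(r.hole)}\t{r.deviation_mm:.17g}\n")
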