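"""Triangular mesh and landmark I/O, and linearized shape-vector conversion.

Meshes are stored as OBJ (``v``/``f`` records) or PLY (ascii or binary
little-endian, via :mod:`trimesh`).  Landmarks live in a sidecar text file with
the same basename and extension ``.lnd``, one ``name x y z`` record per line —
format-independent and diff-friendly.

Vertex ordering is authoritative: the numerics downstream are point-based, so
faces are carried along for rendering/export but never consulted.  A registered
shape is the row-major linearization ``[x1, y1, z1, ..., xm, ym, zm]`` of the
``m`` vertices, in millimetres.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "RegisteredShape",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "linearize",
    "delinearize",
]


class MeshParseError(ValueError):
    """Raised when a mesh or landmark file cannot be parsed."""


@dataclass
class TriMesh:
    """A triangular surface mesh with optional named landmarks.

    Parameters
    ----------
    vertices : (m, 3) float array
        Vertex coordinates in millimetres.
    faces : (nf, 3) int array
        0-based vertex index triplets.  May be empty (point cloud).
    landmarks : dict mapping name -> (3,) float array, optional
        Named anatomical points (e.g. ``"nose_tip"``); insertion-ordered.
    subject_id, label : str, optional
        Provenance metadata (subject identity; AU / expression / neutral tag).
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    landmarks: dict | None = None
    subject_id: str | None = None
    label: str | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (m, 3), got {self.vertices.shape}")
        if self.vertices.shape[0] == 0:
            raise ValueError("mesh has an empty vertex set")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices contain NaN or Inf")
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        m = self.vertices.shape[0]
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= m):
            raise ValueError(
                f"face index out of range: valid indices are [0, {m}), "
                f"got [{self.faces.min()}, {self.faces.max()}]"
            )
        if self.landmarks is not None:
            self.landmarks = {
                str(k): np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.landmarks.items()
            }

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.landmarks is None else {k: v.copy() for k, v in self.landmarks.items()},
            self.subject_id,
            self.label,
        )


@dataclass
class RegisteredShape:
    """A shape vector on a common template topology.

    ``vector`` has length ``3m`` with layout ``[x1, y1, z1, ..., xm, ym, zm]``.
    Two registered shapes are combinable only when ``topology_id`` matches.
    """

    vector: np.ndarray
    topology_id: str

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if self.vector.size % 3 != 0:
            raise ValueError(f"shape vector length {self.vector.size} not divisible by 3")

    @property
    def n_vertices(self) -> int:
        return self.vector.size // 3

    @property
    def points(self) -> np.ndarray:
        """The (m, 3) point-matrix view of the vector."""
        return self.vector.reshape(-1, 3)

    def require_same_topology(self, other: "RegisteredShape") -> None:
        if self.topology_id != other.topology_id:
            raise ValueError(
                f"topology mismatch: {self.topology_id!r} vs {other.topology_id!r}"
            )


def linearize(mesh: TriMesh, topology_id: str) -> RegisteredShape:
    """Flatten a mesh's vertices into a registered shape vector."""
    return RegisteredShape(mesh.vertices.reshape(-1), topology_id)


def delinearize(shape: RegisteredShape | np.ndarray, faces: np.ndarray | None = None, **meta) -> TriMesh:
    """Rebuild a :class:`TriMesh` from a shape vector (inverse of :func:`linearize`)."""
    vec = shape.vector if isinstance(shape, RegisteredShape) else np.asarray(shape, dtype=np.float64)
    verts = vec.reshape(-1, 3)
    if faces is None:
        faces = np.zeros((0, 3), dtype=np.int64)
    return TriMesh(verts, faces, **meta)


# --------------------------------------------------------------------------
# landmark sidecar files

def _lnd_path(path: Path) -> Path:
    return path.with_suffix(".lnd")


def read_landmarks(path) -> dict:
    """Read a ``.lnd`` sidecar: one ``name x y z`` per line; ``#`` comments."""
    path = Path(path)
    landmarks: dict = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MeshParseError(f"{path}:{ln}: expected 'name x y z', got {line!r}")
        name = parts[0]
        if name in landmarks:
            raise MeshParseError(f"{path}:{ln}: duplicate landmark name {name!r}")
        try:
            landmarks[name] = np.array([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise MeshParseError(f"{path}:{ln}: bad coordinate: {exc}") from None
    return landmarks


def write_landmarks(landmarks: dict, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, xyz in landmarks.items():
            fh.write(f"{name} {xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g}\n")


# --------------------------------------------------------------------------
# OBJ — minimal v/f subset, line-accurate errors, strict vertex order

def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts: list = []
    faces: list = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tag, *rest = line.split()
        if tag == "v":
            if len(rest) < 3:
                raise MeshParseError(f"{path}:{ln}: vertex needs 3 coordinates")
            try:
                verts.append([float(v) for v in rest[:3]])
            except ValueError:
                raise MeshParseError(f"{path}:{ln}: bad vertex coordinate in {line!r}") from None
        elif tag == "f":
            if len(rest) != 3:
                raise MeshParseError(f"{path}:{ln}: only triangular faces supported")
            idx = []
            for tok in rest:
                head = tok.split("/")[0]
                try:
                    i = int(head)
                except ValueError:
                    raise MeshParseError(f"{path}:{ln}: bad face index {tok!r}") from None
                if i < 1:
                    raise MeshParseError(f"{path}:{ln}: face indices must be positive (1-based)")
                idx.append(i - 1)
            faces.append(idx)
        # other record types (vn, vt, usemtl, ...) are ignored
    if not verts:
        raise ValueError(f"{path}: no vertices found")
    V = np.asarray(verts, dtype=np.float64)
    F = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if F.size and F.max() >= len(V):
        raise MeshParseError(
            f"{path}: face references vertex {F.max() + 1} but only {len(V)} vertices exist"
        )
    return V, F


def _write_obj(mesh: TriMesh, path: Path) -> None:
    buf = io.StringIO()
    for x, y, z in mesh.vertices:
        buf.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
    for a, b, c in mesh.faces:
        buf.write(f"f {a + 1} {b + 1} {c + 1}\n")
    path.write_text(buf.getvalue())


# --------------------------------------------------------------------------
# public API

_FORMATS = ("obj", "ply")


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = path.suffix.lower().lstrip(".")
    if ext in _FORMATS:
        return ext
    raise ValueError(f"cannot infer mesh format from extension {path.suffix!r}")


def read_mesh(path, format: str = "auto") -> TriMesh:
    """Read an OBJ or PLY mesh; load the ``.lnd`` landmark sidecar if present.

    Raises
    ------
    MeshParseError
        On malformed content (the message names the offending line for OBJ).
    ValueError
        On an empty vertex set or unknown format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "obj":
        verts, faces = _read_obj(path)
    elif fmt == "ply":
        try:
            tm = _trimesh.load(str(path), file_type="ply", process=False)
        except Exception as exc:  # noqa: BLE001 - normalize loader errors
            raise MeshParseError(f"{path}: failed to parse PLY: {exc}") from exc
        verts = np.asarray(tm.vertices, dtype=np.float64)
        faces = np.asarray(getattr(tm, "faces", np.zeros((0, 3))), dtype=np.int64)
        if verts.size == 0:
            raise ValueError(f"{path}: no vertices found")
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    lnd = _lnd_path(path)
    landmarks = read_landmarks(lnd) if lnd.exists() else None
    return TriMesh(verts, faces, landmarks)


def write_mesh(mesh: TriMesh, path, format: str = "auto", ply_encoding: str = "binary") -> None:
    """Write a mesh as OBJ or PLY; emit a ``.lnd`` sidecar when landmarks exist.

    Round-trips through :func:`read_mesh` preserve coordinates to better than
    1e-6 mm (exactly for binary PLY; via %.9g formatting for OBJ/ascii).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not np.all(np.isfinite(mesh.vertices)):
        raise ValueError("refusing to write mesh with non-finite vertices")
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply":
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        data = tm.export(file_type="ply", encoding=ply_encoding)
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    if mesh.landmarks:
        write_landmarks(mesh.landmarks, _lnd_path(path))
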