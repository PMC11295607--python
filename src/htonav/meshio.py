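"""Readers and writers for the formats the toolkit touches.

Surface meshes come and go as STL (ASCII or binary read, ASCII write) or
ASCII PLY; parsing is delegated to :mod:`trimesh` and followed by an exact
(bitwise-equality) vertex weld, so that STL triangle soups with shared edges
collapse to proper shared vertices without any tolerance-based merging.
Landmarks are CSV (``label,x,y,z``, header required, "." decimal separator),
cutting planes and rigid transforms are JSON, result tables are CSV.

Every writer/reader pair is a round-trip identity: geometry to 1e-6 mm,
metadata exactly.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import LandmarkFileError, MeshParseError
from .geometry import CuttingPlane, PointCloud, RigidTransform


@dataclass
class TriangleMesh:
    """A triangle surface mesh: (n, 3) float vertices in mm, (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3 or len(self.vertices) == 0:
            raise ValueError("vertices must be a non-empty (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3 or len(self.faces) == 0:
            raise ValueError("faces must be a non-empty (m, 3) array")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise ValueError("a face repeats a vertex index")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class LandmarkSet:
    """Named anatomical points: ordered mapping label -> (3,) mm coordinates."""

    names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.names = [str(n) for n in self.names]
        if len(self.names) == 0:
            raise ValueError("a landmark set needs at least one entry")
        if len(self.names) != len(self.coords):
            raise ValueError("names and coords must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark labels must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def as_cloud(self) -> PointCloud:
        return PointCloud(self.coords, labels=list(self.names))

    def subset(self, names: list[str]) -> "LandmarkSet":
        idx = {n: i for i, n in enumerate(self.names)}
        return LandmarkSet(list(names), self.coords[[idx[n] for n in names]])


def _weld_exact(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # bitwise-identical coordinates only; deterministic first-occurrence order
    vertices = np.ascontiguousarray(vertices, dtype=float)
    uniq, first, inverse = np.unique(
        vertices.view([("x", float), ("y", float), ("z", float)]).reshape(-1),
        return_index=True,
        return_inverse=True,
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[np.sort(first)], rank[inverse][faces]


def read_mesh(path: str | os.PathLike) -> TriangleMesh:
    """Read an STL (ASCII or binary) or ASCII-PLY mesh; exact-duplicate vertices
    are welded. The format is inferred from the file extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in ("stl", "ply"):
        raise MeshParseError(f"{path}: unsupported mesh extension {ext!r} (use .stl or .ply)")
    try:
        loaded = trimesh.load(path, file_type=ext, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - surface parser detail in our error type
        raise MeshParseError(f"{path}: could not parse {ext.upper()} file: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(verts) == 0 or len(faces) == 0:
        raise MeshParseError(f"{path}: mesh is empty")
    verts, faces = _weld_exact(verts, faces)
    return TriangleMesh(verts, faces)


def write_mesh(mesh: TriangleMesh, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a mesh as ASCII STL or ASCII PLY (``fmt`` inferred from extension
    when omitted). ASCII keeps full float64 precision in both formats."""
    path = os.fspath(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lower().lstrip(".")
    if fmt == "stl":
        text = mesh.as_trimesh().export(file_type="stl_ascii")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif fmt == "ply":
        _write_ply_ascii(mesh, path)
    else:
        raise ValueError(f"unsupported mesh write format {fmt!r} (use 'stl' or 'ply')")


def _write_ply_ascii(mesh: TriangleMesh, path: str) -> None:
    # double-precision properties: trimesh's writer would downcast to float32
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}" for v in mesh.vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read a landmark CSV with exact header ``label,x,y,z``."""
    path = os.fspath(path)
    names: list[str] = []
    coords: list[list[float]] = []
    seen: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["label", "x", "y", "z"]:
            raise LandmarkFileError(f"{path}: header must be 'label,x,y,z', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LandmarkFileError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            label = row[0]
            if label in seen:
                raise LandmarkFileError(
                    f"{path}: duplicate label {label!r} on lines {seen[label]} and {lineno}"
                )
            try:
                xyz = [float(row[1]), float(row[2]), float(row[3])]
            except ValueError as exc:
                raise LandmarkFileError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from exc
            seen[label] = lineno
            names.append(label)
            coords.append(xyz)
    if not names:
        raise LandmarkFileError(f"{path}: no landmarks found")
    return LandmarkSet(names, np.asarray(coords))


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for name, (x, y, z) in zip(landmarks.names, landmarks.coords):
            writer.writerow([name, repr(float(x)), repr(float(y)), repr(float(z))])


def read_planes(path: str | os.PathLike) -> list[CuttingPlane]:
    """Read cutting planes from JSON: a list of
    ``{"origin": [x,y,z], "normal": [x,y,z], "role": "main"|"side"}`` objects.
    Normals within 1e-6 of unit length are re-normalized; others are rejected."""
    with open(os.fspath(path), encoding="utf-8") as fh:
        data = json.load(fh)
    planes = []
    for i, entry in enumerate(data):
        n = np.asarray(entry["normal"], dtype=float)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(
                f"{path}: plane {i}: normal has length {norm:.6g}, not within 1e-6 of 1"
            )
        planes.append(CuttingPlane(np.asarray(entry["origin"], float), n / norm, entry["role"]))
    return planes


def write_planes(planes: list[CuttingPlane], path: str | os.PathLike) -> None:
    data = [
        {
            "origin": [float(v) for v in p.origin],
            "normal": [float(v) for v in p.normal],
            "role": p.role,
        }
        for p in planes
    ]
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def read_transform(path: str | os.PathLike) -> RigidTransform:
    with open(os.fspath(path), encoding="utf-8") as fh:
        return RigidTransform.from_dict(json.load(fh))


def write_transform(
    T: RigidTransform, path: str | os.PathLike, metrics: dict | None = None
) -> None:
    """Write the transform JSON; an optional ``metrics`` block (e.g. fre_mm,
    iterations) is embedded under the ``"metrics"`` key."""
    d = T.to_dict()
    if metrics is not None:
        d["metrics"] = metrics
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")
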