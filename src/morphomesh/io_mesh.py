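"""Mesh export/import: STL (binary + ASCII), OBJ, PLY.

Writers are deterministic (bit-identical output for identical input) and
STL facet normals are written outward-consistent.  Round trips reproduce
vertices within float precision and triangle topology identically.
"""

from __future__ import annotations

import struct

import numpy as np

from .core import TriangleMesh

FORMATS = ("stl_binary", "stl_ascii", "obj", "ply")


def export_mesh(mesh: TriangleMesh, path, fmt: str = "stl_binary") -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; choose from {FORMATS}")
    if fmt == "stl_binary":
        _write_stl_binary(mesh, path)
    elif fmt == "stl_ascii":
        _write_stl_ascii(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        _write_ply(mesh, path)


def import_mesh(path) -> TriangleMesh:
    """Load STL/OBJ/PLY by sniffing the content."""
    with open(path, "rb") as fh:
        head = fh.read(512)
    text_head = head.decode("ascii", errors="replace")
    name = str(path).lower()
    if name.endswith(".obj") or text_head.lstrip().startswith(("v ", "#", "g ")):
        return _read_obj(path)
    if name.endswith(".ply") or text_head.startswith("ply"):
        return _read_ply(path)
    if text_head.lstrip().startswith("solid") and b"facet" in head:
        return _read_stl_ascii(path)
    return _read_stl_binary(path)


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def _facet_normals(mesh: TriangleMesh) -> np.ndarray:
    return mesh.face_normals()


def _write_stl_binary(mesh: TriangleMesh, path) -> None:
    normals = _facet_normals(mesh).astype("<f4")
    tv = mesh.vertices[mesh.triangles].astype("<f4")
    nf = len(mesh.triangles)
    rec = np.zeros(nf, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                              ("attr", "<u2")])
    rec["n"] = normals
    rec["v"] = tv
    with open(path, "wb") as fh:
        fh.write(b"morphomesh".ljust(80, b"\0"))
        fh.write(struct.pack("<I", nf))
        fh.write(rec.tobytes())


def _read_stl_binary(path) -> TriangleMesh:
    with open(path, "rb") as fh:
        fh.read(80)
        (nf,) = struct.unpack("<I", fh.read(4))
        rec = np.frombuffer(fh.read(nf * 50),
                            dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                   ("attr", "<u2")])
    return _weld(rec["v"].reshape(-1, 3).astype(float))


def _write_stl_ascii(mesh: TriangleMesh, path) -> None:
    normals = _facet_normals(mesh)
    tv = mesh.vertices[mesh.triangles]
    with open(path, "w") as fh:
        fh.write("solid morphomesh\n")
        for n, tri in zip(normals, tv):
            fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            fh.write("    outer loop\n")
            for v in tri:
                fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid morphomesh\n")


def _read_stl_ascii(path) -> TriangleMesh:
    pts = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                pts.append([float(parts[1]), float(parts[2]),
                            float(parts[3])])
    return _weld(np.array(pts, dtype=float))


def _weld(flat_vertices: np.ndarray) -> TriangleMesh:
    """Rebuild shared topology from a facet soup by exact-position welding."""
    uniq, inverse = np.unique(flat_vertices, axis=0, return_inverse=True)
    tris = inverse.reshape(-1, 3)
    return TriangleMesh(uniq, tris.astype(np.int64))


# ---------------------------------------------------------------------------
# OBJ / PLY
# ---------------------------------------------------------------------------

def _write_obj(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def _read_obj(path) -> TriangleMesh:
    verts, tris = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                for k in range(1, len(idx) - 1):
                    tris.append([idx[0], idx[k], idx[k + 1]])
    return TriangleMesh(np.array(verts), np.array(tris, dtype=np.int64))


def _write_ply(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_ply(path) -> TriangleMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    nv = nf = 0
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:1] == ["end_header"]:
            break
    body = lines[i + 1:]
    verts = np.array([[float(x) for x in body[k].split()[:3]]
                      for k in range(nv)])
    tris = np.array([[int(x) for x in body[nv + k].split()[1:4]]
                     for k in range(nf)], dtype=np.int64)
    return TriangleMesh(verts, tris)
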