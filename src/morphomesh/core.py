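"""Core domain types: samples, sections, morphologies, triangle meshes, config.

The morphology model follows the de-facto SWC conventions: a neuron is a
forest of radius-tagged 3D samples rooted at the soma.  Chains of segments
between branching points are grouped into :class:`Section` objects; sections
form rooted trees (neurites).  All coordinates are micrometres and column 6
of an SWC file is read as a *radius* (internal fields are radii throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

SOMA_TYPE = 1
AXON_TYPE = 2
BASAL_DENDRITE_TYPE = 3
APICAL_DENDRITE_TYPE = 4
DENDRITE_TYPES = (BASAL_DENDRITE_TYPE, APICAL_DENDRITE_TYPE)


class SWCParseError(ValueError):
    """Raised for malformed SWC rows (message names the offending line)."""


class SWCStructureError(ValueError):
    """Raised for structurally invalid morphologies (cycles, missing soma)."""


@dataclass
class Sample:
    """A single digitized morphology point."""

    id: int
    type_code: int
    position: np.ndarray  # (3,) float64, micrometres
    radius: float  # micrometres
    parent_id: int  # -1 for a root

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("sample position must be a 3-vector")
        if not self.radius > 0:
            raise ValueError(f"sample {self.id}: radius must be > 0")

    def copy(self) -> "Sample":
        return Sample(self.id, self.type_code, self.position.copy(),
                      self.radius, self.parent_id)


@dataclass
class Section:
    """A chain of samples between two branching points (or a terminal)."""

    index: int
    samples: list[Sample]
    parent_section: int | None = None
    child_sections: list[int] = field(default_factory=list)
    branch_order: int = 1
    is_primary: bool = False
    type_code: int = BASAL_DENDRITE_TYPE

    @property
    def points(self) -> np.ndarray:
        return np.array([s.position for s in self.samples], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.samples], dtype=float)

    def length(self) -> float:
        p = self.points
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    def is_root(self) -> bool:
        return self.parent_section is None

    def is_leaf(self) -> bool:
        return not self.child_sections


@dataclass
class Morphology:
    """A neuron: a soma summary plus a forest of section trees."""

    soma_centroid: np.ndarray
    soma_mean_radius: float
    sections: list[Section]
    all_samples: list[Sample]

    def __post_init__(self) -> None:
        self.soma_centroid = np.asarray(self.soma_centroid, dtype=float)
        if not self.soma_mean_radius > 0:
            raise ValueError("soma_mean_radius must be > 0")

    @property
    def neurites(self) -> list[Section]:
        """Root sections, one per neurite."""
        return [s for s in self.sections if s.is_root()]

    def section_tree(self, root: Section) -> list[Section]:
        """All sections of the neurite rooted at *root* (preorder)."""
        out: list[Section] = []
        stack = [root.index]
        while stack:
            sec = self.sections[stack.pop()]
            out.append(sec)
            stack.extend(reversed(sec.child_sections))
        return out

    def copy(self) -> "Morphology":
        return Morphology(
            self.soma_centroid.copy(),
            self.soma_mean_radius,
            [replace(s, samples=[x.copy() for x in s.samples],
                     child_sections=list(s.child_sections))
             for s in self.sections],
            [s.copy() for s in self.all_samples],
        )


@dataclass
class TriangleMesh:
    """An indexed triangle set with vertex positions in micrometres."""

    vertices: np.ndarray  # (n, 3) float64
    triangles: np.ndarray  # (m, 3) int64

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles):
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle index out of range")
            if np.any(self.triangles[:, 0] == self.triangles[:, 1]) or \
               np.any(self.triangles[:, 1] == self.triangles[:, 2]) or \
               np.any(self.triangles[:, 2] == self.triangles[:, 0]):
                raise ValueError("triangle repeats a vertex index")

    # -- connectivity ---------------------------------------------------
    def edges(self) -> np.ndarray:
        """All directed edges as (3m, 2) index pairs."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def edges_sorted_unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected unique edges and their face-incidence counts."""
        e = np.sort(self.edges(), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def euler_characteristic(self) -> int:
        uniq, _ = self.edges_sorted_unique()
        return len(self.vertices) - len(uniq) + len(self.triangles)

    def is_closed(self) -> bool:
        _, counts = self.edges_sorted_unique()
        return bool(np.all(counts == 2))

    # -- geometry -------------------------------------------------------
    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        if normalized:
            lens = np.linalg.norm(n, axis=1)
            lens[lens == 0] = 1.0
            n = n / lens[:, None]
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def translated(self, offset: Sequence[float]) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float),
                            self.triangles.copy())

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.triangles.copy())

    @staticmethod
    def concatenate(meshes: Iterable["TriangleMesh"]) -> "TriangleMesh":
        meshes = list(meshes)
        if not meshes:
            raise ValueError("cannot concatenate an empty mesh list")
        verts, tris, offset = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            tris.append(m.triangles + offset)
            offset += len(m.vertices)
        return TriangleMesh(np.concatenate(verts), np.concatenate(tris))


@dataclass
class MeshingConfig:
    """Every knob of the meshing pipeline in one place."""

    arbor_algorithm: str = "node_to_leaf"  # or "articulated"
    ring_sides: int = 16
    use_spline: bool = True
    soma_initial_radius_factor: float = 0.5
    soma_stiffness: float = 0.1
    soma_steps: int = 100
    spine_density: float = 1.0  # per micrometre of dendrite
    spine_neck_min: float = 0.3  # template bank floor; 0.06 um is resolvable
    spine_neck_max: float = 0.8
    voxel_size_override: float | None = None
    voxel_feature_divisor: float = 2.0
    optimization_target_ratio: float = 0.6
    smoothing_iterations: int = 5
    repair_max_iterations: int = 20
    rng_seed: int = 0
    # implementation plumbing
    voxel_memory_budget: int = 1_500_000_000  # max voxel count (dense bool)
    volume_tolerance: float = 0.02
    keep_largest_component: bool = False

    def __post_init__(self) -> None:
        if self.arbor_algorithm not in ("node_to_leaf", "articulated"):
            raise ValueError(f"unknown arbor_algorithm {self.arbor_algorithm!r}")
        if self.ring_sides < 3:
            raise ValueError("ring_sides must be >= 3")
        for name in ("soma_initial_radius_factor", "soma_stiffness",
                     "voxel_feature_divisor", "optimization_target_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.soma_stiffness <= 1:
            raise ValueError("soma_stiffness must be in (0, 1]")
        if not 0 < self.optimization_target_ratio <= 1:
            raise ValueError("optimization_target_ratio must be in (0, 1]")
        if self.voxel_feature_divisor < 2:
            raise ValueError("voxel_feature_divisor must be >= 2")


# ---------------------------------------------------------------------------
# SWC reading / writing
# ---------------------------------------------------------------------------

def parse_swc_text(text: str) -> list[Sample]:
    """Parse SWC records from *text* (two-pass: forward parents allowed)."""
    samples: list[Sample] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(
                f"line {lineno}: expected 7 whitespace-delimited columns, "
                f"got {len(cols)}")
        try:
            sid = int(cols[0])
            tcode = int(cols[1])
            xyz = [float(cols[2]), float(cols[3]), float(cols[4])]
            radius = float(cols[5])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from None
        if radius <= 0:
            raise SWCParseError(f"line {lineno}: non-positive radius {radius}")
        if sid in seen:
            raise SWCParseError(f"line {lineno}: duplicate sample id {sid}")
        seen.add(sid)
        samples.append(Sample(sid, tcode, np.array(xyz), radius, parent))
    # second pass: referential integrity + acyclicity
    _validate_sample_graph(samples)
    return samples


def _validate_sample_graph(samples: list[Sample]) -> None:
    by_id = {s.id: s for s in samples}
    for s in samples:
        if s.parent_id != -1 and s.parent_id not in by_id:
            raise SWCStructureError(
                f"sample {s.id}: parent {s.parent_id} does not exist")
    state: dict[int, int] = {}  # 0 visiting, 1 done
    for s in samples:
        chain = []
        cur: int | None = s.id
        while cur is not None and cur != -1 and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise SWCStructureError(f"cyclic parent links at sample {cur}")
            state[cur] = 0
            chain.append(cur)
            cur = by_id[cur].parent_id if by_id[cur].parent_id != -1 else None
        for c in chain:
            state[c] = 1


def read_swc(path) -> Morphology:
    """Read an SWC file and build the full section hierarchy.

    All type-1 samples (single-sample, three-point, and contour soma
    dialects alike) are collapsed to a centroid plus mean radius; the
    pipeline re-grows the soma surface from simulation later.
    """
    with open(path) as fh:
        text = fh.read()
    samples = parse_swc_text(text)
    return morphology_from_samples(samples)


def morphology_from_samples(samples: list[Sample]) -> Morphology:
    soma_samples = [s for s in samples if s.type_code == SOMA_TYPE]
    if not soma_samples:
        raise SWCStructureError("no type-1 (soma) sample in morphology")
    centroid = np.mean([s.position for s in soma_samples], axis=0)
    mean_radius = float(np.mean([s.radius for s in soma_samples]))
    sections = build_sections(samples)
    return Morphology(centroid, mean_radius, sections, samples)


def build_sections(samples: list[Sample]) -> list[Section]:
    """Group non-soma samples into sections between branching points.

    Branching samples are *duplicated* as shared endpoints so each section
    owns an independent resamplable point list.  Soma samples never join a
    section.  Branch order is 1 for sections emanating from the soma.
    """
    by_id = {s.id: s for s in samples}
    children: dict[int, list[int]] = {s.id: [] for s in samples}
    roots: list[int] = []
    for s in samples:
        if s.type_code == SOMA_TYPE:
            continue
        parent = by_id.get(s.parent_id)
        if s.parent_id == -1 or parent is None or parent.type_code == SOMA_TYPE:
            roots.append(s.id)
        else:
            children[s.parent_id].append(s.id)
    for v in children.values():
        v.sort()
    roots.sort()

    sections: list[Section] = []

    def walk(first_id: int, parent_sec: int | None, order: int) -> None:
        chain = [by_id[first_id]]
        cur = first_id
        while len(children[cur]) == 1:
            cur = children[cur][0]
            chain.append(by_id[cur])
        if parent_sec is not None:
            # duplicate the branching sample as the shared first endpoint
            chain = [sections[parent_sec].samples[-1].copy()] + chain
        if len(chain) < 2:
            # singleton root twig: drop it (cannot form a segment)
            return
        sec = Section(index=len(sections), samples=chain,
                      parent_section=parent_sec, branch_order=order,
                      type_code=chain[-1].type_code)
        sections.append(sec)
        if parent_sec is not None:
            sections[parent_sec].child_sections.append(sec.index)
        for child in children[cur]:
            walk(child, sec.index, order + 1)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        for r in roots:
            walk(r, None, 1)
    finally:
        sys.setrecursionlimit(old)
    return sections


def write_swc(morphology: Morphology, path) -> None:
    """Write the flat sample table back out (7-column SWC, '#' header)."""
    lines = ["# id type x y z radius parent"]
    for s in morphology.all_samples:
        x, y, z = s.position
        lines.append(f"{s.id} {s.type_code} {x:.6f} {y:.6f} {z:.6f} "
                     f"{s.radius:.6f} {s.parent_id}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def swc_bytes(morphology: Morphology) -> bytes:
    """Deterministic SWC serialization (used for byte-identity checks)."""
    lines = ["# id type x y z radius parent"]
    for s in morphology.all_samples:
        x, y, z = s.position
        lines.append(f"{s.id} {s.type_code} {x:.6f} {y:.6f} {z:.6f} "
                     f"{s.radius:.6f} {s.parent_id}")
    return ("\n".join(lines) + "\n").encode()
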