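"""Parametric dendritic-spine templates and seeded placement sampling.

Templates are head-sphere + neck-frustum lathe composites in a canonical
frame (base disc centred at the origin, axis +Z).  Placements are sampled
uniformly along dendritic arclength with uniform azimuth; each placed spine
is sunk a quarter of the local dendrite radius below the tube surface so
voxel remeshing welds it to the shaft.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .core import DENDRITE_TYPES, Morphology, TriangleMesh

SHAPE_CLASSES = ("stubby", "mushroom", "thin")
MIN_NECK_DIAMETER = 0.06  # µm, finest resolvable spine neck
SINK_FRACTION = 0.25  # of local dendrite radius, below the tube surface
_PROFILE_ARC_STEPS = 32  # axial profile resolution, fixed (azimuthal varies)


@dataclass
class SpineTemplate:
    mesh: TriangleMesh
    length: float
    head_diameter: float
    neck_diameter: float
    shape_class: str


@dataclass
class SpinePlacement:
    section_index: int
    arclength: float
    direction: np.ndarray  # unit outward normal of the dendrite surface
    scale: float
    template_id: int

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("placement direction must be unit-norm")
        if not self.scale > 0:
            raise ValueError("placement scale must be > 0")


def _lathe(profile_r: np.ndarray, profile_z: np.ndarray,
           resolution: int) -> TriangleMesh:
    """Revolve an (r, z) profile about +Z into a closed mesh.

    The profile must start and end at r=0 (poles).  Ring radii are scaled
    so the inscribed polygon matches the circle area, keeping volumes
    faithful at modest azimuthal resolutions.
    """
    n = resolution
    comp = float(np.sqrt(np.pi / (0.5 * n * np.sin(2 * np.pi / n))))
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    interior = [(r, z) for r, z in zip(profile_r, profile_z) if r > 0]
    verts = [np.array([0.0, 0.0, profile_z[0]])]
    for r, z in interior:
        ring = np.stack([comp * r * cos_t, comp * r * sin_t,
                         np.full(n, z)], axis=1)
        verts.append(ring)
    verts.append(np.array([0.0, 0.0, profile_z[-1]]))
    vertices = np.concatenate([v.reshape(-1, 3) for v in verts])

    tris = []
    m = len(interior)
    first_ring = 1
    for j in range(n):
        jn = (j + 1) % n
        tris.append((0, first_ring + jn, first_ring + j))
    for i in range(m - 1):
        a = first_ring + i * n
        b = a + n
        for j in range(n):
            jn = (j + 1) % n
            tris.append((a + j, b + jn, b + j))
            tris.append((a + j, a + jn, b + jn))
    apex = 1 + m * n
    last = first_ring + (m - 1) * n
    for j in range(n):
        jn = (j + 1) % n
        tris.append((apex, last + j, last + jn))
    return TriangleMesh(vertices, np.array(tris, dtype=np.int64))


def make_spine_template(shape_class: str, length: float, head_diameter: float,
                        neck_diameter: float,
                        resolution: int = 16) -> SpineTemplate:
    """Build a closed spine mesh: neck frustum topped by a spherical head.

    The base disc sits at z=0, the tip at z=length, and the widest extent
    equals the head diameter.  ``stubby`` uses head = neck (a capped
    cylinder); ``mushroom`` and ``thin`` bulge into a head sphere.
    """
    if shape_class not in SHAPE_CLASSES:
        raise ValueError(f"unknown shape class {shape_class!r}")
    if min(length, head_diameter, neck_diameter) <= 0:
        raise ValueError("spine dimensions must be positive")
    if neck_diameter < MIN_NECK_DIAMETER:
        raise ValueError(
            f"neck diameter {neck_diameter} below the resolvable floor "
            f"{MIN_NECK_DIAMETER}")
    if shape_class == "mushroom" and neck_diameter > head_diameter:
        raise ValueError("mushroom neck cannot be wider than its head")
    neck_r = neck_diameter / 2.0
    head_r = head_diameter / 2.0

    if shape_class == "stubby" or np.isclose(head_diameter, neck_diameter):
        # cylinder of radius neck_r capped by a hemisphere
        body_h = max(length - neck_r, 0.25 * length)
        zs = [0.0, body_h]
        rs = [neck_r, neck_r]
        ang = np.linspace(0, np.pi / 2, _PROFILE_ARC_STEPS)[1:]
        cap_r = neck_r * np.cos(ang)
        cap_z = body_h + (length - body_h) * np.sin(ang)
        profile_r = np.concatenate([[0.0], rs, cap_r[:-1], [0.0]])
        profile_z = np.concatenate([[0.0], zs, cap_z[:-1], [length]])
    else:
        head_center = length - head_r
        neck_top = max(head_center - head_r * 0.6, 0.3 * length)
        zs = np.linspace(0.0, neck_top, 4)
        rs = np.full(4, neck_r)
        # spherical head arc from the neck junction to the tip pole
        z_on_sphere = np.clip((neck_top - head_center) / head_r, -1.0, 1.0)
        ang0 = np.arcsin(z_on_sphere)
        ang = np.linspace(ang0, np.pi / 2, _PROFILE_ARC_STEPS)[1:]
        arc_r = head_r * np.cos(ang)
        arc_z = head_center + head_r * np.sin(ang)
        profile_r = np.concatenate([[0.0], rs, np.maximum(arc_r[:-1], 1e-6),
                                    [0.0]])
        profile_z = np.concatenate([[0.0], zs, arc_z[:-1], [length]])
    mesh = _lathe(profile_r, profile_z, resolution)
    return SpineTemplate(mesh, length, head_diameter, neck_diameter,
                         shape_class)


def default_templates(rng: np.random.Generator,
                      count: int = 4, resolution: int = 12,
                      neck_range: tuple[float, float] = (MIN_NECK_DIAMETER,
                                                         0.8),
                      length_range: tuple[float, float] = (1.0, 3.0)
                      ) -> list[SpineTemplate]:
    """A deterministic bank of templates spanning the shape classes."""
    templates = []
    classes = ["mushroom", "thin", "stubby"]
    for i in range(count):
        cls = classes[i % len(classes)]
        length = float(rng.uniform(*length_range))
        neck = float(rng.uniform(*neck_range))
        if cls == "stubby":
            head = neck
        else:
            head = float(rng.uniform(max(neck, 0.3), 1.0))
        templates.append(make_spine_template(cls, length, head, neck,
                                             resolution))
    return templates


# ---------------------------------------------------------------------------
# Placement sampling
# ---------------------------------------------------------------------------

def _section_frame(section, arclength: float):
    """(point, radius, tangent) at an arclength position along a section."""
    pts = section.points
    radii = section.radii
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if arclength > cum[-1] + 1e-9:
        raise ValueError(
            f"arclength {arclength} beyond section length {cum[-1]}")
    s = min(arclength, cum[-1])
    i = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0,
                    len(seg) - 1))
    t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    point = pts[i] + t * (pts[i + 1] - pts[i])
    radius = radii[i] + t * (radii[i + 1] - radii[i])
    tangent = (pts[i + 1] - pts[i]) / seg[i]
    return point, float(radius), tangent


def _perpendicular(tangent: np.ndarray, azimuth: float) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangent, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    b1 = np.cross(tangent, ref)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(tangent, b1)
    return np.cos(azimuth) * b1 + np.sin(azimuth) * b2


def sample_spine_placements(morphology: Morphology, density: float,
                            rng_seed: int,
                            n_templates: int = 4) -> list[SpinePlacement]:
    """Sample spine placements on dendritic sections (type codes 3 and 4).

    The count is Poisson with mean ``density * total dendritic arclength``;
    positions are uniform along arclength, azimuths uniform, directions
    perpendicular to the local tangent.  Deterministic per seed.
    """
    if density <= 0:
        return []
    dendrites = [s for s in morphology.sections
                 if s.type_code in DENDRITE_TYPES]
    lengths = np.array([s.length() for s in dendrites])
    total = float(lengths.sum())
    if total <= 0:
        return []
    rng = np.random.default_rng(rng_seed)
    count = int(rng.poisson(density * total))
    placements: list[SpinePlacement] = []
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    for _ in range(count):
        s_global = float(rng.uniform(0.0, total))
        si = int(np.clip(np.searchsorted(cum, s_global, side="right") - 1,
                         0, len(dendrites) - 1))
        sec = dendrites[si]
        s_local = s_global - cum[si]
        _, _, tangent = _section_frame(sec, s_local)
        azimuth = float(rng.uniform(0.0, 2 * np.pi))
        direction = _perpendicular(tangent, azimuth)
        scale = float(rng.uniform(0.8, 1.2))
        template_id = int(rng.integers(0, n_templates))
        placements.append(SpinePlacement(sec.index, s_local, direction,
                                         scale, template_id))
    return placements


def read_placement_csv(path, morphology: Morphology) -> list[SpinePlacement]:
    """Load placements from CSV (section_index, arclength_um, azimuth_deg,
    template_id, scale) for users with real synapse data."""
    placements = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            sec = morphology.sections[int(row["section_index"])]
            s = float(row["arclength_um"])
            _, _, tangent = _section_frame(sec, s)
            direction = _perpendicular(tangent,
                                       np.radians(float(row["azimuth_deg"])))
            placements.append(SpinePlacement(sec.index, s, direction,
                                             float(row["scale"]),
                                             int(row["template_id"])))
    return placements


def _rotation_to(z_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +Z to the unit vector *z_to* (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, z_to))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, z_to)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def place_spine(template: SpineTemplate, placement: SpinePlacement,
                morphology: Morphology) -> TriangleMesh:
    """Transform a template onto the dendrite with guaranteed overlap.

    The template is rotated so +Z aligns with the placement direction,
    scaled, and translated so its base sits ``SINK_FRACTION`` of the local
    dendrite radius *below* the dendrite surface.
    """
    sec = morphology.sections[placement.section_index]
    point, radius, _ = _section_frame(sec, placement.arclength)
    rot = _rotation_to(placement.direction)
    verts = (placement.scale * template.mesh.vertices) @ rot.T
    base = point + placement.direction * (radius * (1.0 - SINK_FRACTION))
    return TriangleMesh(verts + base, template.mesh.triangles.copy())


def build_spine_assembly(morphology: Morphology,
                         placements: list[SpinePlacement],
                         templates: list[SpineTemplate]
                         ) -> list[TriangleMesh]:
    return [place_spine(templates[p.template_id % len(templates)], p,
                        morphology) for p in placements]


def min_neck_diameter(placements: list[SpinePlacement],
                      templates: list[SpineTemplate]) -> float | None:
    """Finest placed spine neck (diameter × scale), or None without spines."""
    if not placements:
        return None
    return min(templates[p.template_id % len(templates)].neck_diameter
               * p.scale for p in placements)
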