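"""Soft-body somatic profile: mass-spring growth of an icosphere.

The soma surface starts as an icosphere at a fraction of the reported soma
radius and is pulled toward the first sample of every connected arbor while
Hooke springs on the icosphere edges resist deformation.  Integration is
damped explicit Euler with unit vertex masses, which is deterministic and
stable at these scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arbors import icosphere
from .core import Morphology, MeshingConfig, TriangleMesh
from .preprocess import verify_soma_connectivity

DEFAULT_DT = 0.1
DEFAULT_DAMPING = 0.9
DEFAULT_PULL_STRENGTH = 0.1
DEFAULT_ANCHOR_FRACTION = 0.05  # goal-spring strength as a stiffness fraction


class SomaDivergenceError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


@dataclass
class PullTarget:
    vertex_indices: np.ndarray  # indices into the network positions
    target: np.ndarray  # (3,)
    target_radius: float


@dataclass
class SpringNetwork:
    positions: np.ndarray  # (n, 3)
    velocities: np.ndarray  # (n, 3)
    edges: np.ndarray  # (e, 2) int
    rest_lengths: np.ndarray  # (e,)
    triangles: np.ndarray  # (f, 3) surface connectivity, carried through
    stiffness: float
    damping: float = DEFAULT_DAMPING
    pull_targets: list[PullTarget] = field(default_factory=list)
    pull_strength: float = DEFAULT_PULL_STRENGTH
    rest_positions: np.ndarray | None = None  # goal anchors (initial shape)

    def __post_init__(self) -> None:
        if np.any(self.rest_lengths <= 0):
            raise ValueError("rest lengths must be > 0")
        if not 0 < self.stiffness <= 1:
            raise ValueError("stiffness must be in (0, 1]")


def init_soma_network(morphology: Morphology,
                      config: MeshingConfig) -> SpringNetwork:
    """Build the spring network seeded from a subdivision-3 icosphere.

    One pull target per *connected* arbor: the icosphere vertices inside
    the cone subtended by the arbor's initial cross-section (half-angle
    ``atan(root_radius / distance)``), targeted at the root sample.  Cone
    membership conflicts resolve to the angularly closest arbor so target
    sets stay disjoint; an arbor whose cone catches no vertex gets the
    single closest vertex instead.
    """
    r0 = config.soma_initial_radius_factor * morphology.soma_mean_radius
    sphere = icosphere(morphology.soma_centroid, r0, 3)
    pos = sphere.vertices.copy()
    edges, _ = sphere.edges_sorted_unique()
    rest = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)

    report = verify_soma_connectivity(morphology)
    connected = [morphology.neurites[i] for i, ok in report.arbors_connected
                 if ok]

    radial = pos - morphology.soma_centroid
    radial_u = radial / np.linalg.norm(radial, axis=1)[:, None]

    dirs, half_angles, targets, radii = [], [], [], []
    for root in connected:
        root_pos = root.samples[0].position
        d = root_pos - morphology.soma_centroid
        dist = np.linalg.norm(d)
        if dist < 1e-9:
            continue
        dirs.append(d / dist)
        half_angles.append(np.arctan2(root.samples[0].radius, dist))
        targets.append(root_pos)
        radii.append(root.samples[0].radius)

    pulls: list[PullTarget] = []
    if dirs:
        dirs_arr = np.array(dirs)
        angles = np.arccos(np.clip(radial_u @ dirs_arr.T, -1.0, 1.0))
        owner = np.argmin(angles, axis=1)
        for k in range(len(dirs)):
            mask = (owner == k) & (angles[:, k] <= half_angles[k])
            idx = np.nonzero(mask)[0]
            if len(idx) == 0:
                idx = np.array([int(np.argmin(angles[:, k]))])
            pulls.append(PullTarget(idx, np.asarray(targets[k], float),
                                    float(radii[k])))
        # enforce disjointness against the nearest-vertex fallback
        seen: set[int] = set()
        for p in pulls:
            p.vertex_indices = np.array(
                [i for i in p.vertex_indices if i not in seen], dtype=int)
            seen.update(int(i) for i in p.vertex_indices)
        pulls = [p for p in pulls if len(p.vertex_indices)]

    return SpringNetwork(pos, np.zeros_like(pos), edges, rest,
                         sphere.triangles.copy(), config.soma_stiffness,
                         DEFAULT_DAMPING, pulls, DEFAULT_PULL_STRENGTH,
                         pos.copy())


def simulate(network: SpringNetwork, steps: int,
             dt: float = DEFAULT_DT) -> TriangleMesh:
    """Run damped explicit Euler for *steps* and return the surface.

    Per step each pulled vertex receives ``pull_strength * (target -
    position)`` (a fixed growth force, decoupled from the edge springs so
    that stiffer somata deform less); every edge exerts a Hooke force
    ``stiffness * (rest - length)``; velocities are damped
    multiplicatively.  Weak goal springs (``DEFAULT_ANCHOR_FRACTION x
    stiffness``) anchor every vertex to its rest position, so stiffer
    somata deform less under the same growth pull.  ``steps=0`` returns
    the icosphere unchanged; with no pull targets the network stays at
    rest.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    pos = network.positions.copy()
    vel = network.velocities.copy()
    e0, e1 = network.edges[:, 0], network.edges[:, 1]
    k = network.stiffness
    for _ in range(steps):
        force = np.zeros_like(pos)
        d = pos[e1] - pos[e0]
        lengths = np.linalg.norm(d, axis=1)
        lengths[lengths == 0] = 1e-12
        # spring force magnitude k*(rest-len) along edge, on both endpoints
        f = (k * (network.rest_lengths - lengths) / lengths)[:, None] * d
        np.subtract.at(force, e0, f)
        np.add.at(force, e1, f)
        if network.rest_positions is not None:
            force += DEFAULT_ANCHOR_FRACTION * k * (network.rest_positions
                                                    - pos)
        for p in network.pull_targets:
            force[p.vertex_indices] += network.pull_strength * (
                p.target - pos[p.vertex_indices])
        vel = (vel + dt * force) * network.damping
        pos = pos + dt * vel
        if not np.all(np.isfinite(pos)):
            raise SomaDivergenceError(
                "soft-body integration diverged; retry with a smaller dt")
    return TriangleMesh(pos, network.triangles.copy())


def build_soma_mesh(morphology: Morphology,
                    config: MeshingConfig) -> TriangleMesh:
    """Convenience wrapper: init network and simulate with config knobs."""
    net = init_soma_network(morphology, config)
    return simulate(net, config.soma_steps)
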