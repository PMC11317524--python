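import numpy as np
import pytest

from morphomesh.arbors import icosphere
from morphomesh.core import TriangleMesh
from morphomesh.quality import (OpenMeshError, check_watertight,
                                edge_counts, enclosed_volume,
                                face_components, nonmanifold_vertices,
                                self_intersections, verdict_metrics)

from conftest import make_cube


# ---------------------------------------------------------------------------
# Independent oracles (deliberately different formulations from the library)
# ---------------------------------------------------------------------------

def _seg_tri_cross(p0, p1, a, b, c, eps=1e-12):
    """Does segment p0-p1 properly cross triangle abc (interior crossing)?"""
    n = np.cross(b - a, c - a)
    d0 = np.dot(n, p0 - a)
    d1 = np.dot(n, p1 - a)
    if d0 * d1 >= -eps * abs(np.dot(n, n)):
        return False
    t = d0 / (d0 - d1)
    x = p0 + t * (p1 - p0)
    # barycentric interior test
    v0, v1, v2 = c - a, b - a, x - a
    dot00, dot01, dot02 = v0 @ v0, v0 @ v1, v0 @ v2
    dot11, dot12 = v1 @ v1, v1 @ v2
    denom = dot00 * dot11 - dot01 * dot01
    if abs(denom) < eps:
        return False
    u = (dot11 * dot02 - dot01 * dot12) / denom
    v = (dot00 * dot12 - dot01 * dot02) / denom
    return u > eps and v > eps and u + v < 1 - eps


def oracle_tri_tri(t1, t2):
    """Brute-force proper-intersection test via edge/triangle crossings."""
    for i in range(3):
        if _seg_tri_cross(t1[i], t1[(i + 1) % 3], *t2):
            return True
        if _seg_tri_cross(t2[i], t2[(i + 1) % 3], *t1):
            return True
    return False


def oracle_self_intersections(mesh):
    """All-pairs oracle; excludes index-sharing pairs like the library."""
    t = mesh.triangles
    v = mesh.vertices
    out = set()
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if set(t[i]) & set(t[j]):
                continue
            if oracle_tri_tri(v[t[i]], v[t[j]]):
                out.add((i, j))
    return out


def oracle_nonmanifold_edges(mesh):
    """Adjacency-dict oracle for edge incidence counts."""
    counts = {}
    for tri in mesh.triangles:
        for k in range(3):
            e = tuple(sorted((int(tri[k]), int(tri[(k + 1) % 3]))))
            counts[e] = counts.get(e, 0) + 1
    boundary = sum(1 for c in counts.values() if c == 1)
    nonmanifold = sum(1 for c in counts.values() if c > 2)
    return boundary, nonmanifold


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def cube_minus_quad():
    cube = make_cube()
    return TriangleMesh(cube.vertices, cube.triangles[2:])  # drop top quad


def two_tets_shared_edge():
    """Two tetrahedra welded along exactly one edge (non-manifold)."""
    v = np.array([[0, 0, 0], [1, 0, 0],  # shared edge 0-1
                  [0.5, 1, 0], [0.5, 0.5, 1],
                  [0.5, -1, 0], [0.5, -0.5, -1]], dtype=float)
    t = np.array([[0, 1, 2], [0, 3, 1], [1, 3, 2], [0, 2, 3],
                  [0, 4, 1], [0, 1, 5], [1, 4, 5], [0, 5, 4]])
    return TriangleMesh(v, t)


class TestCheckWatertight:
    def test_closed_cube(self, cube):
        rep = check_watertight(cube)
        assert rep.watertight
        assert rep.component_count == 1
        assert rep.defect_total() == 0

    def test_cube_minus_quad(self):
        rep = check_watertight(cube_minus_quad())
        assert rep.boundary_edges == 4
        assert not rep.watertight

    def test_two_tets_nonmanifold_edge(self):
        # DERIVED: constructed fixture + fan-cycle oracle
        mesh = two_tets_shared_edge()
        rep = check_watertight(mesh)
        assert rep.non_manifold_edges == 1
        assert not rep.watertight
        b, nm = oracle_nonmanifold_edges(mesh)
        assert (rep.boundary_edges, rep.non_manifold_edges) == (b, nm)

    def test_pinch_vertex_detected(self):
        # two closed tetrahedra sharing a single vertex
        def tet(offset):
            v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
            return v + offset
        v = np.vstack([tet(np.zeros(3)), tet(np.zeros(3))])
        v[4:] *= -1  # mirrored tet; vertex 0 and 4 coincide at origin
        t = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2],
                      [4, 5, 6], [4, 6, 7], [4, 7, 5], [5, 7, 6]])
        # weld the coincident vertices into one index
        t[t == 4] = 0
        mesh = TriangleMesh(v, t)
        nm = nonmanifold_vertices(mesh)
        assert 0 in nm
        rep = check_watertight(mesh)
        assert rep.non_manifold_vertices >= 1

    def test_two_components(self, cube):
        mesh = TriangleMesh.concatenate([cube, cube.translated([5, 0, 0])])
        rep = check_watertight(mesh)
        assert rep.component_count == 2
        assert not rep.watertight

    def test_zero_face_counted(self, cube):
        v = np.vstack([cube.vertices, cube.vertices[:1] + 1e-13])
        t = np.vstack([cube.triangles, [[0, 8, 1]]])
        rep = check_watertight(TriangleMesh(v, t))
        assert rep.zero_faces >= 1


class TestSelfIntersections:
    def test_crossed_triangles_found(self):
        v = np.array([[0, 0, 0], [2, 0, 0], [1, 2, 0],
                      [0.5, 1, -1], [1.5, 1, -1], [1.0, 0.5, 1]])
        t = np.array([[0, 1, 2], [3, 4, 5]])
        pairs = self_intersections(TriangleMesh(v, t))
        assert pairs.tolist() == [[0, 1]]

    def test_shared_vertex_excluded(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1.0]])
        t = np.array([[0, 1, 2], [0, 1, 3]])
        assert len(self_intersections(TriangleMesh(v, t))) == 0

    def test_oracle_equivalence_on_deformed_spheres(self):
        # exact pair-set agreement with the all-pairs oracle (<=500 tris)
        rng = np.random.default_rng(0)
        for trial in range(2):
            mesh = icosphere([0, 0, 0], 1.0, 2)  # 320 faces
            verts = mesh.vertices.copy()
            # displace a few vertices far enough to pierce the surface
            for i in rng.choice(len(verts), size=3, replace=False):
                verts[i] = verts[i] * float(rng.uniform(1.8, 2.5))
                verts[i][0] *= -1
            m = TriangleMesh(verts, mesh.triangles)
            fast = set(map(tuple, self_intersections(m)))
            slow = oracle_self_intersections(m)
            assert fast == slow

    def test_clean_sphere_empty(self):
        assert len(self_intersections(icosphere([0, 0, 0], 1.0, 3))) == 0


class TestVerdictMetrics:
    def test_equilateral(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        q = verdict_metrics(TriangleMesh(v, np.array([[0, 1, 2]])))
        assert q.radius_ratio[0] == pytest.approx(1.0)
        assert q.edge_ratio[0] == pytest.approx(1.0)

    def test_right_isoceles(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        q = verdict_metrics(TriangleMesh(v, np.array([[0, 1, 2]])))
        assert q.edge_ratio[0] == pytest.approx(np.sqrt(2))

    def test_regular_tetrahedron_dihedral(self):
        # TRIVIAL closed form: arccos(1/3) ~ 70.5288 deg
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float)
        t = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        q = verdict_metrics(TriangleMesh(v, t))
        expected = np.degrees(np.arccos(1 / 3))
        assert np.allclose(q.min_dihedral_deg, expected, atol=1e-6)
        assert np.allclose(q.max_dihedral_deg, expected, atol=1e-6)

    def test_degenerate_counted_not_fatal(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0.0]])
        t = np.array([[0, 1, 2], [0, 1, 3]])
        q = verdict_metrics(TriangleMesh(v, t))
        assert q.degenerate_count == 1
        assert np.isinf(q.radius_ratio[0])

    def test_summary_serializable(self, cube):
        import json
        json.dumps(verdict_metrics(cube).summary())


class TestEnclosedVolume:
    def test_unit_cube(self, cube):
        assert enclosed_volume(cube) == pytest.approx(1.0)

    def test_icosphere(self):
        v = enclosed_volume(icosphere([0, 0, 0], 1.0, 4))
        assert v == pytest.approx(4 * np.pi / 3, rel=0.005)

    def test_translation_invariance(self, cube):
        far = cube.translated([123.4, -55.0, 9.1])
        assert enclosed_volume(far) == pytest.approx(enclosed_volume(cube))

    def test_rigid_motion_and_reindex_invariance(self, cube):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = TriangleMesh(cube.vertices @ rot.T + 3.0,
                               cube.triangles[::-1])
        assert enclosed_volume(rotated) == pytest.approx(1.0)

    def test_mixed_orientation_normalized(self, cube):
        t = cube.triangles.copy()
        t[::2] = t[::2][:, ::-1]  # flip half the faces
        assert enclosed_volume(TriangleMesh(cube.vertices, t)) \
            == pytest.approx(1.0)

    def test_open_mesh_rejected(self):
        with pytest.raises(OpenMeshError):
            enclosed_volume(cube_minus_quad())


class TestFaceComponents:
    def test_counts(self, cube):
        both = TriangleMesh.concatenate([cube, cube.translated([9, 0, 0])])
        labels = face_components(both)
        assert labels.max() == 1
        assert np.bincount(labels).tolist() == [12, 12]
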