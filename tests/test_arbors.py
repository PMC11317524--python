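import numpy as np
import pytest

from morphomesh.arbors import (Articulation, Path3D, ProxyAssembly,
                               assemble_joint, build_articulated,
                               build_paths_node_to_leaf, icosphere,
                               interpolate_path, label_primary_children,
                               sweep_tube, export_assembly_obj)
from morphomesh.core import MeshingConfig, Sample, Section, \
    morphology_from_samples
from morphomesh.quality import enclosed_volume, self_intersections

from conftest import binary_tree_morphology


def _branching_morph(child_radii, child_indices=None):
    """Soma + trunk that splits into chains with given initial radii."""
    samples = [Sample(1, 1, np.zeros(3), 2.0, -1),
               Sample(2, 3, np.array([3.0, 0, 0]), 1.0, 1),
               Sample(3, 3, np.array([6.0, 0, 0]), 0.8, 2)]
    nid = 4
    for k, r in enumerate(child_radii):
        y = 2.0 * (k + 1)
        samples.append(Sample(nid, 3, np.array([8.0, y, 0]), r, 3))
        samples.append(Sample(nid + 1, 3, np.array([10.0, 2 * y, 0]),
                              r * 0.9, nid))
        nid += 2
    return morphology_from_samples(samples)


class TestPrimaryLabeling:
    def test_larger_radius_wins(self):
        m = _branching_morph([1.0, 0.4])
        label_primary_children(m, m.neurites[0])
        kids = [m.sections[c] for c in m.sections[0].child_sections]
        primary = [k for k in kids if k.is_primary]
        assert len(primary) == 1
        assert primary[0].samples[1].radius == 1.0

    def test_tie_breaks_to_smaller_index(self):
        m = _branching_morph([0.5, 0.5])
        label_primary_children(m, m.neurites[0])
        kids = sorted((m.sections[c] for c in m.sections[0].child_sections),
                      key=lambda s: s.index)
        assert kids[0].is_primary and not kids[1].is_primary

    def test_trifurcation_single_primary(self):
        # DERIVED: argmax oracle over (0.3, 0.9, 0.6)
        m = _branching_morph([0.3, 0.9, 0.6])
        label_primary_children(m, m.neurites[0])
        kids = [m.sections[c] for c in m.sections[0].child_sections]
        primary = [k for k in kids if k.is_primary]
        assert len(primary) == 1
        assert primary[0].samples[1].radius == 0.9


class TestNodeToLeafPaths:
    def test_y_neurite_two_paths(self, y_morph):
        paths = build_paths_node_to_leaf(y_morph, MeshingConfig())
        assert len(paths) == 2

    def test_unbranched_single_path_with_soma_prefix(self):
        samples = [Sample(1, 1, np.zeros(3), 2.0, -1),
                   Sample(2, 3, np.array([3.0, 0, 0]), 0.5, 1),
                   Sample(3, 3, np.array([6.0, 0, 0]), 0.5, 2)]
        m = morphology_from_samples(samples)
        paths = build_paths_node_to_leaf(m, MeshingConfig())
        assert len(paths) == 1
        assert np.allclose(paths[0].points[0], m.soma_centroid)
        assert paths[0].radii[0] == 0.5

    def test_binary_tree_partition(self, binary_morph):
        # DERIVED: DFS oracle — leaf count paths, disjoint section cover
        paths = build_paths_node_to_leaf(binary_morph, MeshingConfig())
        leaves = [s for s in binary_morph.sections if s.is_leaf()]
        assert len(paths) == len(leaves) == 4
        # every section's samples appear in exactly one path: total point
        # count must match (minus shared duplicates along continuations)
        total_path_pts = sum(len(p.points) for p in paths)
        n_sections = len(binary_morph.sections)
        total_section_pts = sum(len(s.samples)
                                for s in binary_morph.sections)
        # each of the 3 primary continuations merges one duplicate point;
        # the root path gains 1 soma-centroid point
        assert total_path_pts == total_section_pts - 3 + 1


class TestArticulated:
    def test_y_neurite_counts(self, y_morph):
        paths, arts = build_articulated(y_morph, MeshingConfig())
        assert len(paths) == 3
        assert len(arts) == 2  # 1 root + 1 branching

    def test_articulation_radius_is_largest(self):
        samples = [Sample(1, 1, np.zeros(3), 2.0, -1),
                   Sample(2, 3, np.array([3.0, 0, 0]), 0.9, 1),
                   Sample(3, 3, np.array([6.0, 0, 0]), 0.8, 2),
                   Sample(4, 3, np.array([8.0, 2, 0]), 0.5, 3),
                   Sample(5, 3, np.array([10.0, 4, 0]), 0.5, 4),
                   Sample(6, 3, np.array([8.0, -2, 0]), 0.6, 3),
                   Sample(7, 3, np.array([10.0, -4, 0]), 0.6, 6)]
        m = morphology_from_samples(samples)
        # make the children's shared first samples thinner than the
        # parent's end sample, as in a real tapered branch point
        for c in m.sections[0].child_sections:
            m.sections[c].samples[0].radius = 0.5
        _, arts = build_articulated(m, MeshingConfig())
        branching = [a for a in arts
                     if np.allclose(a.center, [6.0, 0, 0])]
        assert len(branching) == 1
        assert branching[0].radius == 0.8

    def test_unbranched(self):
        samples = [Sample(1, 1, np.zeros(3), 2.0, -1),
                   Sample(2, 3, np.array([3.0, 0, 0]), 0.5, 1),
                   Sample(3, 3, np.array([6.0, 0, 0]), 0.5, 2)]
        m = morphology_from_samples(samples)
        paths, arts = build_articulated(m, MeshingConfig())
        assert len(paths) == 1
        assert len(arts) == 1


class TestInterpolatePath:
    def test_collinear_stays_collinear(self):
        p = Path3D(np.array([[0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]]),
                   np.array([0.5, 0.5, 0.5]))
        out = interpolate_path(p, use_spline=True, step=0.25)
        assert np.allclose(out.points[:, 1:], 0.0, atol=1e-9)

    def test_semicircle_arclength(self):
        # DERIVED: analytic semicircle length pi * r
        r = 5.0
        theta = np.linspace(0, np.pi, 5)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        chord = np.linalg.norm(pts[1] - pts[0])
        p = Path3D(pts, np.full(5, 0.5))
        out = interpolate_path(p, use_spline=True, step=chord / 10)
        assert out.arclength() == pytest.approx(np.pi * r, rel=0.01)

    def test_linear_points_on_segments(self):
        pts = np.array([[0, 0, 0], [2.0, 0, 0], [2.0, 3.0, 0]])
        p = Path3D(pts, np.array([0.5, 0.5, 0.5]))
        out = interpolate_path(p, use_spline=False, step=0.4)
        for q in out.points:
            on_seg1 = abs(q[1]) < 1e-9 and -1e-9 <= q[0] <= 2 + 1e-9
            on_seg2 = abs(q[0] - 2.0) < 1e-9 and -1e-9 <= q[1] <= 3 + 1e-9
            assert on_seg1 or on_seg2

    def test_endpoints_exact(self):
        pts = np.array([[0, 0, 0], [1.0, 1.0, 0], [3.0, 0.5, 1.0]])
        p = Path3D(pts, np.array([0.5, 0.4, 0.3]))
        for spline in (True, False):
            out = interpolate_path(p, spline, 0.3)
            assert np.array_equal(out.points[0], pts[0])
            assert np.array_equal(out.points[-1], pts[-1])

    def test_bad_step(self):
        p = Path3D(np.array([[0, 0, 0], [1.0, 0, 0]]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            interpolate_path(p, True, 0.0)


class TestSweepTube:
    def test_cylinder_volume_and_euler(self):
        # DERIVED: analytic cylinder pi r^2 L (flat caps add nothing)
        pts = np.stack([np.linspace(0, 10, 11), np.zeros(11),
                        np.zeros(11)], axis=1)
        tube = sweep_tube(Path3D(pts, np.ones(11)), 16)
        assert tube.is_closed()
        assert tube.euler_characteristic() == 2
        assert enclosed_volume(tube) == pytest.approx(np.pi * 100 / 10,
                                                      rel=0.02)

    def test_minimal_combinatorics(self):
        # DERIVED: 2 rings of 3 + 2 apices; 6 side + 6 cap triangles
        p = Path3D(np.array([[0, 0, 0], [0, 0, 4.0]]), np.array([1.0, 1.0]))
        tube = sweep_tube(p, 3)
        assert len(tube.vertices) == 3 * 2 + 2
        assert len(tube.triangles) == 12
        assert tube.is_closed()

    def test_bent_tube_no_self_intersection(self):
        # 90-degree bend with radius far below the bend radius
        theta = np.linspace(0, np.pi / 2, 12)
        bend_r = 8.0
        pts = np.stack([bend_r * np.cos(theta), bend_r * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        tube = sweep_tube(Path3D(pts, np.full(12, 0.5)), 12)
        assert len(self_intersections(tube)) == 0

    def test_ring_sides_validation(self):
        p = Path3D(np.array([[0, 0, 0], [0, 0, 4.0]]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            sweep_tube(p, 2)

    def test_volume_exact_at_any_ring_count(self):
        # area-compensated rings make the straight-tube volume exact at
        # every ring count (stronger than mere convergence)
        pts = np.stack([np.linspace(0, 10, 11), np.zeros(11),
                        np.zeros(11)], axis=1)
        path = Path3D(pts, np.ones(11))
        for n in (3, 8, 16, 32):
            assert enclosed_volume(sweep_tube(path, n)) == pytest.approx(
                np.pi * 10, abs=1e-9)


class TestIcosphere:
    def test_base_combinatorics(self):
        s = icosphere([0, 0, 0], 1.0, 0)
        uniq, counts = s.edges_sorted_unique()
        assert len(s.vertices) == 12
        assert len(uniq) == 30
        assert len(s.triangles) == 20
        assert s.euler_characteristic() == 2

    def test_subdivision_counts(self):
        # DERIVED: V' = V + E, F' = 4F
        s = icosphere([0, 0, 0], 1.0, 1)
        assert len(s.vertices) == 42
        assert len(s.triangles) == 80

    def test_volume_below_analytic(self):
        # DERIVED: inscribed polyhedron bound
        s = icosphere([1.0, -2.0, 0.5], 1.0, 4)
        v = enclosed_volume(s)
        assert v < 4 * np.pi / 3
        assert v == pytest.approx(4 * np.pi / 3, rel=0.005)

    def test_validation(self):
        with pytest.raises(ValueError):
            icosphere([0, 0, 0], 0.0, 1)
        with pytest.raises(ValueError):
            icosphere([0, 0, 0], 1.0, -1)


class TestAssembleJoint:
    def test_concatenation(self):
        a = icosphere([0, 0, 0], 1.0, 1)
        b = icosphere([0.5, 0, 0], 1.0, 1)
        asm = assemble_joint([a, b], ["a", "b"])
        assert asm.tags == ["a", "b"]
        combined = asm.combined()
        assert len(combined.triangles) == len(a.triangles) + len(b.triangles)

    def test_single_mesh_identity(self):
        a = icosphere([0, 0, 0], 1.0, 1)
        asm = assemble_joint([a])
        assert np.array_equal(asm.combined().vertices, a.vertices)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_joint([])

    def test_tube_plus_articulation_overlap(self):
        # DERIVED: intersection oracle — they overlap by construction
        pts = np.stack([np.linspace(0, 6, 7), np.zeros(7), np.zeros(7)],
                       axis=1)
        tube = sweep_tube(Path3D(pts, np.full(7, 0.5)), 12)
        ball = icosphere([6.0, 0, 0], 0.8, 2)
        combined = assemble_joint([tube, ball]).combined()
        assert len(self_intersections(combined)) >= 1

    def test_obj_export(self, tmp_path):
        asm = assemble_joint([icosphere([0, 0, 0], 1.0, 1)], ["ball"])
        out = tmp_path / "asm.obj"
        export_assembly_obj(asm, out)
        text = out.read_text()
        assert "g ball" in text
        assert text.count("v ") == 42
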