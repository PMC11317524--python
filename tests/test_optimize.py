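import numpy as np
import pytest

from morphomesh.arbors import icosphere
from morphomesh.core import MeshingConfig, TriangleMesh
from morphomesh.optimize import (RepairNonConvergence, coarsen,
                                 collect_defect_vertices,
                                 delete_and_retriangulate, optimize,
                                 repair_loop, smooth)
from morphomesh.quality import check_watertight, edge_counts, \
    enclosed_volume

from conftest import make_cube


def displaced_icosphere(seed: int, subdiv: int = 3) -> TriangleMesh:
    """An icosphere with one vertex shoved through the opposite wall.

    The displaced vertex's fan pierces the far side of the sphere, which
    reliably injects self-intersecting facets.
    """
    rng = np.random.default_rng(seed)
    mesh = icosphere([0, 0, 0], 1.0, subdiv)
    verts = mesh.vertices.copy()
    i = int(rng.integers(0, len(verts)))
    direction = verts[i] / np.linalg.norm(verts[i])
    verts[i] = verts[i] - direction * float(rng.uniform(2.2, 2.6))
    return TriangleMesh(verts, mesh.triangles)


class TestCoarsen:
    def test_identity_at_ratio_one(self, cube):
        out = coarsen(cube, 1.0)
        assert np.array_equal(out.vertices, cube.vertices)
        assert np.array_equal(out.triangles, cube.triangles)

    def test_icosphere_half(self):
        # DERIVED: run + volume oracle
        mesh = icosphere([0, 0, 0], 1.0, 4)
        out = coarsen(mesh, 0.5)
        assert len(out.triangles) <= 2560
        assert enclosed_volume(out) == pytest.approx(enclosed_volume(mesh),
                                                     rel=0.01)

    def test_cube_volume_exact(self, cube):
        # DERIVED: quadric planar exactness
        for ratio in (0.9, 0.5, 0.1):
            out = coarsen(cube, ratio)
            assert abs(enclosed_volume(out) - 1.0) < 1e-9

    def test_subdivided_cube_planar_exact(self):
        # densely triangulated cube: planar interior collapses are exact
        from morphomesh.voxel import polygonize, voxelize_solid
        grid = voxelize_solid(make_cube(side=4.0), 0.25)
        mesh = polygonize(grid)
        out = coarsen(mesh, 0.4)
        assert len(out.triangles) < len(mesh.triangles)
        assert enclosed_volume(out) == pytest.approx(enclosed_volume(mesh),
                                                     rel=0.002)

    def test_bad_ratio(self, cube):
        with pytest.raises(ValueError):
            coarsen(cube, 0.0)
        with pytest.raises(ValueError):
            coarsen(cube, 1.5)

    def test_orientation_preserved(self):
        mesh = icosphere([0, 0, 0], 1.0, 3)
        out = coarsen(mesh, 0.5)
        v, t = out.vertices, out.triangles
        signed = np.einsum("ij,ij->i", v[t[:, 0]],
                           np.cross(v[t[:, 1]], v[t[:, 2]])).sum() / 6.0
        assert signed > 0

    def test_adaptivity_corrugated_vs_flat(self):
        # corrugated hemisphere keeps >= 2x the triangle density of the
        # smooth hemisphere after coarsening
        mesh = icosphere([0, 0, 0], 1.0, 4)
        verts = mesh.vertices.copy()
        upper = verts[:, 2] > 0
        bump = 0.08 * np.sin(8 * np.arctan2(verts[:, 1], verts[:, 0])) \
            * np.sin(8 * np.arccos(np.clip(verts[:, 2], -1, 1)))
        radial = verts / np.linalg.norm(verts, axis=1)[:, None]
        verts[upper] += (bump[upper])[:, None] * radial[upper]
        bumpy = TriangleMesh(verts, mesh.triangles)
        out = coarsen(bumpy, 0.15)
        centroids = out.vertices[out.triangles].mean(axis=1)
        n_up = int((centroids[:, 2] > 0.1).sum())
        n_down = int((centroids[:, 2] < -0.1).sum())
        assert n_up >= 2 * n_down


class TestSmooth:
    def test_zero_iterations_identity(self):
        mesh = icosphere([0, 0, 0], 1.0, 3)
        out = smooth(mesh, 0)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_noisy_sphere_denoised_volume_kept(self):
        # DERIVED: constructed radial noise, measured reduction
        rng = np.random.default_rng(1)
        mesh = icosphere([0, 0, 0], 1.0, 4)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices,
                                                axis=1)[:, None]
        noisy_v = mesh.vertices + 0.01 * rng.standard_normal(
            (len(mesh.vertices), 1)) * radial
        noisy = TriangleMesh(noisy_v, mesh.triangles)
        v0 = enclosed_volume(noisy)
        out = smooth(noisy, 10)
        r_before = np.linalg.norm(noisy.vertices, axis=1)
        r_after = np.linalg.norm(out.vertices, axis=1)
        assert r_after.std() <= r_before.std() / 5.0
        assert enclosed_volume(out) == pytest.approx(v0, rel=0.005)

    def test_topology_unchanged(self):
        mesh = icosphere([0, 0, 0], 1.0, 2)
        out = smooth(mesh, 7)
        assert np.array_equal(out.triangles, mesh.triangles)
        assert len(out.vertices) == len(mesh.vertices)

    def test_negative_iterations(self):
        with pytest.raises(ValueError):
            smooth(icosphere([0, 0, 0], 1.0, 1), -1)


class TestDeleteRetriangulate:
    def test_single_vertex_hole_closed(self):
        # DERIVED: construction + Euler check
        mesh = icosphere([0, 0, 0], 1.0, 2)
        out = delete_and_retriangulate(mesh, {0})
        boundary, nonmanifold = edge_counts(out)
        assert boundary == 0
        assert nonmanifold == 0
        assert out.euler_characteristic() == 2
        assert len(out.vertices) == len(mesh.vertices) - 1

    def test_empty_set_identity(self):
        mesh = icosphere([0, 0, 0], 1.0, 2)
        out = delete_and_retriangulate(mesh, set())
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_two_adjacent_vertices_merged_hole(self):
        # DERIVED: boundary-loop oracle — single merged hole, closed out
        mesh = icosphere([0, 0, 0], 1.0, 2)
        uniq, _ = mesh.edges_sorted_unique()
        a, b = int(uniq[0][0]), int(uniq[0][1])
        out = delete_and_retriangulate(mesh, {a, b})
        boundary, _ = edge_counts(out)
        assert boundary == 0
        assert out.euler_characteristic() == 2

    def test_whole_mesh_rejected(self, cube):
        with pytest.raises(ValueError):
            delete_and_retriangulate(cube, set(range(8)))

    def test_volume_roughly_kept(self):
        mesh = icosphere([0, 0, 0], 1.0, 3)
        out = delete_and_retriangulate(mesh, {3, 77})
        assert enclosed_volume(out) == pytest.approx(enclosed_volume(mesh),
                                                     rel=0.02)


class TestRepairLoop:
    def test_already_watertight_identity(self):
        mesh = icosphere([0, 0, 0], 1.0, 3)
        out, trace = repair_loop(mesh, MeshingConfig())
        assert trace.converged
        assert trace.iterations_used == 0
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_single_defect_fixed(self):
        mesh = displaced_icosphere(7)
        assert not check_watertight(mesh).watertight  # defect injected
        out, trace = repair_loop(mesh, MeshingConfig())
        assert trace.converged
        assert trace.iterations_used <= 3
        assert check_watertight(out).watertight

    def test_fuzz_repair(self):
        # DERIVED: fuzz harness (the acceptance suite runs the full 100)
        for seed in range(15):
            mesh = displaced_icosphere(seed, subdiv=2)
            out, trace = repair_loop(mesh, MeshingConfig())
            assert check_watertight(out).watertight, f"seed {seed}"

    def test_fragmented_mesh_raises(self, cube):
        mesh = TriangleMesh.concatenate([cube, cube.translated([5, 0, 0])])
        with pytest.raises(RepairNonConvergence):
            repair_loop(mesh, MeshingConfig())


class TestOptimize:
    def test_icosphere_optimize(self):
        mesh = icosphere([0, 0, 0], 1.0, 4)
        cfg = MeshingConfig(optimization_target_ratio=0.3,
                            smoothing_iterations=5)
        out, trace = optimize(mesh, cfg)
        assert trace.converged
        assert check_watertight(out).watertight
        assert enclosed_volume(out) == pytest.approx(enclosed_volume(mesh),
                                                     rel=0.02)

    def test_identity_config(self):
        mesh = icosphere([0, 0, 0], 1.0, 3)
        cfg = MeshingConfig(optimization_target_ratio=1.0,
                            smoothing_iterations=0)
        out, _ = optimize(mesh, cfg)
        assert np.array_equal(out.triangles, mesh.triangles)
        assert np.allclose(out.vertices, mesh.vertices)

    def test_trace_serializable(self):
        import json
        mesh = icosphere([0, 0, 0], 1.0, 3)
        _, trace = optimize(mesh, MeshingConfig(
            optimization_target_ratio=0.5, smoothing_iterations=1))
        json.dumps(trace.to_dict())
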