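import numpy as np
import pytest

from morphomesh.core import (Morphology, Sample, TriangleMesh,
                             morphology_from_samples)


def make_cube(side: float = 1.0, origin=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Closed unit cube (12 triangles, outward orientation)."""
    o = np.asarray(origin, dtype=float)
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                 dtype=float) * side + o
    t = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                  [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
                  [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]])
    return TriangleMesh(v, t)


@pytest.fixture
def cube() -> TriangleMesh:
    return make_cube()


def y_morphology() -> Morphology:
    """Soma + a Y-shaped neurite: root chain of 3, then two chains of 2."""
    s = [
        Sample(1, 1, np.array([0.0, 0.0, 0.0]), 2.0, -1),
        Sample(2, 3, np.array([3.0, 0.0, 0.0]), 1.0, 1),
        Sample(3, 3, np.array([5.0, 0.0, 0.0]), 1.0, 2),
        Sample(4, 3, np.array([7.0, 0.0, 0.0]), 0.9, 3),
        Sample(5, 3, np.array([9.0, 1.5, 0.0]), 0.7, 4),
        Sample(6, 3, np.array([11.0, 3.0, 0.0]), 0.6, 5),
        Sample(7, 3, np.array([9.0, -1.5, 0.0]), 0.5, 4),
        Sample(8, 3, np.array([11.0, -3.0, 0.0]), 0.4, 7),
    ]
    return morphology_from_samples(s)


@pytest.fixture
def y_morph() -> Morphology:
    return y_morphology()


def binary_tree_morphology(depth: int = 3) -> Morphology:
    """Full binary tree of sections, 2^depth - 1 sections per neurite."""
    samples = [Sample(1, 1, np.zeros(3), 2.0, -1)]
    next_id = [2]

    def grow(parent_id: int, base: np.ndarray, direction: np.ndarray,
             level: int) -> None:
        direction = direction / np.linalg.norm(direction)
        end = base + 4.0 * direction
        mid = base + 2.0 * direction
        ids = []
        for pos in (mid, end):
            samples.append(Sample(next_id[0], 3, pos.copy(), 0.5, parent_id))
            ids.append(next_id[0])
            parent_id = next_id[0]
            next_id[0] += 1
        if level < depth:
            perp = np.cross(direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(direction, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            grow(ids[-1], end, direction + 0.8 * perp, level + 1)
            grow(ids[-1], end, direction - 0.8 * perp, level + 1)

    samples.append(Sample(next_id[0], 3, np.array([2.0, 0.0, 0.0]), 0.6, 1))
    root_id = next_id[0]
    next_id[0] += 1
    grow(root_id, np.array([2.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), 1)
    return morphology_from_samples(samples)


@pytest.fixture
def binary_morph() -> Morphology:
    return binary_tree_morphology()
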