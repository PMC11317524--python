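"""Seeded synthetic neurons: branched, tapering, spiny test morphologies.

The generator emits valid morphologies (positive radii, acyclic parent
links, soma-rooted neurites) with binary branching up to a maximum order
and radii tapering toward the leaves.  Everything is deterministic per
seed, down to the SWC bytes.
"""

from __future__ import annotations

import numpy as np

from .core import (BASAL_DENDRITE_TYPE, SOMA_TYPE, Morphology, Sample,
                   morphology_from_samples)

MIN_RADIUS = 0.05  # µm floor for the thinnest synthetic fiber


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _spread_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Roughly even directions (Fibonacci sphere with a seeded jitter)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    dirs = np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)
    dirs += 0.15 * rng.standard_normal(dirs.shape)
    return dirs / np.linalg.norm(dirs, axis=1)[:, None]


def synthesize_morphology(rng_seed: int, n_neurites: int = 4,
                          max_branch_order: int = 3, taper: float = 0.85,
                          spatial_extent: float = 40.0,
                          root_radius_range: tuple[float, float] = (0.5, 0.9),
                          soma_radius_range: tuple[float, float] = (3.0, 6.0),
                          samples_per_section: int = 5,
                          type_code: int = BASAL_DENDRITE_TYPE) -> Morphology:
    """Build a random binary-branching neuron around a spherical soma.

    Sections wander outward with persistence; child radii shrink by
    *taper* per order, floored at 0.05 µm; section lengths scale with
    ``spatial_extent`` so the arbor roughly fills it.
    """
    if min(n_neurites, max_branch_order, samples_per_section) <= 0:
        raise ValueError("generator parameters must be positive")
    if not 0 < taper <= 1:
        raise ValueError("taper must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    soma_radius = float(rng.uniform(*soma_radius_range))
    section_length = max((spatial_extent / 2.0 - soma_radius)
                         / max_branch_order, 2.0)

    samples: list[Sample] = []
    next_id = 1
    samples.append(Sample(next_id, SOMA_TYPE, np.zeros(3), soma_radius, -1))
    soma_id = next_id
    next_id += 1

    def add_section(parent_sample_id: int, start: np.ndarray,
                    direction: np.ndarray, radius: float, order: int) -> None:
        nonlocal next_id
        pos = start.copy()
        d = direction.copy()
        prev = parent_sample_id
        end_radius = max(radius * taper, MIN_RADIUS)
        n_pts = samples_per_section
        for i in range(n_pts):
            step = section_length / n_pts
            d = _unit(d + 0.25 * rng.standard_normal(3))
            pos = pos + step * d
            r = radius + (end_radius - radius) * (i + 1) / n_pts
            samples.append(Sample(next_id, type_code, pos.copy(), r, prev))
            prev = next_id
            next_id += 1
        if order < max_branch_order:
            for _ in range(2):
                child_dir = _unit(d + 0.8 * rng.standard_normal(3))
                add_section(prev, pos, child_dir,
                            max(end_radius * taper, MIN_RADIUS), order + 1)

    for direction in _spread_directions(n_neurites, rng):
        root_radius = float(rng.uniform(*root_radius_range))
        start = direction * soma_radius * 0.9
        samples.append(Sample(next_id, type_code, start.copy(),
                              root_radius, soma_id))
        first = next_id
        next_id += 1
        add_section(first, start, direction, root_radius, 1)

    return morphology_from_samples(samples)
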