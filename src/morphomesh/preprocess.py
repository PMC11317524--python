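"""Morphology cleaning: soma connectivity, inner-sample removal, resampling.

None of these operations change the structure of the morphology (section
count, parent/child topology, branch orders); they only edit sample lists
inside sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Morphology, Sample, Section


@dataclass
class PreprocessReport:
    arbors_connected: list[tuple[int, bool]] = field(default_factory=list)
    samples_removed: int = 0
    sections_resampled: int = 0
    samples_before: int = 0
    samples_after: int = 0

    def to_dict(self) -> dict:
        return {
            "arbors_connected": [[i, bool(c)] for i, c in self.arbors_connected],
            "samples_removed": self.samples_removed,
            "sections_resampled": self.sections_resampled,
            "samples_before": self.samples_before,
            "samples_after": self.samples_after,
        }


def verify_soma_connectivity(morphology: Morphology,
                             tolerance_factor: float = 2.0) -> PreprocessReport:
    """Flag neurites whose root sample lies too far from the soma.

    A neurite counts as connected when its root sample is within
    ``tolerance_factor * soma_mean_radius`` of the soma centroid (closed
    interval).  Disconnected neurites are only flagged here; the proxy
    stage bridges them with auxiliary geometry instead of deleting them.
    """
    report = PreprocessReport()
    limit = tolerance_factor * morphology.soma_mean_radius
    for i, root in enumerate(morphology.neurites):
        d = float(np.linalg.norm(root.samples[0].position
                                 - morphology.soma_centroid))
        report.arbors_connected.append((i, d <= limit))
    return report


def remove_inner_samples(morphology: Morphology) -> Morphology:
    """Drop leading root-section samples inside the somatic sphere.

    The somatic spatial extent is taken as the sphere of mean radius about
    the centroid.  Every section keeps at least its last two samples, so
    connectivity is untouched.  Idempotent.
    """
    out = morphology.copy()
    removed = 0
    for sec in out.sections:
        if not sec.is_root():
            continue
        dists = np.linalg.norm(sec.points - out.soma_centroid, axis=1)
        n_inside = 0
        for d in dists:
            if d < out.soma_mean_radius:
                n_inside += 1
            else:
                break
        n_drop = min(n_inside, len(sec.samples) - 2)
        if n_drop > 0:
            sec.samples = sec.samples[n_drop:]
            removed += n_drop
    return out


def resample_section(section: Section) -> tuple[Section, bool]:
    """Resample one section at a spacing of about the local radius.

    The step taken from each output sample equals that sample's radius;
    endpoints are preserved exactly and radii are interpolated linearly
    along arclength.  Returns (section, changed).
    """
    pts = section.points
    radii = section.radii
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        return section, False

    def interp_pos(s: float) -> np.ndarray:
        return np.array([np.interp(s, arclen, pts[:, k]) for k in range(3)])

    def interp_rad(s: float) -> float:
        return float(np.interp(s, arclen, radii))

    new_s = [0.0]
    while True:
        step = interp_rad(new_s[-1])
        nxt = new_s[-1] + step
        if nxt >= total - 0.5 * interp_rad(total):
            break
        new_s.append(nxt)
    new_samples = [section.samples[0].copy()]
    base = section.samples[0]
    for s in new_s[1:]:
        new_samples.append(Sample(base.id, section.type_code, interp_pos(s),
                                  interp_rad(s), base.parent_id))
    new_samples.append(section.samples[-1].copy())
    changed = len(new_samples) != len(section.samples) or not np.allclose(
        np.array([p.position for p in new_samples]), pts)
    section.samples = new_samples
    return section, changed


def resample_adaptive(morphology: Morphology) -> tuple[Morphology, int]:
    """Resample every section; returns (morphology, sections changed)."""
    out = morphology.copy()
    n_changed = 0
    for sec in out.sections:
        _, changed = resample_section(sec)
        n_changed += int(changed)
    return out, n_changed


def preprocess(morphology: Morphology,
               tolerance_factor: float = 2.0) -> tuple[Morphology, PreprocessReport]:
    """Run connectivity check, inner-sample removal, adaptive resampling."""
    before = sum(len(s.samples) for s in morphology.sections)
    report = verify_soma_connectivity(morphology, tolerance_factor)
    report.samples_before = before
    cleaned = remove_inner_samples(morphology)
    report.samples_removed = before - sum(len(s.samples)
                                          for s in cleaned.sections)
    resampled, n_changed = resample_adaptive(cleaned)
    report.sections_resampled = n_changed
    report.samples_after = sum(len(s.samples) for s in resampled.sections)
    return resampled, report
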