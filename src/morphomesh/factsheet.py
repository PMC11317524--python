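"""Comparative quality fact sheets (pre- vs post-optimization)."""

from __future__ import annotations

import json

import numpy as np

from .quality import QualityStats

_METRICS = ("radius_ratio", "edge_ratio", "radius_to_edge_ratio",
            "min_dihedral_deg", "max_dihedral_deg")


def factsheet_dict(pre: QualityStats, post: QualityStats) -> dict:
    return {"voxel_remeshed": pre.summary(), "optimized": post.summary()}


def write_factsheet(pre: QualityStats, post: QualityStats, json_path,
                    plot_path=None) -> None:
    """JSON comparison; optional histogram bundle (PNG/SVG)."""
    with open(json_path, "w") as fh:
        json.dump(factsheet_dict(pre, post), fh, indent=2, default=float)
    if plot_path is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(_METRICS), figsize=(4 * len(_METRICS), 3))
    for ax, name in zip(axes, _METRICS):
        for stats, label, color in ((pre, "voxel remeshed", "#d98880"),
                                    (post, "optimized", "#85c1e9")):
            arr = getattr(stats, name)
            arr = arr[np.isfinite(arr)]
            if len(arr):
                ax.hist(arr, bins=50, alpha=0.6, label=label, color=color)
        ax.set_title(name)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
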