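"""Optional figures: group-mean topology parameters against threshold."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .synthetic import AD, EVOLVED, HEALTHY

_STYLE = {HEALTHY: ("tab:blue", "^"), AD: ("black", "s"), EVOLVED: ("tab:red", "o")}


def plot_group_curves(group_means, feature: str, path) -> Path:
    """Scatter of one group-mean feature across the threshold grid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group in (HEALTHY, AD, EVOLVED):
        pts = sorted(
            (p.threshold, getattr(p, feature))
            for p in group_means
            if p.group == group and p.threshold is not None
        )
        if not pts:
            continue
        color, marker = _STYLE[group]
        ax.scatter(*zip(*pts), c=color, marker=marker, label=group, s=28)
    ax.set_xlabel("correlation threshold")
    ax.set_ylabel(feature.replace("_", " "))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
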