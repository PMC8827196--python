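"""Per-chromosome track panels: depth curves, ∆depth, and q95/q99 lines."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

from .deltadetect import DeltaTrack, NullThresholds, RegionCall
from .windows import WindowTrack

logger = logging.getLogger(__name__)

__all__ = ["render_tracks"]


def render_tracks(
    wt: Mapping[str, WindowTrack],
    mut: Mapping[str, WindowTrack],
    delta: Mapping[str, DeltaTrack],
    thresholds: NullThresholds,
    path: str | Path,
    calls: Sequence[RegionCall] = (),
) -> bool:
    """Render one two-row panel per chromosome (depth above, ∆depth below).

    The ∆depth row carries horizontal q95/q99 threshold lines and shades any
    called regions.  Returns False (and writes nothing) for an empty
    chromosome set.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in wt if c in mut and c in delta]
    if not chroms:
        logger.warning("no chromosomes to plot; no file written")
        return False

    fig, axes = plt.subplots(
        2, len(chroms), figsize=(4.5 * len(chroms), 5.5),
        sharey="row", squeeze=False,
    )
    for col, chrom in enumerate(chroms):
        ax_depth, ax_delta = axes[0][col], axes[1][col]
        mbp = 1e-6
        x = wt[chrom].starts * mbp
        ax_depth.plot(x, wt[chrom].values, lw=0.8, label="wild-type")
        ax_depth.plot(x, mut[chrom].values, lw=0.8, label="mutant")
        ax_depth.set_title(chrom)
        ax_depth.set_ylabel("mean depth")
        ax_delta.plot(delta[chrom].starts * mbp, delta[chrom].values,
                      lw=0.8, color="black", label="Δdepth")
        ax_delta.axhline(thresholds.q95, ls="--", lw=0.8, color="tab:orange",
                         label="q95")
        ax_delta.axhline(thresholds.q99, ls="--", lw=0.8, color="tab:red",
                         label="q99")
        for call in calls:
            if call.chrom == chrom:
                ax_delta.axvspan(call.start * mbp, call.end * mbp,
                                 alpha=0.2, color="tab:red")
        ax_delta.set_xlabel("position (Mbp)")
        ax_delta.set_ylabel("Δdepth")
    axes[0][0].legend(fontsize=8)
    axes[1][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return True
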