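"""Aligned-map plot: linkage groups against physical chromosomes.

One panel per linkage group: the genetic axis (cM) on the left, the
physical axis (bp) of each partner chromosome on the right, with a line per
marker connecting its two positions.  Crossing lines reveal inversions;
markers connecting to a non-partner chromosome stand out as long diagonals.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_aligned_map(corr: pd.DataFrame, path, max_groups: Optional[int] = None
                     ) -> None:
    """Render a correspondence table as an aligned-map figure (PNG/PDF)."""
    groups = list(dict.fromkeys(corr["linkage_group"]))
    if max_groups:
        groups = groups[:max_groups]
    n = len(groups)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(2.2 * max(n, 1), 6),
                             squeeze=False)
    for ax, lg in zip(axes[0], groups):
        sub = corr[corr["linkage_group"] == lg]
        cm_span = max(sub["cM"].max() - sub["cM"].min(), 1e-9)
        chroms = list(dict.fromkeys(sub["chrom"]))
        offsets = {c: i for i, c in enumerate(chroms)}
        for row in sub.itertuples():
            chrom_sub = sub[sub["chrom"] == row.chrom]
            bp_span = max(chrom_sub["bp"].max() - chrom_sub["bp"].min(), 1e-9)
            y_cm = (row.cM - sub["cM"].min()) / cm_span
            y_bp = (row.bp - chrom_sub["bp"].min()) / bp_span
            y_bp = (y_bp + offsets[row.chrom]) / max(len(chroms), 1)
            ax.plot([0, 1], [y_cm, y_bp], lw=0.6, color="steelblue")
        ax.set_title(str(lg), fontsize=8)
        ax.set_xticks([0, 1])
        ax.set_xticklabels(["cM", "bp"], fontsize=7)
        ax.set_yticks([])
        ax.invert_yaxis()
    for ax in axes[0][n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
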