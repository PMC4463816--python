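"""One overview figure: per-test window scores along the genome."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_window_scores"]


def plot_window_scores(
    window_tables: dict[str, pd.DataFrame], path: str | Path
) -> None:
    """Stacked tracks of window scores per test, outlier windows highlighted.

    Windows are laid out on a concatenated genome coordinate (chromosomes
    end-to-end, in table order); top-1% windows are drawn in red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tests = list(window_tables)
    fig, axes = plt.subplots(
        len(tests), 1, figsize=(10, 2.2 * len(tests)), sharex=True, squeeze=False
    )
    for ax, test in zip(axes[:, 0], tests):
        df = window_tables[test]
        offset = 0
        xs, boundaries = [], []
        for chrom, sub in df.groupby("chrom", sort=False):
            xs.append(sub["start"].to_numpy() + offset)
            offset += int(sub["end"].max())
            boundaries.append(offset)
        x = np.concatenate(xs) if xs else np.array([])
        ax.scatter(x, df["score"], s=6, c="0.6", linewidths=0)
        if "top1" in df:
            flagged = df["top1"].to_numpy()
            ax.scatter(x[flagged], df.loc[flagged, "score"], s=10, c="crimson",
                       linewidths=0, label="top 1%")
            ax.legend(loc="upper right", frameon=False, fontsize=8)
        for b in boundaries[:-1]:
            ax.axvline(b, color="0.85", lw=0.8)
        ax.set_ylabel(test)
    axes[-1, 0].set_xlabel("concatenated genome position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
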