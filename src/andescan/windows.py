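"""Fixed-window, empirical-outlier framework for genome scans.

Windows tile each chromosome from coordinate 0 at a fixed width (200 kb
for the haplotype tests, 100 kb for the frequency tests). Windows are
ranked within SNP-count bins -- grouping windows with similar numbers of
scored SNPs compensates for the uneven SNP distribution of array data --
and the empirical top percentile (1% by default, with 5% used for
exclusion sets) is flagged. All calling is rank-based, hence invariant to
monotone transforms of the score.

Window score conventions:

* iHS: fraction of scored SNPs in the window with |standardized iHS| > 2;
* XP-EHH: window maximum standardized score;
* F_ST and PBS: window maximum per-SNP value (these tests emphasize
  extreme single SNPs).

Each window also carries its max-SNP score, id and position, used for
deterministic tie-breaking and for gene-level reporting.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import DataError

__all__ = [
    "make_windows",
    "window_scores",
    "bin_by_snp_count",
    "call_outliers",
    "exclusion_filter",
    "cross_test_overlap",
    "fst_cutoff_count",
    "branch_length_comparison",
]

IHS_ABS_THRESHOLD = 2.0
BIN_FLOOR = 50


def make_windows(snp_df: pd.DataFrame, width: int) -> pd.DataFrame:
    """Tile windows of ``width`` bp (0-based half-open, anchored at 0) over
    the scored SNPs in ``snp_df`` (columns ``chrom``, ``pos`` 1-based).

    Windows containing no scored SNP are dropped. Returns columns
    ``chrom, start, end, snp_count``.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, sub in snp_df.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        win = pos0 // width
        for w, cnt in zip(*np.unique(win, return_counts=True)):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(w) * width,
                    "end": (int(w) + 1) * width,
                    "snp_count": int(cnt),
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_count"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def window_scores(
    snp_df: pd.DataFrame,
    width: int,
    score_col: str,
    kind: str,
    abs_threshold: float = IHS_ABS_THRESHOLD,
) -> pd.DataFrame:
    """Aggregate per-SNP scores into per-window scores.

    Parameters
    ----------
    snp_df
        Columns ``chrom``, ``pos`` (1-based), ``snp_id``, and ``score_col``;
        rows with NaN score are not scored SNPs and are ignored.
    kind
        ``"prop_extreme"`` (fraction of SNPs with \\|score\\| above
        ``abs_threshold``; the iHS convention) or ``"max"`` (window maximum;
        XP-EHH / F_ST / PBS convention).

    Returns
    -------
    DataFrame with ``chrom, start, end, snp_count, score, max_snp_score,
    max_snp_id, max_snp_pos`` sorted by (chrom, start).
    """
    if kind not in ("prop_extreme", "max"):
        raise ValueError(f"unknown window score kind {kind!r}")
    scored = snp_df[np.isfinite(snp_df[score_col].to_numpy(dtype=float))]
    rows = []
    for chrom, sub in scored.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        win = pos0 // width
        s = sub[score_col].to_numpy(dtype=float)
        ids = sub["snp_id"].to_numpy()
        pos = sub["pos"].to_numpy()
        for w in np.unique(win):
            m = win == w
            sw = s[m]
            key = np.abs(sw) if kind == "prop_extreme" else sw
            best = int(np.argmax(key))
            score = (
                float((np.abs(sw) > abs_threshold).mean())
                if kind == "prop_extreme"
                else float(sw[best])
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(w) * width,
                    "end": (int(w) + 1) * width,
                    "snp_count": int(m.sum()),
                    "score": score,
                    "max_snp_score": float(key[best]),
                    "max_snp_id": ids[m][best],
                    "max_snp_pos": int(pos[m][best]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "snp_count", "score",
            "max_snp_score", "max_snp_id", "max_snp_pos",
        ],
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def bin_by_snp_count(windows: pd.DataFrame, bin_floor: int = BIN_FLOOR) -> pd.DataFrame:
    """Assign each window a SNP-count bin id.

    Adjacent SNP-count values are merged upward (from the smallest counts)
    until every bin holds at least ``bin_floor`` windows; a deficient final
    bin is merged into its predecessor. With fewer than ``bin_floor``
    windows in total, a single bin is used.
    """
    df = windows.copy()
    counts = df["snp_count"].to_numpy()
    uniq, n_per = np.unique(counts, return_counts=True)
    if counts.size < bin_floor:
        df["bin_id"] = 0
        return df
    bin_of_count = {}
    bin_id = 0
    acc = 0
    for u, n in zip(uniq, n_per):
        bin_of_count[int(u)] = bin_id
        acc += int(n)
        if acc >= bin_floor:
            bin_id += 1
            acc = 0
    if acc and bin_id > 0:
        # fold a deficient trailing bin into the previous one
        for u in bin_of_count:
            if bin_of_count[u] == bin_id:
                bin_of_count[u] = bin_id - 1
    df["bin_id"] = [bin_of_count[int(c)] for c in counts]
    return df


def call_outliers(
    windows: pd.DataFrame,
    top1: float = 0.01,
    top5: float = 0.05,
) -> pd.DataFrame:
    """Rank windows within their bin and flag empirical outliers.

    Within each bin the top ``ceil(percentile * N_bin)`` windows by score
    are flagged; ties on score are broken by higher max-SNP score, then by
    lower (chrom, start). ``percentile`` = (rank - 1) / N_bin with rank 1
    the best window of its bin, so smaller is more extreme.
    """
    if not 0 < top1 <= top5 <= 1:
        raise ValueError("need 0 < top1 <= top5 <= 1")
    df = windows.copy()
    if "bin_id" not in df.columns:
        df["bin_id"] = 0
    df["rank"] = 0
    df["percentile"] = np.nan
    df["top1"] = False
    df["top5"] = False
    for b in np.unique(df["bin_id"]):
        sub = df[df["bin_id"] == b]
        order = sub.sort_values(
            ["score", "max_snp_score", "chrom", "start"],
            ascending=[False, False, True, True],
        ).index
        n = len(order)
        ranks = pd.Series(np.arange(1, n + 1), index=order)
        df.loc[order, "rank"] = ranks
        df.loc[order, "percentile"] = (ranks - 1) / n
        df.loc[order, "top1"] = ranks <= math.ceil(top1 * n)
        df.loc[order, "top5"] = ranks <= math.ceil(top5 * n)
    assert bool((df["top1"] <= df["top5"]).all())
    return df


def exclusion_filter(
    focal: pd.DataFrame,
    control: pd.DataFrame,
    focal_flag: str = "top1",
    control_flag: str = "top5",
) -> pd.DataFrame:
    """Retain focal outlier windows that are not outliers in the control.

    This is the cross-population exclusion rule: focal top-1% windows are
    only kept when absent from the control population's top-5% set,
    removing signals shared with the lowland control (hence unlikely to be
    altitude-driven). Both scans must share the window tiling.
    """
    w_f = (focal["end"] - focal["start"]).max()
    w_c = (control["end"] - control["start"]).max()
    if w_f != w_c:
        raise DataError(f"mismatched window tilings: width {w_f} vs {w_c}")
    control_set = {
        (c, s)
        for c, s in control.loc[control[control_flag], ["chrom", "start"]].itertuples(
            index=False
        )
    }
    flagged = focal[focal[focal_flag]]
    keep = [
        (c, s) not in control_set
        for c, s in flagged[["chrom", "start"]].itertuples(index=False)
    ]
    retained = flagged[np.asarray(keep, dtype=bool)]
    n_removed = len(flagged) - len(retained)
    if n_removed:
        import logging

        logging.getLogger("andescan").info(
            "exclusion filter removed %d of %d focal outlier windows",
            n_removed,
            len(flagged),
        )
    return retained.reset_index(drop=True)


def cross_test_overlap(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Tabulate genes by the number of tests flagging them.

    Returns a DataFrame ``gene, tests, n_tests`` sorted by descending
    support then name; the summaries the scans report are the genes with
    ``n_tests >= 2`` and ``n_tests == 3``.
    """
    support: dict[str, set[str]] = {}
    for test, genes in gene_sets.items():
        for g in genes:
            support.setdefault(g, set()).add(test)
    rows = [
        {"gene": g, "tests": ",".join(sorted(t)), "n_tests": len(t)}
        for g, t in support.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "tests", "n_tests"])
    return df.sort_values(["n_tests", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )


def fst_cutoff_count(windows: pd.DataFrame, cutoff: float = 0.6) -> int:
    """Number of windows with score strictly above ``cutoff``."""
    return int((windows["score"].to_numpy() > cutoff).sum())


def branch_length_comparison(
    focal1: pd.DataFrame, focal2: pd.DataFrame, flag: str = "top1"
) -> tuple[float | None, int]:
    """Share of jointly-outlying windows where focal1's PBS exceeds focal2's.

    Both PBS scans must share the window tiling (same sister/outgroup
    scheme). The overlap is the set of windows flagged in both scans;
    the share uses a strict ``>`` on the window max PBS. Returns
    ``(share, n_overlap)``; share is None when the overlap is empty.
    """
    a = focal1.loc[focal1[flag], ["chrom", "start", "score"]]
    b = focal2.loc[focal2[flag], ["chrom", "start", "score"]]
    merged = a.merge(b, on=["chrom", "start"], suffixes=("_1", "_2"))
    if merged.empty:
        return None, 0
    share = float((merged["score_1"] > merged["score_2"]).mean())
    return share, len(merged)
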