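"""Gene assignment, candidate-list intersection and GO-term enrichment.

A gene is assigned to a flagged window when their intervals overlap by at
least 1 bp; an optional flank (default 10 kb, reporting only) also captures
genes just outside a window, mirroring near-window reporting such as a top
SNP a few kb downstream of a gene with no internal SNP.

Enrichment of a gene set among the top-window genes is summarized by the
expected overlap ``n * K / N`` (selected n, annotated K, universe N) and a
hypergeometric upper tail. GO-term enrichment uses the EASE score: the
one-sided Fisher exact p-value recomputed after removing one gene from the
observed overlap (k' = max(k - 1, 0), margins unchanged), a conservative
penalization that damps single-gene hits; k = 0 gives p = 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneAnnotation, CandidateGeneList

__all__ = [
    "EnrichmentResult",
    "assign_genes",
    "scan_universe",
    "candidate_overlap",
    "fisher_upper_tail",
    "ease_score",
    "go_enrichment",
]

DEFAULT_FLANK = 10_000


@dataclass
class EnrichmentResult:
    """Overlap of a gene list with the top-window genes."""

    name: str
    N: int  # universe size (genes overlapping any scanned window)
    K: int  # list genes within the universe
    n: int  # genes in top windows
    k: int  # observed overlap
    expected: float  # n * K / N
    fisher_p: float
    ease_p: float

    @property
    def ratio(self) -> float:
        return self.k / self.expected if self.expected > 0 else np.nan


def _overlaps(genes: GeneAnnotation, intervals: pd.DataFrame, flank: int = 0) -> np.ndarray:
    """Boolean mask over genes overlapping any interval (chrom, start, end)."""
    g = genes.df
    hit = np.zeros(len(g), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        gm = (g["chrom"] == chrom).to_numpy()
        if not gm.any():
            continue
        gs = g.loc[gm, "start"].to_numpy() - flank
        ge = g.loc[gm, "end"].to_numpy() + flank
        ws = sub["start"].to_numpy()
        we = sub["end"].to_numpy()
        # gene overlaps some window iff any (gs < we) & (ge > ws)
        m = (gs[:, None] < we[None, :]) & (ge[:, None] > ws[None, :])
        hit[np.flatnonzero(gm)] |= m.any(axis=1)
    return hit


def assign_genes(
    flagged: pd.DataFrame,
    genes: GeneAnnotation,
    snp_scores: pd.DataFrame | None = None,
    score_col: str = "score",
    flank: int = 0,
) -> pd.DataFrame:
    """Assign genes to flagged windows (>= 1 bp interval overlap).

    Parameters
    ----------
    flagged
        Flagged window rows (``chrom, start, end, score, rank, ...``).
    snp_scores
        Optional per-SNP table (``chrom, pos, score_col``) used to report
        the max statistic among SNPs inside each gene body; genes with no
        internal SNP are flagged and annotated with the distance to the
        nearest scored SNP.
    flank
        Optional symmetric flank (bp) widening gene intervals for the
        window match -- reporting aid only, keep 0 for enrichment counts.

    Returns
    -------
    DataFrame ``gene, chrom, gene_start, gene_end, n_windows, best_rank,
    window_score, gene_max_score, has_internal_snp, nearest_snp_bp``
    sorted by (best_rank, gene). ``window_score`` is the best flagged
    window's score (the window max for max-type tests).
    """
    g = genes.df
    rows = []
    for chrom, wsub in flagged.groupby("chrom", sort=False):
        gsub = g[g["chrom"] == chrom]
        if gsub.empty:
            continue
        gs = gsub["start"].to_numpy() - flank
        ge = gsub["end"].to_numpy() + flank
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        m = (gs[:, None] < we[None, :]) & (ge[:, None] > ws[None, :])
        for gi in np.flatnonzero(m.any(axis=1)):
            wins = wsub.iloc[np.flatnonzero(m[gi])]
            best = wins.sort_values(["rank", "start"]).iloc[0] if "rank" in wins else wins.iloc[0]
            row = {
                "gene": gsub.iloc[gi]["name"],
                "chrom": chrom,
                "gene_start": int(gsub.iloc[gi]["start"]),
                "gene_end": int(gsub.iloc[gi]["end"]),
                "n_windows": len(wins),
                "best_rank": int(best["rank"]) if "rank" in wins else np.nan,
                "window_score": float(best["score"]),
                "gene_max_score": np.nan,
                "has_internal_snp": False,
                "nearest_snp_bp": np.nan,
            }
            rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "gene_start", "gene_end", "n_windows",
            "best_rank", "window_score", "gene_max_score",
            "has_internal_snp", "nearest_snp_bp",
        ],
    )
    if snp_scores is not None and not df.empty:
        for i, row in df.iterrows():
            sub = snp_scores[
                (snp_scores["chrom"] == row["chrom"])
                & np.isfinite(snp_scores[score_col].to_numpy(dtype=float))
            ]
            if sub.empty:
                continue
            pos0 = sub["pos"].to_numpy() - 1
            inside = (pos0 >= row["gene_start"]) & (pos0 < row["gene_end"])
            if inside.any():
                df.loc[i, "gene_max_score"] = float(
                    sub.loc[inside, score_col].max()
                )
                df.loc[i, "has_internal_snp"] = True
                df.loc[i, "nearest_snp_bp"] = 0
            else:
                d = np.minimum(
                    np.abs(pos0 - row["gene_start"]),
                    np.abs(pos0 - (row["gene_end"] - 1)),
                )
                df.loc[i, "nearest_snp_bp"] = int(d.min())
    return df.sort_values(["best_rank", "gene"]).reset_index(drop=True)


def scan_universe(genes: GeneAnnotation, windows: pd.DataFrame) -> list[str]:
    """The gene universe: genes overlapping at least one scanned window."""
    mask = _overlaps(genes, windows[["chrom", "start", "end"]])
    return sorted(set(genes.df.loc[mask, "name"]))


def fisher_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact upper tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    if k < 0 or n < 0 or K < 0 or k > min(n, K) or n > N or K > N:
        raise ValueError(f"invalid contingency margins k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE score: Fisher upper tail with one gene removed from the overlap
    (k' = max(k - 1, 0)), list margins unchanged. Always >= the Fisher
    p-value; equals 1 for k <= 1, so single-gene overlaps never enrich."""
    if k < 0 or k > min(n, K):
        raise ValueError(f"invalid overlap k={k} for margins n={n}, K={K}")
    return fisher_upper_tail(max(k - 1, 0), n, K, N)


def candidate_overlap(
    selected_genes: set[str] | list[str],
    candidates: CandidateGeneList,
    universe: list[str],
    name: str = "candidates",
) -> EnrichmentResult:
    """Intersect the top-window genes with an a-priori candidate list.

    Candidate genes absent from the scan universe are counted out of the
    intersection (logged); the expected overlap is ``n * K / N`` and
    significance is the hypergeometric upper tail P(X >= k).
    """
    uni = {g.upper() for g in universe}
    sel = {g.upper() for g in selected_genes} & uni
    cand_in = {g for g in candidates.genes if g in uni}
    dropped = len(candidates.genes) - len(cand_in)
    if dropped:
        import logging

        logging.getLogger("andescan").info(
            "%d candidate genes absent from scan universe", dropped
        )
    N, K, n = len(uni), len(cand_in), len(sel)
    k = len(sel & cand_in)
    expected = n * K / N if N else np.nan
    return EnrichmentResult(
        name=name,
        N=N,
        K=K,
        n=n,
        k=k,
        expected=expected,
        fisher_p=fisher_upper_tail(k, n, K, N),
        ease_p=ease_score(k, n, K, N),
    )


def go_enrichment(
    selected_genes: set[str] | list[str],
    gene2term: pd.DataFrame,
    universe: list[str],
    ease_threshold: float = 0.01,
    filter_threshold: bool = True,
) -> pd.DataFrame:
    """Per-GO-term enrichment of the top-window genes.

    ``gene2term`` maps genes to terms (columns ``gene, term_id,
    term_name``); only universe genes count toward margins. Terms with no
    selected gene are excluded. Results carry the ``k/K`` enrichment
    string, EASE and Fisher p-values and a Benjamini-Hochberg column
    (informational; the reported filter is EASE < ``ease_threshold``).
    """
    if gene2term.empty:
        raise ValueError("empty gene-to-term mapping")
    uni = {g.upper() for g in universe}
    sel = {g.upper() for g in selected_genes} & uni
    g2t = gene2term[gene2term["gene"].str.upper().isin(uni)]
    N, n = len(uni), len(sel)
    rows = []
    for (term_id, term_name), sub in g2t.groupby(["term_id", "term_name"], sort=True):
        members = set(sub["gene"].str.upper())
        K = len(members)
        k = len(members & sel)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "K": K,
                "enrichment": f"{k}/{K}",
                "expected": n * K / N,
                "ease_p": ease_score(k, n, K, N),
                "fisher_p": fisher_upper_tail(k, n, K, N),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "K", "enrichment",
            "expected", "ease_p", "fisher_p",
        ],
    )
    if df.empty:
        df["bh_fdr"] = pd.Series(dtype=float)
        return df
    # Benjamini-Hochberg on the EASE p-values, informational only
    p = df["ease_p"].to_numpy()
    order = np.argsort(p, kind="stable")
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i, idx in enumerate(order[::-1]):
        i = m - rank_i  # rank from 1..m, descending pass
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    df["bh_fdr"] = adj
    if filter_threshold:
        df = df[df["ease_p"] < ease_threshold]
    return df.sort_values(["ease_p", "term_id"]).reset_index(drop=True)
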