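"""Allele frequencies, Weir-Cockerham F_ST and the population branch
statistic (PBS).

F_ST follows the two-population variance-components estimator
(Weir & Cockerham 1984), computed from observed heterozygote proportions
(not HWE-expected ones), per SNP:

    r = 2,  nbar = mean(n_i),  n_c = (r nbar - sum n_i^2 / (r nbar)) / (r - 1)
    pbar = sum n_i p_i / (r nbar)
    s2   = sum n_i (p_i - pbar)^2 / ((r - 1) nbar)
    hbar = sum n_i h_i / (r nbar)
    a = (nbar / n_c) [s2 - (pbar(1-pbar) - s2 (r-1)/r - hbar/4) / (nbar - 1)]
    b = (nbar / (nbar - 1)) [pbar(1-pbar) - s2 (r-1)/r - hbar (2 nbar - 1)/(4 nbar)]
    c = hbar / 2
    theta_hat = a / (a + b + c)

The raw estimate may be negative; it is clamped to zero before any
branch-length transform (and the raw value kept for inspection). SNPs
monomorphic in both populations (a + b + c = 0) are undefined and excluded
from windows.

PBS isolates allele-frequency change on the focal branch of a three-taxon
tree: with T = -ln(1 - F_ST) per pair,

    PBS_focal = (T_{focal,sister} + T_{focal,outgroup} - T_{sister,outgroup}) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DataError, HaplotypeMatrix, PopulationPanel, VariantTable

__all__ = [
    "SnpFreqStat",
    "allele_freqs",
    "wc_fst",
    "multilocus_fst",
    "branch_length",
    "pbs",
    "pbs_table",
]

FST_CLAMP_EPS = 1e-12


@dataclass
class SnpFreqStat:
    """Per-SNP, per-population inputs to the variance-components estimator:
    derived-allele frequency ``p``, diploid sample size ``n`` and observed
    heterozygote proportion ``h``."""

    p: dict[str, np.ndarray]
    n: dict[str, int]
    h: dict[str, np.ndarray]

    def populations(self) -> list[str]:
        return list(self.p)


def allele_freqs(
    haps: HaplotypeMatrix,
    panel: PopulationPanel,
    variants: VariantTable | None = None,
    populations: list[str] | None = None,
) -> SnpFreqStat:
    """Per-population derived-allele frequencies and heterozygote proportions.

    ``p_i`` is the derived-allele count over ``2 n_i``; ``h_i`` is the
    fraction of diploids whose two haplotypes differ at the SNP. When a
    variant table is given, columns whose derived allele is REF are flipped
    so that ``p`` always counts the derived allele; without one, ``p``
    counts the allele encoded 1.
    """
    pops = populations if populations is not None else panel.populations()
    flip = None
    if variants is not None:
        flip = ~variants.derived_is_alt()
    p, n, h = {}, {}, {}
    for pop in pops:
        rows = panel.haplotype_rows(haps, pop)
        n_dip = rows.size // 2
        if n_dip < 2:
            raise DataError(f"population {pop!r} has {n_dip} diploids; need >= 2")
        block = haps.values[rows].astype(np.float64)
        pairs = block.reshape(n_dip, 2, -1)
        freq = block.mean(axis=0)
        het = (pairs[:, 0, :] != pairs[:, 1, :]).mean(axis=0)
        if flip is not None:
            freq = np.where(flip, 1.0 - freq, freq)
        p[pop], n[pop], h[pop] = freq, n_dip, het
    return SnpFreqStat(p, n, h)


def wc_components(
    stat: SnpFreqStat, popA: str, popB: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components (a, b, c) of the two-population estimator."""
    nA, nB = stat.n[popA], stat.n[popB]
    pA, pB = stat.p[popA], stat.p[popB]
    hA, hB = stat.h[popA], stat.h[popB]
    r = 2.0
    nbar = (nA + nB) / r
    nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
    pbar = (nA * pA + nB * pB) / (r * nbar)
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (nA * hA + nB * hB) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst(stat: SnpFreqStat, popA: str, popB: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham theta-hat.

    Returns
    -------
    (fst_raw, fst)
        ``fst_raw`` is the raw estimate (may be negative, NaN where
        undefined); ``fst`` is clamped to ``[0, 1]``.
    """
    a, b, c = wc_components(stat, popA, popB)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(denom != 0.0, a / denom, np.nan)
    clamped = np.clip(raw, 0.0, 1.0)
    return raw, clamped


def multilocus_fst(stat: SnpFreqStat, popA: str, popB: str) -> float:
    """Multi-locus (ratio-of-sums) Weir-Cockerham estimate
    ``sum(a) / sum(a + b + c)`` over all defined SNPs — the standard
    genome-wide estimator, unbiased where the mean of per-SNP ratios is not."""
    a, b, c = wc_components(stat, popA, popB)
    denom = a + b + c
    ok = denom != 0.0
    return float(a[ok].sum() / denom[ok].sum())


def branch_length(fst: np.ndarray | float) -> np.ndarray | float:
    """Population-divergence branch length ``T = -ln(1 - F_ST)`` with F_ST
    clamped to ``[0, 1 - 1e-12]`` before the (natural) log."""
    clamped = np.clip(fst, 0.0, 1.0 - FST_CLAMP_EPS)
    return -np.log(1.0 - clamped)


def pbs(
    fst_fs: np.ndarray | float,
    fst_fo: np.ndarray | float,
    fst_so: np.ndarray | float,
) -> np.ndarray | float:
    """PBS of the focal population from the three pairwise F_ST values
    (focal-sister, focal-outgroup, sister-outgroup)."""
    t_fs = branch_length(fst_fs)
    t_fo = branch_length(fst_fo)
    t_so = branch_length(fst_so)
    return (t_fs + t_fo - t_so) / 2.0


def pbs_table(
    stat: SnpFreqStat,
    focal: str,
    sister: str,
    outgroup: str,
    variants: VariantTable | None = None,
) -> pd.DataFrame:
    """Per-SNP F_ST and PBS for a (focal, sister, outgroup) configuration.

    SNPs where any pairwise F_ST is undefined get NaN PBS (excluded from
    windows downstream). PBS itself may be negative.
    """
    if len({focal, sister, outgroup}) != 3:
        raise DataError("focal, sister and outgroup must be three distinct populations")
    raw_fs, fst_fs = wc_fst(stat, focal, sister)
    raw_fo, fst_fo = wc_fst(stat, focal, outgroup)
    raw_so, fst_so = wc_fst(stat, sister, outgroup)
    undefined = np.isnan(raw_fs) | np.isnan(raw_fo) | np.isnan(raw_so)
    t_fs = branch_length(fst_fs)
    t_fo = branch_length(fst_fo)
    t_so = branch_length(fst_so)
    score = (t_fs + t_fo - t_so) / 2.0
    score = np.where(undefined, np.nan, score)
    df = pd.DataFrame(
        {
            "fst_fs_raw": raw_fs,
            "fst_fs": fst_fs,
            "fst_fo": fst_fo,
            "fst_so": fst_so,
            "T_fs": t_fs,
            "T_fo": t_fo,
            "T_so": t_so,
            "pbs": score,
        }
    )
    if variants is not None:
        df.insert(0, "chrom", variants.chrom)
        df.insert(1, "pos", variants.pos)
        df.insert(2, "snp_id", variants.snp_id)
    return df
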