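"""Extended haplotype homozygosity (EHH) statistics: iHS and XP-EHH.

EHH at a marker ``x`` for a set of ``n`` haplotypes carrying a core allele
is the probability that two haplotypes drawn at random from the set are
identical over the span from the core to ``x``:

    EHH(x) = sum_j C(c_j, 2) / C(n, 2)

over the distinct extended haplotypes (counts ``c_j``) spanning core -> x.
The decay curve is evaluated at each successive SNP outward until it drops
below a floor (default 0.05), the chromosome ends, or an inter-SNP gap
exceeds ``gap_max`` (default 200 kb). iHH is the trapezoidal integral of
the curve against physical distance, truncated at the interpolated
floor crossing; left and right contributions are summed.

iHS at a core SNP is ``ln(iHH_ancestral / iHH_derived)``, standardized to
mean 0 / SD 1 within derived-allele-frequency bins (width 0.02, bins with
fewer than 20 SNPs merged with their nearest neighbour). XP-EHH compares
two populations at the same core using allele-pooled EHH (all haplotypes,
core allele included in the span) integrated out to a shared boundary --
the floor crossing of the EHH of the two populations combined -- and is
standardized genome-wide.

Distances are physical bp throughout; the array data this package targets
carries no genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DataError, HaplotypeMatrix, PopulationPanel, VariantTable

__all__ = [
    "EhhCurve",
    "ehh",
    "ihh",
    "ihs_scan",
    "xpehh_scan",
    "standardize_binned",
]

EHH_FLOOR = 0.05
GAP_MAX = 200_000
FREQ_BOUNDS = (0.05, 0.95)
BIN_WIDTH = 0.02
MIN_BIN_SNPS = 20

VALID_FLAGS = frozenset({"ok", "edge"})


@dataclass
class EhhCurve:
    """One-directional EHH decay curve from a core SNP.

    ``distances[0] == 0`` with ``ehh[0] == 1`` (two haplotypes are trivially
    identical over the empty interval); values are non-increasing outward.
    ``stop_reason`` is ``"floor"``, ``"end"`` (chromosome edge) or ``"gap"``
    (inter-SNP gap above ``gap_max``).
    """

    core: int
    allele: int | str
    direction: str
    distances: np.ndarray
    ehh: np.ndarray
    stop_reason: str


def _pair_homozygosity(counts: np.ndarray, n: int) -> float:
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk(
    block: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    subsets: list[np.ndarray],
    include_core: bool,
    floor: float,
    gap_max: float,
    stop_mode: str,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Extend outward from ``core``, tracking EHH for each row subset.

    ``stop_mode``: ``"all"`` stops once every subset's EHH is below the
    floor (each curve is truncated at its own crossing later); ``"last"``
    stops on the final subset only (the pooled boundary used by XP-EHH).
    Returns (distances, ehh matrix of shape (n_subsets, n_points), reason).
    """
    H, M = block.shape
    step = 1 if direction == "right" else -1
    sizes = [s.size for s in subsets]
    codes = (
        block[:, core].astype(np.int64) if include_core else np.zeros(H, dtype=np.int64)
    )
    dists = [0.0]
    series = [[1.0] for _ in subsets]
    reason = "end"
    prev = core
    j = core + step
    while 0 <= j < M:
        if abs(int(positions[j]) - int(positions[prev])) > gap_max:
            reason = "gap"
            break
        key = codes * 2 + block[:, j]
        _, codes = np.unique(key, return_inverse=True)
        vals = []
        for s, n in zip(subsets, sizes):
            counts = np.bincount(codes[s])
            vals.append(_pair_homozygosity(counts, n))
        dists.append(abs(int(positions[j]) - int(positions[core])))
        for lst, v in zip(series, vals):
            lst.append(v)
        hit = (
            all(v < floor for v in vals) if stop_mode == "all" else vals[-1] < floor
        )
        if hit:
            reason = "floor"
            break
        prev = j
        j += step
    return np.asarray(dists, dtype=np.float64), np.asarray(series), reason


def ehh(
    block: np.ndarray,
    positions: np.ndarray,
    core: int,
    allele: int | str = 1,
    direction: str = "right",
    floor: float = EHH_FLOOR,
    gap_max: float = GAP_MAX,
) -> EhhCurve:
    """EHH decay curve for one core SNP in one population slice.

    Parameters
    ----------
    block : (H, M) array
        Binary haplotypes of the population.
    positions : (M,) array
        Physical positions (monotone increasing).
    core : int
        Core SNP column.
    allele : {0, 1, "pooled"}
        Condition on carriers of this core allele, or pool all haplotypes
        (the core allele then participates in the extended-haplotype span).
    direction : {"left", "right"}
    floor : float
        Stop once EHH drops below this (0 walks to the chromosome end).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if allele == "pooled":
        subset = np.arange(block.shape[0])
        include_core = True
    else:
        subset = np.flatnonzero(block[:, core] == allele)
        include_core = False
    if subset.size < 2:
        raise DataError(
            f"need >= 2 haplotypes carrying core allele (got {subset.size})"
        )
    sub_block = block[subset]
    dists, series, reason = _walk(
        sub_block,
        positions,
        core,
        direction,
        [np.arange(subset.size)],
        include_core,
        floor,
        gap_max,
        stop_mode="all",
    )
    return EhhCurve(core, allele, direction, dists, series[0], reason)


def _area_to_floor(
    dists: np.ndarray, vals: np.ndarray, floor: float, reason: str
) -> tuple[float, str]:
    """Trapezoidal area of one directional curve, truncated at the
    interpolated floor crossing. Status: "ok" if the floor was reached,
    else "edge" (chromosome end) or "gap"."""
    below = np.flatnonzero(vals < floor)
    if below.size:
        i = int(below[0])
        x0, y0 = dists[i - 1], vals[i - 1]
        x1, y1 = dists[i], vals[i]
        xc = x0 + (y0 - floor) * (x1 - x0) / (y0 - y1)
        d = np.concatenate([dists[:i], [xc]])
        v = np.concatenate([vals[:i], [floor]])
        return float(np.trapezoid(v, d)), "ok"
    status = "edge" if reason == "end" else ("gap" if reason == "gap" else "ok")
    return float(np.trapezoid(vals, dists)), status


def ihh(
    left: EhhCurve, right: EhhCurve, floor: float = EHH_FLOOR
) -> tuple[float, str]:
    """Integrated EHH: summed left+right trapezoidal areas in bp units.

    Returns (area, flag) with flag "ok", "edge" (one-sided chromosome-end
    truncation, score kept), "gap" (invalid) or "zero_area" (invalid).
    """
    area_l, st_l = _area_to_floor(left.distances, left.ehh, floor, left.stop_reason)
    area_r, st_r = _area_to_floor(right.distances, right.ehh, floor, right.stop_reason)
    area = area_l + area_r
    if "gap" in (st_l, st_r):
        return area, "gap"
    if area <= 0.0:
        return area, "zero_area"
    if "edge" in (st_l, st_r):
        return area, "edge"
    return area, "ok"


def _combine_flags(*flags: str) -> str:
    for bad in ("gap", "zero_area"):
        if bad in flags:
            return bad
    if "edge" in flags:
        return "edge"
    return "ok"


def standardize_binned(
    values: np.ndarray,
    freqs: np.ndarray,
    valid: np.ndarray,
    bin_width: float = BIN_WIDTH,
    min_bin: int = MIN_BIN_SNPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize scores to mean 0 / SD 1 within frequency bins.

    Bins are ``floor(freq / bin_width)``; bins holding fewer than
    ``min_bin`` valid scores are merged with their nearest neighbouring bin
    (ties broken toward the lower bin) until all satisfy the floor or one
    bin remains. Returns (standardized values, merged bin id per SNP);
    invalid entries get NaN.
    """
    std = np.full(values.shape, np.nan)
    bin_id = np.full(values.shape, -1, dtype=np.int64)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return std, bin_id
    raw_bin = np.floor(freqs[idx] / bin_width).astype(np.int64)
    # group structure: ordered list of groups, each a list of raw bin labels
    labels = sorted(set(raw_bin.tolist()))
    groups = [[b] for b in labels]

    def count(group):
        return int(np.isin(raw_bin, group).sum())

    while len(groups) > 1:
        counts = [count(g) for g in groups]
        deficient = [i for i, c in enumerate(counts) if c < min_bin]
        if not deficient:
            break
        i = deficient[0]
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            # nearest neighbour by bin-label distance; tie -> lower
            d_left = min(abs(a - b) for a in groups[i] for b in groups[i - 1])
            d_right = min(abs(a - b) for a in groups[i] for b in groups[i + 1])
            j = i - 1 if d_left <= d_right else i + 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        del groups[hi]
    for gi, group in enumerate(groups):
        mask = np.isin(raw_bin, group)
        members = idx[mask]
        bin_id[members] = gi
        x = values[members]
        mu = x.mean()
        sd = x.std()
        if sd > 0:
            std[members] = (x - mu) / sd
    return std, bin_id


def _derived_block(
    haps: HaplotypeMatrix,
    variants: VariantTable,
    rows: np.ndarray,
    cols: np.ndarray,
) -> np.ndarray:
    """Population slice re-encoded so 1 = derived allele."""
    block = haps.values[np.ix_(rows, cols)]
    flip = ~variants.derived_is_alt()[cols]
    return np.where(flip[None, :], 1 - block, block).astype(np.uint8)


def ihs_scan(
    haps: HaplotypeMatrix,
    variants: VariantTable,
    panel: PopulationPanel,
    population: str,
    floor: float = EHH_FLOOR,
    gap_max: float = GAP_MAX,
    freq_bounds: tuple[float, float] = FREQ_BOUNDS,
    bin_width: float = BIN_WIDTH,
    min_bin: int = MIN_BIN_SNPS,
) -> pd.DataFrame:
    """iHS scan of one population.

    Cores are SNPs with known ancestral allele and derived frequency inside
    ``freq_bounds``. ``ihs_unstd = ln(iHH_A / iHH_D)`` (A = ancestral-allele
    carriers, D = derived); ``ihs_std`` standardizes within derived-frequency
    bins. Flags: "ok"/"edge" valid; "low_freq", "no_polarization", "n_core",
    "gap", "zero_area" invalid (NaN standardized score).
    """
    rows = panel.haplotype_rows(haps, population)
    if rows.size < 4:
        raise DataError(f"population {population!r} too small for iHS")
    known = variants.ancestral_known()
    records = []
    for chrom in variants.chromosomes():
        cols = np.flatnonzero(variants.chrom == chrom)
        block = _derived_block(haps, variants, rows, cols)
        positions = variants.pos[cols]
        ids = variants.snp_id[cols]
        dfreq = block.mean(axis=0)
        for m in range(cols.size):
            rec = {
                "chrom": chrom,
                "pos": int(positions[m]),
                "snp_id": ids[m],
                "dfreq": float(dfreq[m]),
                "ihh_a": np.nan,
                "ihh_d": np.nan,
                "ihs_unstd": np.nan,
                "flag": "ok",
            }
            records.append(rec)
            if not known[cols[m]]:
                rec["flag"] = "no_polarization"
                continue
            if not (freq_bounds[0] <= dfreq[m] <= freq_bounds[1]):
                rec["flag"] = "low_freq"
                continue
            der = np.flatnonzero(block[:, m] == 1)
            anc = np.flatnonzero(block[:, m] == 0)
            if der.size < 2 or anc.size < 2:
                rec["flag"] = "n_core"
                continue
            flags = []
            areas = {}
            dl, sl, rl = _walk(
                block, positions, m, "left", [anc, der], False, floor, gap_max, "all"
            )
            dr, sr, rr = _walk(
                block, positions, m, "right", [anc, der], False, floor, gap_max, "all"
            )
            for name, si in (("a", 0), ("d", 1)):
                area, flag = ihh(
                    EhhCurve(m, name, "left", dl, sl[si], rl),
                    EhhCurve(m, name, "right", dr, sr[si], rr),
                    floor,
                )
                areas[name] = area
                flags.append(flag)
            rec["ihh_a"], rec["ihh_d"] = areas["a"], areas["d"]
            rec["flag"] = _combine_flags(*flags)
            if rec["flag"] in VALID_FLAGS:
                rec["ihs_unstd"] = float(np.log(areas["a"] / areas["d"]))
    df = pd.DataFrame.from_records(records)
    valid = df["flag"].isin(VALID_FLAGS).to_numpy() & np.isfinite(
        df["ihs_unstd"].to_numpy()
    )
    std, bin_id = standardize_binned(
        df["ihs_unstd"].to_numpy(), df["dfreq"].to_numpy(), valid, bin_width, min_bin
    )
    df["ihs_std"] = std
    df["freq_bin"] = bin_id
    df["valid"] = np.isfinite(std)
    return df


def xpehh_scan(
    haps: HaplotypeMatrix,
    variants: VariantTable,
    panel: PopulationPanel,
    popA: str,
    popB: str,
    floor: float = EHH_FLOOR,
    gap_max: float = GAP_MAX,
) -> pd.DataFrame:
    """XP-EHH scan of ``popA`` against ``popB``.

    At each core, allele-pooled EHH is integrated in each population out to
    the shared boundary where the EHH of both populations combined crosses
    the floor; ``xpehh_unstd = ln(iHH_A / iHH_B)`` is standardized
    genome-wide. Positive standardized scores mean longer haplotype
    homozygosity in ``popA``.
    """
    rows_a = panel.haplotype_rows(haps, popA)
    rows_b = panel.haplotype_rows(haps, popB)
    if rows_a.size < 2 or rows_b.size < 2:
        raise DataError("both populations need >= 2 haplotypes for XP-EHH")
    rows = np.concatenate([rows_a, rows_b])
    sub_a = np.arange(rows_a.size)
    sub_b = np.arange(rows_a.size, rows.size)
    sub_all = np.arange(rows.size)
    records = []
    for chrom in variants.chromosomes():
        cols = np.flatnonzero(variants.chrom == chrom)
        block = _derived_block(haps, variants, rows, cols)
        positions = variants.pos[cols]
        ids = variants.snp_id[cols]
        for m in range(cols.size):
            rec = {
                "chrom": chrom,
                "pos": int(positions[m]),
                "snp_id": ids[m],
                "ihh_pop1": np.nan,
                "ihh_pop2": np.nan,
                "xpehh_unstd": np.nan,
                "flag": "ok",
            }
            records.append(rec)
            dl, sl, rl = _walk(
                block, positions, m, "left", [sub_a, sub_b, sub_all], True,
                floor, gap_max, "last",
            )
            dr, sr, rr = _walk(
                block, positions, m, "right", [sub_a, sub_b, sub_all], True,
                floor, gap_max, "last",
            )
            areas = {"a": 0.0, "b": 0.0}
            side_flags = []
            for dists, series, reason in ((dl, sl, rl), (dr, sr, rr)):
                # shared boundary: floor crossing of the combined curve
                comb = series[2]
                below = np.flatnonzero(comb < floor)
                if below.size:
                    i = int(below[0])
                    x0, y0 = dists[i - 1], comb[i - 1]
                    x1, y1 = dists[i], comb[i]
                    xb = x0 + (y0 - floor) * (x1 - x0) / (y0 - y1)
                    side_flags.append("ok")
                else:
                    xb = dists[-1]
                    side_flags.append(
                        "edge" if reason == "end" else ("gap" if reason == "gap" else "ok")
                    )
                for name, si in (("a", 0), ("b", 1)):
                    areas[name] += _integrate_to(dists, series[si], xb)
            flag = _combine_flags(*side_flags)
            if areas["a"] <= 0.0 or areas["b"] <= 0.0:
                flag = "zero_area"
            rec["ihh_pop1"], rec["ihh_pop2"] = areas["a"], areas["b"]
            rec["flag"] = flag
            if flag in VALID_FLAGS:
                rec["xpehh_unstd"] = float(np.log(areas["a"] / areas["b"]))
    df = pd.DataFrame.from_records(records)
    vals = df["xpehh_unstd"].to_numpy()
    valid = df["flag"].isin(VALID_FLAGS).to_numpy() & np.isfinite(vals)
    std = np.full(vals.shape, np.nan)
    if valid.sum() >= 2 and vals[valid].std() > 0:
        std[valid] = (vals[valid] - vals[valid].mean()) / vals[valid].std()
    df["xpehh_std"] = std
    df["valid"] = np.isfinite(std)
    return df


def _integrate_to(dists: np.ndarray, vals: np.ndarray, xb: float) -> float:
    """Trapezoidal area of a piecewise-linear curve truncated at ``xb``."""
    if xb <= 0:
        return 0.0
    inside = dists <= xb
    d = dists[inside]
    v = vals[inside]
    if d[-1] < xb and inside.sum() < dists.size:
        i = int(inside.sum())  # first point beyond xb
        x0, y0 = dists[i - 1], vals[i - 1]
        x1, y1 = dists[i], vals[i]
        yb = y0 + (y1 - y0) * (xb - x0) / (x1 - x0)
        d = np.concatenate([d, [xb]])
        v = np.concatenate([v, [yb]])
    return float(np.trapezoid(v, d))
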