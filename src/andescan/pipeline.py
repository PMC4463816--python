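"""End-to-end orchestration: load -> scan -> windows -> outliers -> genes
-> enrichment, with a machine-readable run manifest.

The full scan design mirrors the study setup: an intermediate-altitude
focal population scanned with four tests; iHS outliers screened against a
lowland control's top 5% (signals shared with the control are unlikely to
be altitude-driven); XP-EHH and F_ST contrasting focal vs sister; PBS on
the (focal, sister, outgroup) tree; top-1% windows intersected with an
a-priori candidate list and screened for GO-term enrichment at
EASE < 0.01.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import enrichment as enr
from . import freq as fq
from . import haplotype as hap
from . import io as gio
from . import windows as win
from .containers import (
    CandidateGeneList,
    ConfigError,
    GeneAnnotation,
    HaplotypeMatrix,
    PopulationPanel,
    VariantTable,
)

logger = logging.getLogger("andescan")

__all__ = ["ScanParams", "ScanConfig", "ScanResult", "scan", "run_scan"]

ALL_TESTS = ("ihs", "xpehh", "fst", "pbs")


@dataclass
class ScanParams:
    """Tunable scan parameters (defaults follow the study design)."""

    tests: tuple[str, ...] = ALL_TESTS
    hap_window: int = 200_000  # iHS / XP-EHH window width, bp
    freq_window: int = 100_000  # F_ST / PBS window width, bp
    top1: float = 0.01
    top5: float = 0.05
    ihs_abs_threshold: float = 2.0
    ehh_floor: float = 0.05
    gap_max: int = 200_000
    bin_floor: int = 50
    fst_cutoff: float = 0.6
    ease_threshold: float = 0.01
    gene_flank: int = 0  # widen gene intervals for window matching (report only)

    def __post_init__(self) -> None:
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ConfigError(f"unknown tests: {sorted(unknown)}")
        if not (0 < self.top1 <= self.top5 <= 1):
            raise ConfigError("need 0 < top1 <= top5 <= 1")
        if min(self.hap_window, self.freq_window) <= 0:
            raise ConfigError("window widths must be positive")


@dataclass
class ScanConfig:
    """ScanParams plus input paths and role bindings, for the CLI."""

    vcf: str
    panel: str
    out: str
    genes: str | None = None
    candidates: str | None = None
    gene2term: str | None = None
    focal: str | None = None
    sister: str | None = None
    control: str | None = None
    outgroup: str | None = None
    params: ScanParams = field(default_factory=ScanParams)
    vcf_mode: str = "strict"
    seed: int = 0


@dataclass
class ScanResult:
    tables: dict[str, pd.DataFrame]
    summary: dict
    manifest: dict


def _require_roles(panel: PopulationPanel, tests, *needed: str) -> None:
    for role in needed:
        if role not in panel.roles:
            raise ConfigError(
                f"tests {tests} require role {role!r} to be bound to a population"
            )


def scan(
    variants: VariantTable,
    haps: HaplotypeMatrix,
    panel: PopulationPanel,
    genes: GeneAnnotation | None = None,
    candidates: CandidateGeneList | None = None,
    gene2term: pd.DataFrame | None = None,
    params: ScanParams | None = None,
) -> ScanResult:
    """Run the configured selection scans on in-memory data.

    Returns a :class:`ScanResult` whose ``tables`` hold every per-SNP,
    per-window, gene-level and enrichment table, and whose ``summary``
    carries the scan-level counts (outlier windows, exclusion removals,
    F_ST-cutoff windows, multi-test gene overlaps, candidate enrichment).
    """
    p = params or ScanParams()
    tests = tuple(p.tests)
    panel.validate_against(haps)
    if "pbs" in tests:
        _require_roles(panel, tests, "focal", "sister", "outgroup")
        if len({panel.role("focal"), panel.role("sister"), panel.role("outgroup")}) != 3:
            raise ConfigError("focal, sister and outgroup must be distinct for PBS")
    if "xpehh" in tests or "fst" in tests:
        _require_roles(panel, tests, "focal", "sister")
    if "ihs" in tests:
        _require_roles(panel, tests, "focal")

    tables: dict[str, pd.DataFrame] = {}
    window_tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"tests": list(tests), "n_variants": int(variants.n_variants)}

    focal = panel.roles.get("focal")
    sister = panel.roles.get("sister")

    need_freq = {"fst", "pbs"} & set(tests)
    if need_freq:
        pops = {focal, sister}
        if "pbs" in tests:
            pops.add(panel.role("outgroup"))
        stat = fq.allele_freqs(haps, panel, variants, sorted(pops - {None}))

    if "ihs" in tests:
        snp = hap.ihs_scan(
            haps, variants, panel, focal,
            floor=p.ehh_floor, gap_max=p.gap_max,
        )
        tables["snp_ihs"] = snp
        w = win.window_scores(snp, p.hap_window, "ihs_std", "prop_extreme", p.ihs_abs_threshold)
        w = win.call_outliers(win.bin_by_snp_count(w, p.bin_floor), p.top1, p.top5)
        window_tables["ihs"] = w
        if "control" in panel.roles:
            control = panel.role("control")
            snp_c = hap.ihs_scan(
                haps, variants, panel, control,
                floor=p.ehh_floor, gap_max=p.gap_max,
            )
            tables["snp_ihs_control"] = snp_c
            wc = win.window_scores(
                snp_c, p.hap_window, "ihs_std", "prop_extreme", p.ihs_abs_threshold
            )
            wc = win.call_outliers(win.bin_by_snp_count(wc, p.bin_floor), p.top1, p.top5)
            window_tables["ihs_control"] = wc
            retained = win.exclusion_filter(w, wc)
            summary["ihs_excluded"] = int(w["top1"].sum()) - len(retained)
        else:
            retained = w[w["top1"]].reset_index(drop=True)
            summary["ihs_excluded"] = None
        tables["windows_ihs"] = w
        tables["windows_ihs_retained"] = retained

    if "xpehh" in tests:
        snp = hap.xpehh_scan(
            haps, variants, panel, focal, sister,
            floor=p.ehh_floor, gap_max=p.gap_max,
        )
        tables["snp_xpehh"] = snp
        w = win.window_scores(snp, p.hap_window, "xpehh_std", "max")
        w = win.call_outliers(win.bin_by_snp_count(w, p.bin_floor), p.top1, p.top5)
        window_tables["xpehh"] = w
        tables["windows_xpehh"] = w

    if "fst" in tests:
        raw, clamped = fq.wc_fst(stat, focal, sister)
        snp = pd.DataFrame(
            {
                "chrom": variants.chrom,
                "pos": variants.pos,
                "snp_id": variants.snp_id,
                "fst_raw": raw,
                "fst": clamped,  # NaN where undefined propagates through clip
            }
        )
        tables["snp_fst"] = snp
        w = win.window_scores(snp, p.freq_window, "fst", "max")
        w = win.call_outliers(win.bin_by_snp_count(w, p.bin_floor), p.top1, p.top5)
        window_tables["fst"] = w
        tables["windows_fst"] = w
        summary["fst_windows_above_cutoff"] = win.fst_cutoff_count(w, p.fst_cutoff)

    if "pbs" in tests:
        snp = fq.pbs_table(
            stat, focal, sister, panel.role("outgroup"), variants
        )
        tables["snp_pbs"] = snp
        w = win.window_scores(snp, p.freq_window, "pbs", "max")
        w = win.call_outliers(win.bin_by_snp_count(w, p.bin_floor), p.top1, p.top5)
        window_tables["pbs"] = w
        tables["windows_pbs"] = w

    for test, w in window_tables.items():
        summary[f"{test}_n_windows"] = len(w)
        summary[f"{test}_top1"] = int(w["top1"].sum())

    if genes is not None:
        snp_score_col = {"ihs": ("snp_ihs", "ihs_std"), "xpehh": ("snp_xpehh", "xpehh_std"),
                         "fst": ("snp_fst", "fst"), "pbs": ("snp_pbs", "pbs")}
        gene_sets: dict[str, set[str]] = {}
        gene_frames = []
        for test in tests:
            key = "windows_ihs_retained" if test == "ihs" else f"windows_{test}"
            flagged = tables[key]
            flagged = flagged[flagged["top1"]] if "top1" in flagged else flagged
            snp_name, col = snp_score_col[test]
            hits = enr.assign_genes(
                flagged, genes, tables.get(snp_name), col, flank=p.gene_flank
            )
            hits.insert(0, "test", test)
            gene_frames.append(hits)
            gene_sets[test] = set(hits["gene"])
        tables["genes"] = (
            pd.concat(gene_frames, ignore_index=True)
            if gene_frames
            else pd.DataFrame()
        )
        overlap = win.cross_test_overlap(gene_sets)
        tables["gene_overlap"] = overlap
        summary["genes_ge2_tests"] = int((overlap["n_tests"] >= 2).sum())
        summary["genes_eq3_tests"] = int((overlap["n_tests"] == 3).sum())

        # universe: genes overlapping any scanned window (haplotype tiling
        # for haplotype tests is a superset of the freq tiling windows)
        any_windows = pd.concat(
            [w[["chrom", "start", "end"]] for w in window_tables.values()],
            ignore_index=True,
        ).drop_duplicates()
        universe = enr.scan_universe(genes, any_windows)
        summary["universe_size"] = len(universe)

        if candidates is not None:
            cand_rows = []
            for test in tests:
                res = enr.candidate_overlap(
                    gene_sets[test], candidates, universe, name=test
                )
                cand_rows.append(asdict_result(res))
            tables["enrichment_candidates"] = pd.DataFrame(cand_rows)
        if gene2term is not None:
            go_frames = []
            for test in tests:
                if test == "fst":
                    continue  # GO screening covers the iHS/XP-EHH/PBS sets
                df = enr.go_enrichment(
                    gene_sets[test], gene2term, universe, p.ease_threshold
                )
                df.insert(0, "test", test)
                go_frames.append(df)
            tables["enrichment_go"] = pd.concat(go_frames, ignore_index=True)

    manifest = {
        "andescan_version": __version__,
        "params": asdict(p),
        "roles": dict(panel.roles),
        "populations": {pop: panel.size(pop) for pop in panel.populations()},
        "summary": summary,
    }
    return ScanResult(tables=tables, summary=summary, manifest=manifest)


def asdict_result(res: enr.EnrichmentResult) -> dict:
    d = asdict(res)
    d["ratio"] = res.ratio
    return d


def run_scan(config: ScanConfig) -> ScanResult:
    """Load inputs from disk, run :func:`scan`, and write all outputs
    (tables, manifest, overview figure) under ``config.out``.

    Identical config + inputs produce byte-identical outputs.
    """
    panel = gio.read_panel(config.panel).with_roles(
        focal=config.focal,
        sister=config.sister,
        control=config.control,
        outgroup=config.outgroup,
    )
    variants, haps = gio.read_phased_vcf(config.vcf, panel, mode=config.vcf_mode)
    genes = gio.read_gene_bed(config.genes) if config.genes else None
    candidates = (
        gio.read_candidate_list(config.candidates) if config.candidates else None
    )
    gene2term = gio.read_gene2term(config.gene2term) if config.gene2term else None

    result = scan(variants, haps, panel, genes, candidates, gene2term, config.params)

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_scan_results(result.tables, outdir)
    result.manifest["inputs"] = {
        "vcf": str(config.vcf),
        "panel": str(config.panel),
        "genes": str(config.genes) if config.genes else None,
        "candidates": str(config.candidates) if config.candidates else None,
        "gene2term": str(config.gene2term) if config.gene2term else None,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    try:
        from .plotting import plot_window_scores

        window_tables = {
            name.removeprefix("windows_"): tbl
            for name, tbl in result.tables.items()
            if name.startswith("windows_") and not name.endswith("_retained")
        }
        if window_tables:
            plot_window_scores(window_tables, outdir / "window_scores.png")
    except Exception as exc:  # plotting is best-effort
        logger.warning("overview figure failed: %s", exc)
    return result
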