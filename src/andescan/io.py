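"""Readers and writers for phased genotypes, panels, annotations and results.

Formats owned by this module:

* phased VCF (read via :mod:`cyvcf2`, written as plain text),
* a plain haplotype-matrix text format for small fixtures,
* panel TSV (``sample_id<TAB>population``),
* BED4 gene annotations,
* candidate-gene lists (one symbol per line),
* gene-to-term TSV (``gene<TAB>term_id<TAB>term_name``),
* scan-result TSVs (deterministic row order, floats at 6 significant digits).

Parse -> write -> parse is the identity on every format here; strict mode
never silently drops records, lenient mode logs exact drop counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CandidateGeneList,
    DataError,
    GeneAnnotation,
    HaplotypeMatrix,
    PopulationPanel,
    VariantTable,
)

logger = logging.getLogger("andescan")

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_haplotype_text",
    "write_haplotype_text",
    "read_panel",
    "write_panel",
    "read_gene_bed",
    "write_gene_bed",
    "read_candidate_list",
    "write_candidate_list",
    "read_gene2term",
    "write_scan_results",
]


def read_phased_vcf(
    path: str | Path,
    panel: PopulationPanel | None = None,
    mode: str = "strict",
) -> tuple[VariantTable, HaplotypeMatrix]:
    """Read a phased VCF into a variant table and haplotype matrix.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    panel
        If given, all panel samples must be present; haplotype rows follow
        the panel's sample order. Without a panel, VCF sample order is used.
    mode
        ``"strict"`` raises on unphased or multiallelic records;
        ``"lenient"`` drops them and logs the count.

    Returns
    -------
    (VariantTable, HaplotypeMatrix)
        Columns ordered by (chrom, pos). The ancestral allele is read from
        the ``AA`` INFO tag when present, else recorded as ``"unknown"``.
        A ``1`` in the matrix encodes the ALT allele (polarization to
        derived/ancestral is done downstream from the variant table).
    """
    from cyvcf2 import VCF

    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if panel is not None:
        missing = [s for s in panel.samples() if s not in vcf_samples]
        if missing:
            raise DataError(f"panel samples missing from VCF: {missing[:5]}")
        samples = panel.samples()
    else:
        samples = vcf_samples
    col_of = {s: vcf_samples.index(s) for s in samples}
    order = np.asarray([col_of[s] for s in samples], dtype=np.intp)

    rows = []
    hap_cols: list[np.ndarray] = []
    n_dropped_multi = 0
    n_dropped_unphased = 0
    for var in vcf:
        if len(var.ALT) != 1:
            if mode == "strict":
                raise DataError(
                    f"multiallelic record at {var.CHROM}:{var.POS} (strict mode)"
                )
            n_dropped_multi += 1
            continue
        gt = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        gt = gt[order]
        if np.any(gt[:, 0] < 0) or np.any(gt[:, 1] < 0):
            if mode == "strict":
                raise DataError(
                    f"missing genotype at {var.CHROM}:{var.POS} (strict mode)"
                )
            n_dropped_unphased += 1
            continue
        if not np.all(gt[:, 2] == 1):
            if mode == "strict":
                raise DataError(
                    f"unphased genotype at {var.CHROM}:{var.POS} (strict mode)"
                )
            n_dropped_unphased += 1
            continue
        aa = var.INFO.get("AA")
        aa = aa if aa in (var.REF, var.ALT[0]) else "unknown"
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "snp_id": var.ID if var.ID else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
                "ancestral_allele": aa,
            }
        )
        hap_cols.append(gt[:, :2].reshape(-1).astype(np.uint8))
    vcf.close()
    if n_dropped_multi or n_dropped_unphased:
        logger.warning(
            "lenient VCF parse dropped %d multiallelic and %d unphased/missing records",
            n_dropped_multi,
            n_dropped_unphased,
        )
    if not rows:
        raise DataError(f"no usable biallelic phased records in {path}")

    vt = pd.DataFrame(rows)
    # stable sort keeps input order within equal (chrom, pos); construction
    # then enforces strictly increasing positions per chromosome
    key = np.lexsort((vt["pos"].to_numpy(), vt["chrom"].to_numpy()))
    vt = vt.iloc[key].reset_index(drop=True)
    values = np.stack(hap_cols, axis=1)[:, key]
    return VariantTable(vt), HaplotypeMatrix(values, samples)


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_phased_vcf(
    path: str | Path,
    variants: VariantTable,
    haps: HaplotypeMatrix,
) -> None:
    """Write a phased VCF (plain text, deterministic byte-for-byte)."""
    df = variants.df
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in variants.chromosomes():
            sub = df[df["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(haps.sample_ids)
            + "\n"
        )
        values = haps.values
        for m in range(variants.n_variants):
            row = df.iloc[m]
            info = (
                f"AA={row.ancestral_allele}"
                if row.ancestral_allele != "unknown"
                else "."
            )
            gts = values[:, m].reshape(-1, 2)
            gt_str = "\t".join(f"{a}|{b}" for a, b in gts)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{info}\tGT\t{gt_str}\n"
            )


def write_haplotype_text(
    path: str | Path, variants: VariantTable, haps: HaplotypeMatrix
) -> None:
    """Write the plain haplotype-matrix fixture format.

    Line 1: ``#samples`` + sample ids; line 2: ``#pos`` + 1-based positions;
    line 3: SNP ids; then one row of 0/1 characters per haplotype.
    """
    with open(path, "w") as fh:
        fh.write("#samples\t" + "\t".join(haps.sample_ids) + "\n")
        fh.write("#pos\t" + "\t".join(str(p) for p in variants.pos) + "\n")
        fh.write("\t".join(variants.snp_id) + "\n")
        for row in haps.values:
            fh.write("".join(str(int(v)) for v in row) + "\n")


def read_haplotype_text(path: str | Path) -> tuple[VariantTable, HaplotypeMatrix]:
    """Read the plain haplotype-matrix fixture format (single chromosome
    ``"1"``, alleles A (ancestral/0) and T (derived/1))."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 4 or not lines[0].startswith("#samples"):
        raise DataError(f"malformed haplotype text file {path}")
    samples = lines[0].split("\t")[1:]
    pos = [int(x) for x in lines[1].split("\t")[1:]]
    snp_ids = lines[2].split("\t")
    values = np.asarray(
        [[int(c) for c in ln] for ln in lines[3:]], dtype=np.uint8
    )
    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": "1",
                "pos": pos,
                "snp_id": snp_ids,
                "ref": "A",
                "alt": "T",
                "ancestral_allele": "A",
            }
        )
    )
    return vt, HaplotypeMatrix(values, samples)


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a sample->population panel TSV with header
    ``sample_id<TAB>population``. Role bindings are supplied separately."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ("sample_id", "population")
    if any(c not in df.columns for c in need):
        raise DataError(f"panel must have columns {need}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample_id {dup!r} in panel")
    if df["population"].isna().any() or (df["population"].str.len() == 0).any():
        raise DataError("empty population label in panel")
    return PopulationPanel(dict(zip(df["sample_id"], df["population"])))


def write_panel(path: str | Path, panel: PopulationPanel) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in panel.assignments.items():
            fh.write(f"{s}\t{p}\n")


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    """Read a BED4+ gene annotation; intervals validated and sorted."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{i}: BED line has < 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{i}: non-integer coordinates") from exc
            if start >= end:
                raise DataError(f"{path}:{i}: start {start} >= end {end}")
            rows.append(
                {"chrom": parts[0], "start": start, "end": end, "name": parts[3]}
            )
    if not rows:
        raise DataError(f"no intervals in {path}")
    return GeneAnnotation(pd.DataFrame(rows))


def write_gene_bed(path: str | Path, genes: GeneAnnotation) -> None:
    genes.df.to_csv(path, sep="\t", header=False, index=False, columns=["chrom", "start", "end", "name"])


def read_candidate_list(path: str | Path) -> CandidateGeneList:
    with open(path) as fh:
        genes = {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
    return CandidateGeneList(genes)


def write_candidate_list(path: str | Path, candidates: CandidateGeneList) -> None:
    with open(path, "w") as fh:
        for g in sorted(candidates.genes):
            fh.write(g + "\n")


def read_gene2term(path: str | Path) -> pd.DataFrame:
    """Read a gene-to-GO-term mapping TSV with columns
    ``gene, term_id, term_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ("gene", "term_id", "term_name")
    if any(c not in df.columns for c in need):
        raise DataError(f"gene2term must have columns {need}")
    df["gene"] = df["gene"].str.upper()
    return df


def _format_float(x) -> str:
    if pd.isna(x):
        return "NA"
    return f"{x:.6g}"


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write a TSV with floats at 6 significant digits and NA for missing."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_scan_results(results: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write per-SNP, per-window, gene and enrichment tables to a directory.

    ``results`` maps a table name (e.g. ``"snp_ihs"``, ``"windows_pbs"``,
    ``"genes"``, ``"enrichment_go"``) to a DataFrame. Row order must already
    be deterministic (chrom, pos / chrom, start); reruns on identical inputs
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        path = outdir / f"{name}.tsv"
        write_table(path, results[name])
        written.append(path)
    return written
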