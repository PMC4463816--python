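"""Synthetic phased multi-population SNP-array data.

The generator produces the statistical structure the selection scans
assume, without a coalescent machinery:

* allele frequencies drift along a rooted population tree under the
  Balding-Nichols model (child frequency ~ Beta with mean equal to the
  parent frequency and variance ``F * p * (1 - p)`` for edge drift ``F``);
* ascertainment of array SNPs is mimicked by bounding ancestral
  frequencies away from 0 and 1;
* linkage disequilibrium comes from a founder-copying model: each sample
  haplotype is a mosaic of a small pool of founder haplotypes, switching
  founders between adjacent SNPs with probability
  ``1 - exp(-switch_rate * distance_bp)``;
* selective sweeps are stamped in by copying one founder haplotype around
  a core SNP into other haplotypes until a target derived frequency is
  reached, with exponentially distributed copied-tract lengths.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning (one substream per chromosome and
per population), so every fixture is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CandidateGeneList,
    ConfigError,
    GeneAnnotation,
    HaplotypeMatrix,
    PopulationPanel,
    VariantTable,
)
from . import io as gio

__all__ = [
    "TreeEdge",
    "PopulationTree",
    "SweepSpec",
    "ScenarioConfig",
    "default_tree",
    "default_config",
    "simulate_frequencies",
    "simulate_haplotypes",
    "inject_sweep",
    "generate_dataset",
]

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TreeEdge:
    parent: str
    child: str
    F: float  # Balding-Nichols drift along this edge, in [0, 1)


@dataclass
class PopulationTree:
    """Rooted population tree; leaves are population labels, each edge
    carries a drift parameter ``F`` in [0, 1)."""

    root: str
    edges: list[TreeEdge]

    def __post_init__(self) -> None:
        children = [e.child for e in self.edges]
        if len(set(children)) != len(children):
            raise ConfigError("tree child labels must be unique")
        for e in self.edges:
            if not (0.0 <= e.F < 1.0):
                raise ConfigError(f"edge {e.parent}->{e.child}: F={e.F} not in [0, 1)")
        parents = {e.parent for e in self.edges}
        known = parents | set(children) | {self.root}
        if any(e.parent not in known for e in self.edges):
            raise ConfigError("edge parent not reachable from root")

    def leaves(self) -> list[str]:
        parents = {e.parent for e in self.edges}
        return [e.child for e in self.edges if e.child not in parents]

    def topo_edges(self) -> list[TreeEdge]:
        """Edges in root-to-leaf order."""
        order, out = [self.root], []
        remaining = list(self.edges)
        while remaining:
            progress = False
            for e in list(remaining):
                if e.parent in order:
                    out.append(e)
                    order.append(e.child)
                    remaining.remove(e)
                    progress = True
            if not progress:
                raise ConfigError("tree edges do not form a rooted tree")
        return out

    def path_drift(self, leaf: str) -> float:
        """Total drift 1 - prod(1 - F_edge) from root to ``leaf``."""
        parent_of = {e.child: e for e in self.edges}
        keep, node = 1.0, leaf
        while node != self.root:
            e = parent_of[node]
            keep *= 1.0 - e.F
            node = e.parent
        return 1.0 - keep


def default_tree() -> PopulationTree:
    """Four populations mirroring the study design: an intermediate-altitude
    focal group (CAL) and its high-altitude sister (COL) on a short Andean
    stem, a lowland control (WIC), and a distant Siberian outgroup (ESK)."""
    return PopulationTree(
        root="root",
        edges=[
            TreeEdge("root", "ESK", 0.10),
            TreeEdge("root", "AMR", 0.04),
            TreeEdge("AMR", "WIC", 0.06),
            TreeEdge("AMR", "AND", 0.03),
            TreeEdge("AND", "CAL", 0.02),
            TreeEdge("AND", "COL", 0.02),
        ],
    )


@dataclass
class SweepSpec:
    """A single hard-sweep stamp.

    Attributes
    ----------
    population : str
        Target population (must be a tree leaf).
    chrom : str
        Chromosome of the core SNP.
    snp_index : int
        Column index of the core SNP within that chromosome; -1 lets
        :func:`generate_dataset` auto-select a mid-chromosome standing
        variant (derived frequency 0.2-0.8) via :func:`choose_sweep_core`.
    f_target : float
        Final derived-allele frequency in (0, 1]; must exceed the neutral
        frequency at the core.
    L_sweep : float
        Mean copied-tract half-length per side, bp.
    """

    population: str
    chrom: str
    snp_index: int
    f_target: float
    L_sweep: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_target <= 1.0):
            raise ConfigError(f"f_target={self.f_target} not in (0, 1]")
        if self.L_sweep <= 0:
            raise ConfigError("L_sweep must be positive")


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic dataset.

    Defaults emulate the study's scale, scaled down: 23/23/20/20 diploids
    for CAL/COL/WIC/ESK, SNP spacing of ~4 kb matching a 730k genome-wide
    array, ancestral frequencies bounded in (0.05, 0.95) to mimic
    common-variant ascertainment.
    """

    n_diploids: dict[str, int] = field(
        default_factory=lambda: {"CAL": 23, "COL": 23, "WIC": 20, "ESK": 20}
    )
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_snps: int = 2500  # per chromosome
    freq_low: float = 0.05
    freq_high: float = 0.95
    n_founders: int = 10
    switch_rate: float = 5e-5  # per bp; LD scale ~ 1/switch_rate = 20 kb
    tree: PopulationTree = field(default_factory=default_tree)
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_low < self.freq_high < 1.0):
            raise ConfigError("need 0 < freq_low < freq_high < 1")
        if min(self.n_chromosomes, self.chrom_length, self.n_snps, self.n_founders) <= 0:
            raise ConfigError("counts must be positive")
        if self.switch_rate < 0:
            raise ConfigError("switch_rate must be >= 0")
        leaves = set(self.tree.leaves())
        if set(self.n_diploids) != leaves:
            raise ConfigError(
                f"n_diploids keys {sorted(self.n_diploids)} must match tree leaves {sorted(leaves)}"
            )
        if any(n <= 0 for n in self.n_diploids.values()):
            raise ConfigError("n_diploids must be positive")
        for sw in self.sweeps:
            if sw.population not in leaves:
                raise ConfigError(f"sweep population {sw.population!r} not a tree leaf")

    def chromosome_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tree"] = {
            "root": self.tree.root,
            "edges": [[e.parent, e.child, e.F] for e in self.tree.edges],
        }
        d["sweeps"] = [asdict(s) for s in self.sweeps]
        return d


def default_config(seed: int = 0, **overrides) -> ScenarioConfig:
    return ScenarioConfig(seed=seed, **overrides)


def _bn_child(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols: Beta draw with mean p and variance F p (1 - p).

    Frequencies at 0 or 1 (fixed alleles, possible after upstream drift)
    stay fixed: the Beta parameters degenerate there.
    """
    if F == 0.0:
        return p.copy()
    fixed = (p <= 0.0) | (p >= 1.0)
    safe = np.where(fixed, 0.5, p)
    a = safe * (1.0 - F) / F
    b = (1.0 - safe) * (1.0 - F) / F
    draw = rng.beta(a, b)
    return np.where(fixed, p, draw)


def simulate_frequencies(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Draw per-population derived-allele frequencies for every SNP.

    Returns
    -------
    dict chrom -> DataFrame
        One column per tree node (internal nodes included), one row per SNP;
        leaf columns are the population frequencies downstream code uses.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    out = {}
    for chrom in config.chromosome_names():
        anc = rng.uniform(config.freq_low, config.freq_high, size=config.n_snps)
        node_freq = {config.tree.root: anc}
        for e in config.tree.topo_edges():
            node_freq[e.child] = _bn_child(rng, node_freq[e.parent], e.F)
        out[chrom] = pd.DataFrame(node_freq)
    return out


def _positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Evenly spaced 1-based positions with uniform jitter, strictly increasing."""
    spacing = length / n
    base = (np.arange(n) + 0.5) * spacing
    jitter = rng.uniform(-0.4, 0.4, size=n) * spacing
    pos = np.sort(np.floor(base + jitter).astype(np.int64)) + 1
    # de-duplicate while keeping order (spacing >> 1 makes this rare)
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def _copy_model(
    rng: np.random.Generator,
    founders: np.ndarray,
    n_haps: int,
    pos: np.ndarray,
    switch_rate: float,
) -> np.ndarray:
    """Mosaic haplotypes copied from founders with distance-dependent switching."""
    K, M = founders.shape
    idx = np.empty((n_haps, M), dtype=np.intp)
    idx[:, 0] = rng.integers(0, K, size=n_haps)
    if switch_rate == 0.0:
        idx[:, 1:] = idx[:, [0]]
    else:
        p_switch = 1.0 - np.exp(-switch_rate * np.diff(pos))
        switches = rng.random((n_haps, M - 1)) < p_switch[None, :]
        new = rng.integers(0, K, size=(n_haps, M - 1))
        for m in range(1, M):
            idx[:, m] = np.where(switches[:, m - 1], new[:, m - 1], idx[:, m - 1])
    return founders[idx, np.arange(M)[None, :]]


def simulate_haplotypes(
    freqs: dict[str, pd.DataFrame], config: ScenarioConfig
) -> tuple[VariantTable, HaplotypeMatrix, PopulationPanel]:
    """Generate phased haplotypes from per-population frequencies.

    Founder haplotypes are drawn SNP-wise from the population frequencies;
    sample haplotypes are founder mosaics (see module docstring), which
    yields LD decaying with physical distance at scale ``1/switch_rate``.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    pops = config.tree.leaves()
    chroms = config.chromosome_names()
    child_seeds = ss.spawn(len(chroms) * (len(pops) + 1))

    sample_ids, assignments = [], {}
    for pop in pops:
        for i in range(config.n_diploids[pop]):
            sid = f"{pop}{i:03d}"
            sample_ids.append(sid)
            assignments[sid] = pop

    var_frames, hap_blocks = [], []
    k = 0
    for chrom in chroms:
        pos_rng = np.random.default_rng(child_seeds[k]); k += 1
        pos = _positions(pos_rng, config.chrom_length, config.n_snps)
        anc_idx = pos_rng.integers(0, 4, size=config.n_snps)
        der_idx = (anc_idx + 1 + pos_rng.integers(0, 3, size=config.n_snps)) % 4
        var_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "snp_id": [f"snp_{chrom}_{i}" for i in range(config.n_snps)],
                    "ref": NUCLEOTIDES[anc_idx],
                    "alt": NUCLEOTIDES[der_idx],
                    "ancestral_allele": NUCLEOTIDES[anc_idx],
                }
            )
        )
        pop_blocks = []
        for pop in pops:
            rng = np.random.default_rng(child_seeds[k]); k += 1
            p = freqs[chrom][pop].to_numpy()
            founders = (rng.random((config.n_founders, config.n_snps)) < p).astype(
                np.uint8
            )
            n_haps = 2 * config.n_diploids[pop]
            pop_blocks.append(
                _copy_model(rng, founders, n_haps, pos, config.switch_rate)
            )
        hap_blocks.append(np.concatenate(pop_blocks, axis=0))

    variants = VariantTable(pd.concat(var_frames, ignore_index=True))
    haps = HaplotypeMatrix(np.concatenate(hap_blocks, axis=1), sample_ids)
    panel = PopulationPanel(assignments)
    return variants, haps, panel


def choose_sweep_core(
    variants: VariantTable,
    haps: HaplotypeMatrix,
    panel: PopulationPanel,
    population: str,
    chrom: str,
    freq_range: tuple[float, float] = (0.2, 0.8),
    near_index: int | None = None,
) -> int:
    """Pick a sweep core SNP: the variant closest to ``near_index``
    (default: the chromosome middle) whose derived frequency in the target
    population lies in ``freq_range`` -- a standing variant a sweep can
    plausibly act on."""
    cols = np.flatnonzero(variants.chrom == chrom)
    if cols.size == 0:
        raise ConfigError(f"no variants on chromosome {chrom!r}")
    rows = panel.haplotype_rows(haps, population)
    block = haps.values[np.ix_(rows, cols)]
    flip = ~variants.derived_is_alt()[cols]
    dfreq = np.where(flip, 1 - block.mean(axis=0), block.mean(axis=0))
    ok = np.flatnonzero((dfreq >= freq_range[0]) & (dfreq <= freq_range[1]))
    if ok.size == 0:
        raise ConfigError(
            f"no SNP with derived frequency in {freq_range} on {chrom!r}"
        )
    target = cols.size // 2 if near_index is None else near_index
    return int(ok[np.argmin(np.abs(ok - target))])


def inject_sweep(
    variants: VariantTable,
    haps: HaplotypeMatrix,
    panel: PopulationPanel,
    spec: SweepSpec,
    seed: int,
) -> HaplotypeMatrix:
    """Stamp a hard sweep into one population around one core SNP.

    One existing carrier haplotype becomes the sweep founder; randomly
    chosen non-carriers copy the founder over a tract around the core
    (per-side half-lengths ~ Exponential(mean ``L_sweep``)) until the
    derived frequency at the core reaches ``f_target``. Other populations
    and distal sequence are untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    chrom_mask = variants.chrom == spec.chrom
    chrom_cols = np.flatnonzero(chrom_mask)
    if not (0 <= spec.snp_index < len(chrom_cols)):
        raise ConfigError(
            f"snp_index {spec.snp_index} outside chromosome {spec.chrom!r}"
        )
    core = chrom_cols[spec.snp_index]
    pos = variants.pos
    derived_allele = 1 if variants.derived_is_alt()[core] else 0

    rows = panel.haplotype_rows(haps, spec.population)
    if rows.size == 0:
        raise ConfigError(f"population {spec.population!r} has no haplotypes")
    values = haps.values.copy()
    carriers = rows[values[rows, core] == derived_allele]
    if carriers.size == 0:
        raise ConfigError(
            f"no carrier of the derived allele at {spec.chrom}:{pos[core]}; "
            "cannot seed sweep"
        )
    current = carriers.size / rows.size
    if spec.f_target < current:
        raise ConfigError(
            f"f_target {spec.f_target} below current frequency {current:.3f}"
        )
    founder = carriers[rng.integers(0, carriers.size)]
    non_carriers = rows[values[rows, core] != derived_allele]
    need = int(np.ceil(spec.f_target * rows.size)) - carriers.size
    need = min(max(need, 0), non_carriers.size)
    chosen = rng.choice(non_carriers, size=need, replace=False)
    core_pos = pos[core]
    for h in chosen:
        left = rng.exponential(spec.L_sweep)
        right = rng.exponential(spec.L_sweep)
        in_tract = chrom_mask & (pos >= core_pos - left) & (pos <= core_pos + right)
        cols = np.flatnonzero(in_tract)
        values[h, cols] = values[founder, cols]
        values[h, core] = values[founder, core]  # core always copied
    return HaplotypeMatrix(values, list(haps.sample_ids))


def _tiling_genes(config: ScenarioConfig, gene_length: int = 25_000, step: int = 50_000) -> GeneAnnotation:
    rows = []
    g = 0
    for chrom in config.chromosome_names():
        for start in range(10_000, config.chrom_length - gene_length, step):
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_length,
                    "name": f"GENE{g:05d}",
                }
            )
            g += 1
    return GeneAnnotation(pd.DataFrame(rows))


def generate_dataset(
    config: ScenarioConfig,
    outdir: str | Path,
    n_candidates: int = 40,
) -> dict[str, Path]:
    """Simulate a scenario and write a complete on-disk fixture.

    Writes ``genotypes.vcf`` (phased), ``panel.tsv``, ``genes.bed`` (tiling
    synthetic genes), ``candidates.txt`` (genes overlapping sweep windows
    plus random genes, up to ``n_candidates``) and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freqs = simulate_frequencies(config)
    variants, haps, panel = simulate_haplotypes(freqs, config)
    resolved = []
    for sw in config.sweeps:
        if sw.snp_index < 0:
            sw = SweepSpec(
                sw.population,
                sw.chrom,
                choose_sweep_core(variants, haps, panel, sw.population, sw.chrom),
                sw.f_target,
                sw.L_sweep,
            )
        resolved.append(sw)
        haps = inject_sweep(variants, haps, panel, sw, config.seed)
    genes = _tiling_genes(config)

    cand_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    sweep_genes: set[str] = set()
    for sw in resolved:
        cols = np.flatnonzero(variants.chrom == sw.chrom)
        core_pos0 = int(variants.pos0[cols[sw.snp_index]])
        gdf = genes.df
        hit = gdf[
            (gdf["chrom"] == sw.chrom)
            & (gdf["start"] < core_pos0 + 100_000)
            & (gdf["end"] > core_pos0 - 100_000)
        ]
        sweep_genes.update(hit["name"])
    pool = [g for g in genes.names() if g not in sweep_genes]
    n_extra = max(n_candidates - len(sweep_genes), 0)
    extra = sorted(cand_rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    candidates = CandidateGeneList(sweep_genes | set(extra))

    paths = {
        "vcf": outdir / "genotypes.vcf",
        "panel": outdir / "panel.tsv",
        "genes": outdir / "genes.bed",
        "candidates": outdir / "candidates.txt",
        "manifest": outdir / "manifest.json",
    }
    gio.write_phased_vcf(paths["vcf"], variants, haps)
    gio.write_panel(paths["panel"], panel)
    gio.write_gene_bed(paths["genes"], genes)
    gio.write_candidate_list(paths["candidates"], candidates)
    manifest = {
        "config": {**config.to_dict(), "sweeps": [asdict(s) for s in resolved]},
        "seed": config.seed,
        "n_variants": int(variants.n_variants),
        "n_samples": int(haps.n_samples),
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
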