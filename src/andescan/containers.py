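"""In-memory containers for phased genotype data and its annotations.

Conventions used throughout the package:

* VCF positions are 1-based; BED intervals and every internal window
  computation are 0-based half-open.
* Haplotype matrices are binary ``(H, M)`` arrays with two consecutive rows
  per diploid sample (rows ``2i`` and ``2i + 1`` belong to ``sample_ids[i]``).
  A ``1`` encodes the derived allele where the ancestral state is known, and
  the ALT allele otherwise.
* Missing genotypes are not representable: data with missingness must be
  filtered or rejected before construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "HaplotypeMatrix",
    "PopulationPanel",
    "GeneAnnotation",
    "CandidateGeneList",
]


class DataError(ValueError):
    """Invalid or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration (bad roles, bad parameter values)."""


@dataclass
class VariantTable:
    """Per-SNP metadata for a set of biallelic variants.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``snp_id`` (str),
        ``ref`` (str), ``alt`` (str), ``ancestral_allele`` (str; one of the
        two alleles or ``"unknown"``).
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "pos", "snp_id", "ref", "alt", "ancestral_allele")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise DataError(f"VariantTable missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                i = int(np.argmax(np.diff(pos) <= 0))
                raise DataError(
                    f"positions not strictly increasing on {chrom} near "
                    f"{chrom}:{pos[i + 1]}"
                )
        bad = df["ref"] == df["alt"]
        if bad.any():
            raise DataError("variant with identical ref and alt allele")
        known = df["ancestral_allele"] != "unknown"
        ok = (df["ancestral_allele"] == df["ref"]) | (df["ancestral_allele"] == df["alt"])
        if (known & ~ok).any():
            row = df[known & ~ok].iloc[0]
            raise DataError(
                f"ancestral allele {row.ancestral_allele!r} at "
                f"{row.chrom}:{row.pos} matches neither ref nor alt"
            )
        self.df = df

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        """1-based positions (VCF convention)."""
        return self.df["pos"].to_numpy()

    @property
    def pos0(self) -> np.ndarray:
        """0-based positions used for window arithmetic."""
        return self.df["pos"].to_numpy() - 1

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def ancestral_known(self) -> np.ndarray:
        return (self.df["ancestral_allele"] != "unknown").to_numpy()

    def derived_is_alt(self) -> np.ndarray:
        """True where the derived allele is the ALT allele.

        Where the ancestral allele is unknown the ALT allele is treated as
        derived (callers that require true polarization must restrict to
        :meth:`ancestral_known`).
        """
        return (self.df["ancestral_allele"] != self.df["alt"]).to_numpy()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: ``values[h, m]`` is the allele of haplotype
    ``h`` at variant ``m`` (1 = derived when polarized, else 1 = alt)."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 2:
            raise DataError("haplotype matrix must be 2-dimensional")
        if v.shape[0] % 2 != 0:
            raise DataError("haplotype count must be even (two per diploid)")
        if v.shape[0] != 2 * len(self.sample_ids):
            raise DataError("haplotype rows must be 2 x number of samples")
        if v.size and v.max() > 1:
            raise DataError("haplotype matrix entries must be 0/1")
        self.values = v
        self.sample_ids = list(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def rows_for_samples(self, samples: list[str]) -> np.ndarray:
        """Haplotype row indices for the given samples, two per sample."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in samples:
            if s not in index:
                raise DataError(f"sample {s!r} not present in haplotype matrix")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(rows, dtype=np.intp)


ROLES = ("focal", "sister", "control", "outgroup")


@dataclass
class PopulationPanel:
    """Sample-to-population assignment plus role bindings.

    Roles name which population plays which part in the scans: ``focal`` is
    scanned for selection, ``sister`` is the comparison population for
    XP-EHH/F_ST/PBS, ``control`` supplies the iHS exclusion set, and
    ``outgroup`` closes the three-population PBS tree.
    """

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, p in self.assignments.items():
            if not p:
                raise DataError(f"sample {s!r} has empty population")
        for role, pop in self.roles.items():
            if role not in ROLES:
                raise ConfigError(f"unknown role {role!r}")
            if pop not in self.populations():
                raise ConfigError(f"role {role!r} bound to unknown population {pop!r}")

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.assignments.values()))

    def samples(self, population: str | None = None) -> list[str]:
        if population is None:
            return list(self.assignments)
        return [s for s, p in self.assignments.items() if p == population]

    def size(self, population: str) -> int:
        return len(self.samples(population))

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]

    def with_roles(self, **roles: str) -> "PopulationPanel":
        merged = dict(self.roles)
        merged.update({r: p for r, p in roles.items() if p is not None})
        return PopulationPanel(dict(self.assignments), merged)

    def role(self, name: str) -> str:
        if name not in self.roles:
            raise ConfigError(f"role {name!r} not bound to a population")
        return self.roles[name]

    def haplotype_rows(self, haps: HaplotypeMatrix, population: str) -> np.ndarray:
        return haps.rows_for_samples(
            [s for s in haps.sample_ids if self.assignments.get(s) == population]
        )

    def validate_against(self, haps: HaplotypeMatrix) -> None:
        unassigned = [s for s in haps.sample_ids if s not in self.assignments]
        if unassigned:
            raise DataError(f"samples without population assignment: {unassigned[:5]}")


@dataclass
class GeneAnnotation:
    """Gene intervals in BED convention (0-based half-open), sorted by
    (chrom, start). Overlapping genes are retained as-is."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = ("chrom", "start", "end", "name")
        missing = [c for c in need if c not in self.df.columns]
        if missing:
            raise DataError(f"GeneAnnotation missing columns: {missing}")
        df = self.df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise DataError(f"gene {row['name']!r}: start {row.start} >= end {row.end}")
        if (df["name"].astype(str).str.len() == 0).any():
            raise DataError("empty gene name")
        self.df = df.sort_values(["chrom", "start", "end", "name"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def names(self) -> list[str]:
        return list(self.df["name"])


@dataclass
class CandidateGeneList:
    """An a-priori gene list (e.g. hypoxia-pathway genes), case-normalized."""

    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = {g.strip().upper() for g in self.genes if g.strip()}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.genes
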