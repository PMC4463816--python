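from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import andescan as a


@pytest.fixture(scope="session")
def small_scenario():
    """One-chromosome neutral scenario at the study's sample sizes."""
    cfg = a.default_config(
        seed=7, n_snps=400, n_chromosomes=1, chrom_length=1_600_000
    )
    freqs = a.simulate_frequencies(cfg)
    variants, haps, panel = a.simulate_haplotypes(freqs, cfg)
    panel = panel.with_roles(focal="CAL", sister="WIC", control="WIC", outgroup="ESK")
    return cfg, variants, haps, panel


def toy_variants(positions, chrom="1"):
    return a.VariantTable(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": list(positions),
                "snp_id": [f"s{i}" for i in range(len(positions))],
                "ref": "A",
                "alt": "T",
                "ancestral_allele": "A",
            }
        )
    )


def toy_haps(rows, sample_prefix="S"):
    values = np.asarray(rows, dtype=np.uint8)
    n = values.shape[0] // 2
    return a.HaplotypeMatrix(values, [f"{sample_prefix}{i}" for i in range(n)])
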