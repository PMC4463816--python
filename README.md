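# andescan

Selection scans for small, array-genotyped population samples — built for
the study design where an intermediate-altitude Andean population is
screened for signatures of adaptation to hypobaric hypoxia against a
high-altitude sister group, a lowland control and a distant outgroup.

Detecting recent positive selection in samples of ~20 diploids per
population, genotyped on a common-variant SNP array, rules out parametric
nulls; the standard approach is an *empirical outlier* scan. `andescan`
implements the full framework as a tested, reusable library and CLI:

* **Four per-SNP statistics.**
  * iHS: `ln(iHH_A / iHH_D)` — the log ratio of integrated EHH between
    ancestral- and derived-allele carriers at a core SNP, standardized
    within derived-allele-frequency bins;
  * XP-EHH: `ln(iHH_pop1 / iHH_pop2)` between two populations at the same
    core, standardized genome-wide;
  * Weir–Cockerham F_ST: the two-population variance-components estimator
    θ̂ = a / (a + b + c), computed from observed heterozygotes;
  * PBS: `(T_fs + T_fo − T_so) / 2` with `T = −ln(1 − F_ST)`, isolating
    allele-frequency change on the focal branch.
* **Empirical-outlier windows.** Fixed tiling windows (200 kb for the
  haplotype tests, 100 kb for the frequency tests), ranked within
  SNP-count bins, top 1% / 5% flagged with deterministic tie-breaks; a
  cross-population exclusion rule (focal top-1% iHS windows dropped when
  in the control's top 5%); multi-test gene overlaps; F_ST-cutoff counts;
  focal-vs-focal branch-length comparison.
* **Enrichment.** Gene↔window assignment, a-priori candidate-list
  intersection with the expected-by-chance count `n·K/N`, and GO-term
  screening with the EASE score (Fisher's exact upper tail with one gene
  removed from the overlap) at EASE < 0.01.
* **Synthetic data.** A seedable generator — Balding–Nichols drift on a
  population tree, founder-copying LD, array-like ascertainment, hard-sweep
  stamps — so the entire pipeline runs and is tested without any genotype
  download.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 5,000-SNP chromosome (four populations: CAL 23, COL 23, WIC 20,
ESK 20 diploids) with a sweep in the focal population CAL driven to
derived frequency 0.9 around a mid-chromosome core, then scan it:

```sh
andescan simulate --out fixture --seed 42 \
    --n-snps 5000 --n-chromosomes 1 --chrom-length 20000000 \
    --sweep CAL:1:-1:0.9:100000

andescan scan --vcf fixture/genotypes.vcf --panel fixture/panel.tsv \
    --genes fixture/genes.bed --candidates fixture/candidates.txt \
    --focal CAL --sister WIC --control WIC --outgroup ESK \
    --out scanout
```

The scan prints a summary (and writes per-SNP, per-window, gene and
enrichment TSVs plus `manifest.json` and an overview figure to `scanout/`):

```json
{
  "fst_windows_above_cutoff": 56,
  "ihs_excluded": 0,
  "ihs_n_windows": 100,
  "ihs_top1": 1,
  "pbs_n_windows": 200,
  "pbs_top1": 3,
  "universe_size": 400,
  "xpehh_top1": 1,
  ...
}
```

The 20 Mb chromosome tiles into 100 windows of 200 kb for the haplotype
tests (200 × 100 kb for the frequency tests); the top 1% flags
⌈0.01·N⌉ windows per SNP-count bin. Here the simulated sweep sits at
position ~9.99 Mb, and the iHS outlier table recovers it:

```
chrom    start      end  snp_count    score  rank
    1 10000000 10200000         33 0.242424     1
```

i.e. the window spanning the swept haplotypes is the genome-wide rank-1
iHS window (score = fraction of its SNPs with |standardized iHS| > 2).
`genes.tsv` assigns the flagged windows to the synthetic genes they
overlap, and `enrichment_candidates.tsv` intersects them with the
candidate list — for iHS in this run, k = 2 candidate genes among the
n = 4 top-window genes against 0.4 expected by chance.

The same operations are available as a library:

```python
import andescan as a

cfg = a.default_config(seed=42)
variants, haps, panel = a.simulate_haplotypes(a.simulate_frequencies(cfg), cfg)
panel = panel.with_roles(focal="CAL", sister="WIC", control="WIC", outgroup="ESK")
result = a.scan(variants, haps, panel)
result.tables["windows_pbs"].head()
```

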