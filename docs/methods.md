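# Methods

`andescan` implements a four-statistic scan for recent positive selection in
small, array-genotyped population samples, an empirical-outlier window
framework on top of the per-SNP statistics, candidate-gene and GO-term
enrichment, and a synthetic-data generator that reproduces the statistical
structure the scans assume. This note records the models, the defaults and
why they were chosen, and what the simulations do and do not establish.

## Selection statistics

### Weir–Cockerham F_ST

Per SNP, the two-population variance-components estimator θ̂ (Weir &
Cockerham 1984) is computed from per-population derived-allele frequencies
`p_i`, diploid sample sizes `n_i` and *observed* heterozygote proportions
`h_i` (the `c` component of the estimator is defined on observed
heterozygotes; we do not substitute Hardy–Weinberg expectations, which
matters at n ≈ 20 diploids). The raw estimate may be negative; it is
reported raw and clamped to `[0, 1]` for downstream use. SNPs monomorphic
in both populations (a + b + c = 0) are undefined and excluded from
windows.

For genome-wide summaries (`multilocus_fst`) the ratio-of-sums estimator
`Σa / Σ(a+b+c)` is used rather than the mean of per-SNP ratios: at these
sample sizes the per-SNP ratio has a substantial Jensen bias (we measure
≈ −0.05 at true F = 0.2), while the ratio of sums recovers the simulated
drift parameter to within ±0.005.

### PBS

With `T = −ln(1 − F_ST)` (natural log) per population pair, the population
branch statistic of the focal population is
`PBS = (T_fs + T_fo − T_so) / 2` for focal/sister/outgroup. Pairwise F_ST
is clamped to `[0, 1 − 1e-12]` before the log so fixed differences stay
finite; negative per-SNP θ̂ is clamped to 0 before the transform (the raw
value remains in the output), which is common practice in PBS
implementations since `−ln(1−x)` is not meaningful on the estimator's
negative range. PBS itself may be negative and is left so.

### EHH, iHH, iHS

EHH at marker `x` for the `n` carriers of a core allele is
`Σ_j C(c_j, 2) / C(n, 2)` over the distinct extended haplotypes spanning
core→x. The decay curve is evaluated at each successive SNP outward and
stops at the first of: EHH below the 0.05 floor, the chromosome end, or an
inter-SNP gap above 200 kb. iHH is the trapezoidal integral of the curve
against physical distance, truncated at the linearly interpolated floor
crossing, left and right sides summed. Scores whose curves cross a
super-threshold gap are invalidated; cores truncated by a chromosome end
keep their one-sided value but carry an `edge` flag that propagates to
window scores.

iHS is `ln(iHH_ancestral / iHH_derived)` at cores with known ancestral
state and derived frequency in [0.05, 0.95], standardized to mean 0 / SD 1
within derived-allele-frequency bins of width 0.02; bins with fewer than
20 scored SNPs are merged with their nearest neighbouring bin (ties toward
the lower bin). The 0.05 floor, 0.02 bin width and physical-distance
integration follow the Voight et al. conventions; all are exposed in the
API since array studies vary here. Distances are physical bp because array
data of this kind carries no genetic map; a map-based metric would slot
into the same integration.

### XP-EHH

At each core the allele-pooled EHH (all haplotypes; the core allele is part
of the extended haplotype span, so pooled EHH drops to core homozygosity at
the first marker) is integrated in each population out to a shared
boundary: the floor crossing of the EHH of the two populations combined.
`ln(iHH_A / iHH_B)` is then standardized genome-wide to mean 0 / SD 1.
The curve's distance-0 point is defined as 1 (two haplotypes are trivially
identical over an empty interval), which keeps every EHH curve
non-increasing from 1 regardless of mode.

## Window framework

Windows tile each chromosome from coordinate 0: 200 kb for the haplotype
tests, 100 kb for the frequency tests. All internal arithmetic is 0-based
half-open; VCF positions are 1-based and BED intervals 0-based, stated
once and converted at the boundary. Windows with no scored SNP are
dropped. Window scores: iHS uses the fraction of scored SNPs with
|standardized score| > 2, XP-EHH/F_ST/PBS use the window maximum (the
frequency tests emphasize extreme single SNPs).

Windows are ranked within SNP-count bins to keep uneven SNP density from
driving outlier calls: adjacent SNP-count values are merged upward until
every bin holds ≥ 50 windows (a deficient final bin folds into its
predecessor). Within each bin the top `⌈p·N_bin⌉` windows are flagged at
p = 0.01 and 0.05; ties break by higher max-SNP score, then lower
(chrom, start), so reruns are byte-identical. Because calling is
rank-based it is invariant to monotone transforms of the scores.

The cross-population exclusion rule drops focal top-1% iHS windows that
appear in the control population's top 5%, removing signals shared with a
lowland control. The F_ST cutoff count uses a strict `>` at 0.6, and the
focal-vs-focal branch comparison computes the share of jointly top-1% PBS
windows where one focal population's window maximum strictly exceeds the
other's.

## Enrichment

Genes are assigned to flagged windows on ≥ 1 bp interval overlap; each
gene inherits its best window's rank, and the maximum statistic among SNPs
inside the gene body is reported separately (genes without an internal SNP
are flagged with the distance to the nearest scored SNP, since a top SNP
can sit a few kb outside the gene it implicates). An optional flank
(default 10 kb when enabled) widens the match for reporting; enrichment
counts always use the strict rule.

The gene universe is the set of genes overlapping any scanned window, not
the whole annotation — consistent with an empirical-outlier design in
which only scanned regions can produce hits. Candidate-list intersection
reports the expected overlap `n·K/N` and a hypergeometric upper tail.
GO-term screening uses the EASE score: the one-sided Fisher exact p-value
recomputed with one gene removed from the observed overlap
(`k′ = max(k−1, 0)`, margins unchanged; `k = 0` → p = 1). EASE ≥ Fisher
always, with equality iff k = 0, and single-gene overlaps can never
enrich. Results are filtered at EASE < 0.01; a Benjamini–Hochberg column
is emitted for information only, mirroring the reporting style this
framework is built for.

## Synthetic data

The generator produces phased, complete, biallelic genotypes with the four
properties the scans rely on, without a coalescent simulator:

* **Tree-structured drift.** Ancestral frequencies are uniform on
  (0.05, 0.95) — mimicking common-variant array ascertainment — and drift
  along each tree edge under Balding–Nichols (Beta with mean `p_parent`,
  variance `F·p(1−p)`); an F = 0 edge copies its parent, and frequencies
  that reach 0/1 stay fixed.
* **LD.** Each population's haplotypes are mosaics of a founder pool
  (default 10 founders drawn SNP-wise from the population frequencies),
  switching founders between adjacent SNPs with probability
  `1 − exp(−switch_rate · distance)`; the default `switch_rate = 5e-5`/bp
  gives an LD scale of ~20 kb.
* **Sweeps.** A hard sweep is stamped in by copying one carrier haplotype
  around a core SNP into randomly chosen non-carriers until a target
  derived frequency is reached; copied-tract half-lengths are exponential
  (mean `L_sweep` per side, independent per side). Non-target populations
  are untouched.
* **Scale.** Defaults mirror the study design: four populations
  (focal CAL = 23, sister/high-altitude COL = 23, lowland control
  WIC = 20, distant outgroup ESK = 20 diploids), SNP spacing of ~4 kb
  matching a 730k genome-wide array, default 2 × 10 Mb chromosomes. Tree
  drifts (0.02–0.10 per edge) were set once to give realistic
  Andean/lowland/Siberian differentiation.

One integer seed drives everything through `numpy.random.SeedSequence`
spawning (per-chromosome and per-population substreams), so fixtures are
reproducible byte-for-byte.

**Known deviation from real data.** The founder pool is itself a
bottleneck: it adds roughly `1/n_founders` of extra per-population drift
on top of the tree parameter (with the default 10 founders, pairwise F_ST
runs ~0.1 above the tree value). This is harmless for the scans — which
are rank-based — but parameter-recovery checks use `n_founders = 1000` so
that the Beta-drift parameter is the estimand being recovered. The
generator also has no mutation model, no recombination-map structure, and
its sweep is a stamp rather than a trajectory; passing tests therefore
demonstrate correctness of the statistics and the framework's behaviour
under the assumed structure, not calibrated power on real human data.

In the drift-recovery setting, "two populations separated by drift F"
means each population has coancestry F relative to their shared ancestor
(drift F on each leaf edge): that is the quantity the Weir–Cockerham
estimator is defined to estimate.

## Problem sizes

Simulation-based checks run at: 6,000 SNPs per drift-recovery replicate
(three drift values); 2,000 SNPs for neutral outlier calling; and twenty
seeded sweep replicates of 5,000 SNPs on one 20 Mb chromosome (100
windows at 200 kb), with the sweep at a mid-chromosome standing variant
(derived frequency 0.2–0.8) driven to 0.9 with 100 kb tracts. These sizes
keep every seed-averaged quantity stable while the whole suite stays
small enough to run routinely.

## Degenerate inputs and numerical choices

* Populations need ≥ 2 diploids for frequency statistics and ≥ 2 carrier
  haplotypes per core allele for EHH; violations are flagged per SNP
  (scans) or raised (direct calls).
* Monomorphic-in-both SNPs have undefined F_ST and propagate NaN; windows
  never see them.
* iHS/XP-EHH standardization uses population SD (ddof 0); a degenerate
  zero-SD bin yields NaN scores rather than infinities.
* Floats are written at 6 significant digits with `NA` for missing; row
  order is always (chrom, pos) or (chrom, start), making reruns
  byte-identical.

## Limitations

The exclusion rule, window widths, percentile cutoffs and EASE threshold
are faithful to the study design this package operationalizes, but the
paper-scale headline gene lists depend on the genotyping platform,
annotation build and universe definition, so real-data gene counts are
annotation-sensitive. The scans assume phased, complete genotypes;
phasing error is not modelled. GO mappings are user-supplied inputs — no
term database is bundled.
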