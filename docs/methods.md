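# Methods

## Genotype model

All computations run on a samples × variants table of dosages counting
copies of the alternate allele (0, 1, 2) with a distinct missing sentinel.
Only biallelic SNPs are modelled. Internally windows use 0-based half-open
coordinates; files use 1-based positions (VCF convention). Every statistic
is cell- or pairwise-complete with respect to missing data: missing calls
leave both numerator and denominator, and quantities with an empty
denominator are reported as NaN rather than guessed.

## Simulator

The generator emulates a diversity panel of inbred lines drawn from two
differentiated germplasm pools.

* **Differentiation.** Ancestral minor-allele frequencies are uniform on
  `ancestral_maf_range` (default 0.05–0.5). Each population's frequency is
  drawn from the Balding–Nichols beta distribution
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = target_fst`; `F = 0` copies the
  ancestral frequency exactly. Balding–Nichols was chosen because only a
  target differentiation statistic is meaningful here, not a demographic
  history; its `F` parameter is exactly the variance-standardised
  between-population frequency variance that the Weir–Cockerham estimator
  targets, which is what makes recovery tests well-posed.
* **Inbreeding.** A line's genotype at a site is a single allele draw
  doubled (dosage 0 or 2), with a residual-heterozygosity overlay (dosage
  set to 1) at a per-line rate. This mirrors how near-fixed inbred lines
  behave on arrays (observed het rates of order 1%) without simulating
  selfing generations.
* **Missing–het coupling.** Each line has a latent standard-normal
  "dispensable-genome exposure" that scales both its heterozygosity and
  missing rates log-normally (mean-preserving, σ = 0.75); the missing-rate
  latent mixes the shared factor with independent noise at weight
  `missing_het_correlation`. Both artefacts plausibly arise from probes
  falling in genome segments absent from some lines, hence a shared
  factor; only the sign of the correlation is calibrated, as no
  quantitative value is available.
* **Linkage.** Two regimes: unlinked draws (default), and founder-copying
  in which each line copies one of `n_founders` (default 10) population
  haplotypes, switching founders between adjacent sites with probability
  `1 − exp(−d/ld_block_mean_length)`. This yields r² decaying on the block
  length scale, enough to exercise LD pruning and decay curves; it is not
  a coalescent and makes no claim about realistic haplotype diversity or
  recombination maps.
* **Defaults as study conditions.** 100+100 lines, 5,000 SNPs on 10
  chromosomes of 10 Mb, F_ST 0.15, het 1%, missing 2%, correlation 0.5,
  50-kb LD blocks. These are desk-scale stand-ins for a diversity panel:
  large enough for stable frequency estimates, small enough that the whole
  pipeline runs in seconds.

What passing tests on this simulator do **not** show: behaviour under real
ascertainment bias, genotype-calling error, population substructure beyond
two pools, or realistic LD heterogeneity. The simulator's purpose is
ground-truth recovery and contract checking, not realism.

## Statistics

* **PIC** uses the textbook two-term form
  `1 − ΣPᵢ² − Σᵢ<ⱼ2Pᵢ²Pⱼ²` (biallelic maximum 0.375 at p = 0.5).
* **AFD** is the absolute temperate–tropical frequency difference.
* **F_ST** is the Weir–Cockerham (1984) θ from per-site genotype-based
  variance components a (between populations), b (between individuals
  within populations) and c (within individuals), including the
  observed-heterozygosity corrections — retained even though inbred hets
  are rare, so the estimator stays correct for arbitrary input. Per-site
  θ = a/(a+b+c) preserves negative estimates and is NaN where both groups
  are monomorphic. The multi-locus summary sums components before taking
  the ratio (`fst_weir_cockerham_global`); averaging per-site ratios is
  biased downward (measured ≈ 0.195 for a true 0.30 under the default
  conditions) and is deliberately not used as a summary.
* **Folded 2-D SFS**: one fold per variant, oriented by the pooled minor
  allele so both axes stay comparable; equal-width frequency bins on
  [0, 1], counts conserved over retained variants.
* **IBS distance** is `1 − mean IBS` with allele-sharing credit
  1 / 0.5 / 0 (identical / one shared allele / opposite homozygotes),
  equivalently `|dᵢ − dⱼ|/2` averaged over jointly non-missing sites —
  the PLINK DST convention. Within- and between-group nucleotide
  diversity are means of these distances over the respective pairs.
* **Kinship** is a centred-IBS style estimator: dosages centred by twice
  the pooled frequency (after MAF > 0.05 and missing < 20% filters),
  cross-product normalised by Σ2pq, negatives truncated at 0, and the
  matrix scaled by its largest diagonal entry so clones sit near 1 and
  unrelated lines near 0. The truncation-and-scale convention was chosen
  because the downstream interpretation is ordinal (close to 0 = weak,
  close to 1 = strong relationship).
* **LD decay** bins all same-chromosome pairs closer than `max_distance`
  into disjoint 50-kb distance bins (disjoint rather than sliding — the
  choice is immaterial for a monotone curve and keeps pair counts
  interpretable) and reports mean r² and pair counts per bin. The decay
  distance is reported as the first bin range whose mean r² drops below
  the threshold (default 0.1), not an interpolated point.

## Panel design

Stages are estimators so they compose with sklearn pipelines; each
records the ids it selected.

* *Filter*: missing rate < 5% and, when population labels exist, MAF ≥
  0.05 within **each** population ("high polymorphism in both pools" is
  operationalised as a within-pool MAF floor, consistent with the MAF
  filter used everywhere else).
* *Coverage*: the genome is tiled into disjoint 100-kb bins per
  chromosome; each non-empty bin keeps its `min_per_window` best-ranked
  candidates (ties by position then id). Empty bins are reported as gaps,
  not errors — an array cannot conjure candidates where none exist.
* *Top-F_ST*: the n largest per-site θ, undefined values excluded with a
  warning, ties broken by (chrom, pos, id).
* *LD pruning*: greedy left-to-right scan; a candidate is dropped if its
  r² with any of the previous 50 **retained** candidates on the same
  chromosome exceeds 0.1. The greedy direction is a convention; the
  output guarantee (no retained within-window pair above the threshold)
  is what is contractually tested. Genotype r² is used throughout.
* *Assembly*: source lists are pooled in caller priority order with
  first-source-wins deduplication, then pruned; provenance and
  non-increasing stage counts are recorded. The pipeline is idempotent on
  its own output.

## Core sets

* **Genotyping bins**: k-medoids over Hamming distance between variant
  genotype patterns (fraction of jointly non-missing samples that
  disagree; pairs sharing no sample get distance 1). Clustering runs on
  distinct patterns weighted by multiplicity, so identical patterns
  always co-cluster, and k is capped by the number of distinct patterns.
  Initialisation is seeded D²-sampling; updates alternate assignment and
  weighted medoid refresh (max 20 sweeps). k-medoids was preferred over
  hierarchical or k-means alternatives because the medoid is itself a
  genotype pattern — the cluster stays interpretable — and the whole
  procedure is deterministic under the seed.
* **Genetic bins**: B intervals allocated to chromosomes by
  largest-remainder proportional-to-length rounding (every chromosome at
  least one bin; total exactly B), equal-width and half-open within a
  chromosome.
* **GA**: a (1+1) hill-climber per set — the minimal algorithm consistent
  with "random start set, mutate a bin's representative, keep
  improvements". Start: one uniformly random candidate per non-empty
  genotyping bin. Proposal: re-draw the representative of one random
  multi-member bin. Accept iff the count of distinct genetic bins covered
  does not decrease (so trajectories are non-decreasing and neutral
  drift is allowed). Budget: a fixed number of proposals, or of accepted
  proposals when `count_accepted_only` is set. No crossover and no
  population of solutions — with a one-swap neighbourhood the
  hill-climber already reaches the exhaustive optimum on every small
  instance in the oracle suite.
* **Complementary mode**: each later set scores only genetic bins not yet
  covered by earlier sets. Two independent 100-marker sets cannot cover
  90% of 200 genetic bins (each covers at most 50%), so union-level
  coverage claims are made in complementary mode; per-set genotyping
  coverage is 1.0 over non-empty bins by construction.
* **Differential locus rate**: per unordered pair of lines, the fraction
  of jointly non-missing markers with unequal dosage; pairs sharing no
  marker are excluded and counted. Core sets built from genotyping bins
  score higher per marker than the full panel because near-redundant and
  low-information patterns collapse into single bins.

## Numerical and degenerate-input choices

* Sample-pair computations (IBS, differential rates) run in float64;
  the variant-pair Hamming matrix for clustering uses float32 for
  memory (5,000 variants → 100 MB) — cluster assignment is insensitive
  to 1e-7 rounding.
* Tie-breaks are always (chrom, pos, id) or first-index argmin, keeping
  every pipeline stage deterministic for fixed inputs and seeds.
* `target_fst = 0` bypasses the beta draw entirely (no division by zero).
* Empty groups, singleton diversity groups, all-missing variants, empty
  candidate unions, zero surviving kinship variants, and k or B
  exceeding what the data supports all raise typed errors naming the
  offending quantity.

## Scale of the shipped checks

The test suite and the acceptance script run the full workflow at
desk scale — 200 lines × 5,000 markers, K = 100, B = 200, two 100-marker
core sets — chosen so estimates are stable (binomial error on a frequency
at n = 200 lines is ≈ 0.025) while any laptop reproduces the results in
seconds. Panel-scale figures from real germplasm collections (tens of
thousands of markers, hundreds of lines) are outside what synthetic
desk-scale data can certify; the corresponding behaviours are covered as
qualitative properties (e.g. core-set differential rates exceed the full
panel's; longer LD blocks delay r² decay).
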