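# Methods

## Model and procedure

`haploscan` treats a phase-known reference panel as a lookup table of
haplotypes. Three components interlock:

**Perfect-phylogeny cluster selection.** A set of biallelic sites admits a
perfect phylogeny (a single mutation tree, each site mutating once) iff no
pair of sites exhibits all four gametes {00, 01, 10, 11} across haplotypes
(Gusfield's criterion). The selector enumerates, for each polymorphic anchor
SNP, every subset of polymorphic sites on the same chromosome within
±window/2 of the anchor that contains the anchor, has size within the
configured bounds, and passes the pairwise four-gamete test, and keeps the
subset with maximal haplotype Shannon entropy in the panel. Entropy is
computed from raw panel counts without pseudo-counts; monomorphic sites are
never anchors or members. The search is exhaustive rather than greedy — at
the default maximum of 3 SNPs per cluster it is quadratic in the number of
in-window sites and cheap; the configuration cap of 6 SNPs keeps the subset
enumeration bounded.

**Rule-based phasing.** A genotype with h heterozygous member sites has
2^(h−1) unordered haplotype decompositions. The phaser classifies each
genotype by priority: (1) *phase-known* if some decomposition consists of two
panel-observed haplotypes — under four-gamete compatibility of the observed
set this decomposition is unique (two distinct fully observed decompositions
would exhibit all four gametes at some pair of heterozygous sites; verified
by brute force in the tests); (2) *predictable* if some decomposition pairs
one observed haplotype with its complement, choosing the observed haplotype
of highest panel frequency; (3) *unknown* otherwise. The rule deliberately
prefers a fully observed decomposition even when the truth is an
observed/unobserved pair — this is the method's dominant error mechanism and
is reproduced, not patched.

**Pooled chi-square association.** Haplotype counts per cluster form an m×2
case/control table. Every unobserved haplotype — predictable complements and
both haplotypes of unknown genotypes — enters a single pooled row, limiting
the degrees of freedom to m−1 where m is the number of realized rows. We use
the realized row count (distinct observed haplotypes present in the sample,
plus the pooled row when populated) rather than the theoretical n+1 / n+2,
because zero-count rows carry no information and corrupt the degrees of
freedom. Pearson's chi-square is computed without continuity correction and
without a minimum-expected-count rule (a debug log notes expected counts
below 5). Markers with fewer than two populated rows or an empty case or
control column are skipped with a reason code rather than forced through.

**Coverage model.** With an n-chromosome panel, the total frequency p of
unobserved haplotypes is bounded via the minimum of n uniforms:
F(x) = 1−(1−x)ⁿ and E(min) = 1/(n+1). With e = E(min) and HWE, genotype
categories occur in proportions phase-known (1−e)², predictable 2e(1−e),
unknown e². (A source describing this construction pairs the labels with the
formulas in the opposite order, which would make phase-known genotypes the
rarest class and contradict its own panel-size trend; we use the ordering
that is internally consistent.)

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window_bp | 20,000 | bp | typical LD-block scale; the window is centered on the anchor (±window/2, closed interval) for symmetric, deterministic context |
| max_cluster_size | 3 | SNPs | clusters of 2–4 SNPs balance information against degrees of freedom; excessive SNPs dilute power |
| min_cluster_size | 2 | SNPs | single-SNP fallback is off by default (`--allow-singleton` enables it); anchors with no compatible neighbour are skipped and logged |
| entropy_base | 2 | — | entropy in bits |
| alpha | 1×10⁻⁷ | — | fixed genome-wide significance threshold; no further multiple-testing correction |
| Ne | 5,000 | diploid individuals | simulation default |
| mu, rec | 2×10⁻⁸, 1.2×10⁻⁸ | per bp per generation | simulation defaults; over 25 Mb these scale to θ = 4·Ne·mu·L = 10,000 and ρ = 6,000 |
| maf_min | 0.05 | frequency | sites below this minor-allele frequency among study chromosomes are dropped; the boundary value is retained |

Entropy ties break deterministically: smaller cluster first, then smaller
total |position − anchor|, then lexicographically smallest index tuple.
Predictable-rule frequency ties break on the lexicographically smallest
observed haplotype. The theoretically impossible case of multiple fully
observed decompositions (reachable only with a four-gamete-violating,
user-supplied cluster) picks the maximum frequency product and warns.

## Synthetic data

The generator emulates a standard neutral coalescent design: constant
population size, haplotypes simulated by msprime (Hudson coalescent with
recombination; samples are haploid chromosomes, so the population size is
passed as the 2·Ne chromosome copies of Ne diploid individuals, keeping
E[π] = 4·Ne·mu per bp — verified against Monte Carlo in the tests).
Mutations follow an infinite-sites binary model on a continuous genome so
that every segregating site carries exactly one mutation; a
recombination-free run is therefore globally four-gamete compatible.
Continuous positions are floored to 1-based integer bp, dropping rare
collisions.

Chromosomes are shuffled once under the seed; the first block forms the
phase-known panel, the rest are split into equal case/control pools and
paired into diploid individuals. Phenotype labels are null by default — no
disease model — which is what the type-I analyses require. An optional
single-site multiplicative relative-risk assignment is provided for power
experiments; it is an extension beyond the null design and off by default.
MAF filtering uses study chromosomes only, since the filter defines the
analysis marker set, not the panel.

Full scale is 25 Mb and 2,200 chromosomes (200 panel, 500+500 individuals).
The package's working defaults are 1 Mb and 600 chromosomes (200 panel,
100+100 individuals), which preserve every rate while keeping a full
pipeline run around a second; `SimulationParams.full_scale()` restores the
large configuration.

What the generator does *not* emulate: genotyping error and missingness
(study VCFs may carry missing genotypes, and the phaser handles them, but
the simulator never produces them), demographic structure or ethnicity
mismatch between panel and cohort, strand-flip artefacts, and real LD
architecture beyond the constant-Ne coalescent. Passing tests therefore
demonstrate correctness of the machinery under the stated sampling model,
not robustness to platform artefacts.

## Cross-validation scoring

k folds are seeded partitions of panel individuals (sizes differ by at most
1). Per fold, clusters are re-selected from the retained individuals only,
the held-out individuals are collapsed to genotypes, phased, and scored.
Wrong haplotypes are counted by optimally matching the called unordered pair
to the true unordered pair (0, 1 or 2 wrong per genotype) — the per-haplotype
convention. Unknown genotypes contribute two unknown haplotypes and zero
wrong; genotypes with missing member sites are excluded from the totals
(keeping "unknown" synonymous with "novel haplotype" rather than a
missing-data bucket). Correct phasing % is defined as 100 − error%; unknown
haplotypes are reported separately, not subtracted. Percentages are rounded
to two decimals for display only.

## Numerical and degenerate-input choices

- Genomic coordinates are 1-based; windows are closed intervals.
- Harmonization matches sites on (chrom, pos, ref, alt); swapped ref/alt is
  recoded g → 2−g unless the pair is strand-ambiguous (A/T, C/G), which is
  dropped with a warning — silent strand guessing would create phasing
  artefacts. An empty intersection is a hard error.
- Entropy sums run over counts sorted in decreasing order so equal count
  multisets give bit-identical entropies, making tie-breaks exact.
- The accordance rate uses |p_a − p_b| ≤ tol·max(p_a, p_b) with tol = 0
  (strict equality) by default.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` and the simulator's seed arguments); the
  generation pipeline is bit-reproducible under a fixed seed.

## Known limitations

- The phaser is local per cluster; no long-range phasing across clusters.
- The unknown pool is never imputed; markers dominated by unobserved
  haplotypes lose information to the pooled row.
- The single-SNP comparison test is the allelic 2×2 chi-square (a genotypic
  test is a possible alternative; the allelic form matches the haplotype
  test's allele-level accounting).
- Type-I calibration is measured by averaging rejection fractions over
  random label assignments; within one simulated region markers are in
  strong LD, so a single label draw's rejection fraction is highly variable
  even when the test is perfectly calibrated.
- Panels with recurrent mutation or gene conversion violate the
  perfect-phylogeny assumption and will simply yield fewer selected
  clusters, not incorrect ones.
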