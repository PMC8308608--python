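# Methods

This note documents the models and procedures implemented in `diplopop`,
the parameters that matter, the deliberate choices made where the design
was open, and what the synthetic-data generator does and does not emulate.

## Data model

Input is one aligned FASTA per marker, sequences of identical length over
the IUPAC alphabet, plus a delimited table mapping `sample_id` to
`population` (and optionally `population` to `cluster`). Two-base codes
(R, Y, S, W, K, M) encode heterozygous diploid sites. Gaps (`-`) and `N`
are accepted and treated as missing data everywhere downstream: excluded
pairwise in distance computation and excluded from per-site allele
denominators. Three- and four-base codes are tolerated in the alignment
(they contribute 1/3 or 1/4 weight per base in frequency counts) but are
rejected by the phasing step, since they cannot represent a diploid
genotype. Internally all coordinates are 0-based; every report and error
message uses 1-based positions.

## F84 distances on diploid genotypes

The genotype-based analysis treats each diploid IUPAC sequence as the
unit of comparison. The F84 distance is computed in closed form from the
observed transition proportion P and transversion proportion Q, with the
constants A, B, C derived from the base frequencies (estimated once over
the whole marker set, ambiguity codes contributing fractional counts; an
explicit override is available). The estimator inverts the expected
mismatch proportions of the F84 process, so no transition/transversion
ratio enters the distance itself; the `ts_tv_ratio` parameter (default
2.0) is carried in run manifests for the record.

**Ambiguity handling.** At each site the two genotypes are represented as
base-mass vectors (1 for a homozygote, ½+½ for a heterozygote). Shared
mass is matched first; only the residual mass, coupled independently, is
classified as transition or transversion. Consequences: identical
symbols — including identical heterozygotes — contribute no difference;
a homozygote against an overlapping heterozygote (A vs R) contributes
half a transition; disjoint heterozygotes (M vs K) split their unit
mismatch across the four residual base pairings. This matching rule is
what makes the distance zero exactly when the fractional mismatch is
zero, a property a plain product coupling would not have.

**Saturation.** When a log argument is non-positive the distance is
undefined; such pairs are recorded at a configurable ceiling (default
5.0 substitutions/site) with a warning, keeping population means finite.
The ceiling only matters for pathological inputs; none of the simulated
or realistic regimes reach it.

Individual distances are averaged over all cross-population pairs
(entry (p,q) = mean of |p|·|q| distances), and the two marker matrices
are combined entrywise as the square root of the sum of squares.

## Haplotype-based variant

Statistical phasing is deliberately not implemented. The deterministic
rule — alphabetically smaller base to haplotype 1 at every heterozygous
site — is reproducible and collapses back to the exact input genotype,
but it breaks within-individual linkage between heterozygous sites, so
haplotype-level results should be read as a linkage-free approximation.
Users with externally phased haplotypes (ids `sample/1`, `sample/2`) can
supply them directly and bypass the rule. Distances, population means
and marker combination reuse the F84 engine unchanged.

## SNP-distribution method

Polymorphism is defined on the pooled dataset: a column is a SNP if at
least two distinct bases occur across all samples after IUPAC expansion,
missing symbols ignored. All populations therefore share one position
list per marker. Allele counting is haplotype-based — each diploid
contributes two alleles, a heterozygote one of each — for consistency
with the expected-heterozygosity formula; missing alleles are excluded
from the denominator per population and site rather than imputed. The
three per-site metrics (squared Euclidean, modified squared chord,
Manhattan) all live on [0, 2] on the 4-simplex; squared Euclidean and
squared chord are semimetrics (no triangle inequality). Per-site
distances are arithmetic means over positions — sites in linkage
disequilibrium are averaged as if independent, which is the method's
declared trade-off — and every per-site distance is emitted to an audit
TSV so the averaging is inspectable.

## Diversity statistics

Per population and marker: mean number of distinct alleles per position
(over all L positions), expected heterozygosity
1 − (1/N)·Σ_k Σ_i x²_{i,k} with N equal to the **full marker length**
(monomorphic positions contribute zero, diluting the statistic — this is
intentional and matches the definition used for the reference survey),
and percent polymorphic positions counted **within** the population
(a population-specific quantity, unlike the pooled SNP list). The
across-marker average is unweighted; a length-weighted average would let
the longer marker dominate, which is not what a two-marker summary
should do. Allelic richness is not rarefied to equal sample sizes;
populations differ moderately in size (15–28), so richness comparisons
carry a small sample-size bias, noted as a limitation.

## Clustering and tests

Complete-linkage (furthest-neighbour) agglomeration is implemented
directly: merge the closest pair, inter-cluster distance = maximum cross
pair. Ties are broken toward the pair whose smallest original leaf
indices are lexicographically lowest, making the merge history — and the
Newick output — fully deterministic. Heights are provably non-decreasing
and asserted on every tree. Trees are serialised ultrametrically: a
child's branch length is (parent merge height − child height)/2, leaves
at height 0, spaces in labels replaced by underscores.

The permutation test compares the pair-weighted mean distance within
clusters to the mean among clusters (statistic = among − within),
permuting cluster labels over populations with sizes preserved. The
Monte-Carlo p-value uses the add-one estimator (1 + #{≥ observed}) /
(n_perm + 1), one-sided in the direction of separation, so p is never
exactly 0; an exhaustive mode enumerates all distinct assignments when
their number is manageable. Pair-weighting matters: with clusters of
3+3+3+5 populations there are 19 within-cluster pairs, and the pooled
within mean is the pair-count-weighted combination of the per-cluster
means, not their simple average.

One-way ANOVA uses the classical SSB/SSW decomposition; the Bonferroni
post-hoc runs pairwise two-sided t-tests on the pooled within-group
variance (MSW, with the ANOVA's within degrees of freedom), multiplying
raw p by the number of pairs, capped at 1. Normality is checked with a
one-sample Kolmogorov–Smirnov test against a normal with the sample
mean and SD; by default the asymptotic p-value with plug-in parameters
(the legacy procedure of classical statistics packages, conservative
because estimation is ignored), with a Lilliefors-corrected alternative
available since published p-values cannot adjudicate which variant was
used.

## Synthetic-data generator

The generator emulates the reference survey's shape: 14 populations in
clusters of 3+3+3+5, a configurable number of diploids per population
(default 20, matching the 15–28 range), two markers of 425 and 239
positions carrying 30 and 33 biallelic SNPs. Allele frequencies follow
the Balding–Nichols hierarchical island model — cluster frequencies are
Beta-distributed around an ancestral frequency with divergence
F_between (default 0.2), population frequencies around their cluster
with F_within (default 0.05) — and genotypes are Hardy–Weinberg draws.
Ancestral frequencies are uniform on [0.1, 0.9], avoiding near-fixed
SNPs. Background positions use a mildly AT-rich composition
(0.28/0.22/0.22/0.28). Sites whose realized pooled sample turns out
monomorphic are redrawn (genotypes first, then frequencies), mirroring
the ascertainment of real SNP panels, so configured SNP counts are
realized exactly. A fixed seed fixes every emitted byte.

What the generator does **not** emulate: linkage disequilibrium between
sites (sites are independent, so the haplotype method's linkage caveat
cannot be probed on synthetic data), tri-/tetra-allelic sites
(biallelic only, for analytic tractability), migration or isolation by
distance within clusters, sequencing error and alignment gaps. Passing
tests on synthetic data therefore demonstrate correctness of the
computations and recoverability of clean hierarchical structure, not
robustness to the messier features of field data.

## Problem sizes and numerics

The test suite and the reproduction script run the full study scale:
315/316 genotypes (49,455 / 49,770 pairwise distances) and 630/632
haplotypes (198,135 / 199,396 pairs), vectorised over chunks of pairs;
cluster-recovery checks use 20 seeded replicates of the 14×20 design.
Distance matrices are symmetrised and clipped at 0 to absorb float
round-off; matrix writers emit 10 significant digits so CSV/PHYLIP
round-trips agree to well below 1e-6. Degenerate inputs error early
with named offenders: ragged alignments, illegal symbols (1-based
position), unmapped samples, all-missing population/site combinations,
empty SNP lists, single-cluster permutation tests, zero-variance ANOVA.
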