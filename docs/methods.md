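# Methods

`lousepop` is a pipeline for multi-population population-genomic inference in
systems like host-specific parasites: a handful of populations (here, seal
lice on different seal host populations), a few diploid individuals each,
whole-genome SNP data on a fragmented draft assembly, and demographic
questions about the order, timing and permeability of population splits.
This note documents the models, conventions and numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Coalescent simulation (`simdata`)

Genealogies are drawn from the structured coalescent with msprime. All times
are in generations before present, all sizes are diploid effective sizes
(pairwise coalescence rate 1/(2N) per generation), and mutation rates are
per site per generation. Loci are independent and non-recombining — a
deliberate simplification matching the way downstream statistics treat
blocks/loci as exchangeable units; intra-locus recombination, selection and
gene conversion are out of scope.

Mutations follow the infinite-sites model: per locus the mutation count is
Poisson with mean `mu * L * (total branch length)`, branches are chosen
proportionally to length, and integer positions are drawn uniformly without
replacement; a locus too short for its realised mutation count raises an
error rather than silently merging sites. The ancestral allele becomes the
REF allele, so truth-polarized checks are possible. Haploid genomes are
paired into diploids in sampling order.

Sequencing-noise layers (`synthesize_vcf_annotations`) are intentionally
minimal but sufficient to exercise every downstream filter: per-genotype DP
is Poisson around a mean depth (DP=0 genotypes become missing), GQ is a
clamped normal on [0, 99], site QUAL a clamped normal, and a configurable
fraction of sites is converted into all-heterozygous artefacts emulating
collapsed repeats. Real short-read data have spatially correlated coverage,
allele-balance-dependent genotype errors and reference bias; none of that is
modelled, so passing filter tests here shows the cascade's logic is correct,
not that the thresholds are optimal for any real dataset.

Randomness: one master seed per operation; stage-level child seeds are
derived with `numpy.random.SeedSequence(master).spawn()` in a fixed order
and folded below 2^31 for msprime. Everything is bit-reproducible given the
seed.

### The demographic model registry

Eight competing demographies for a five-population system (lice of Arctic,
Baltic, Ladoga and Saimaa ringed seals, plus Baltic gray seal; optional
Baikal outgroup branch):

| model | structure | free parameters |
|---|---|---|
| 1 | Saimaa splits first, then Ladoga/Baltic | 12 |
| 2 | Baltic splits first, then Saimaa/Ladoga | 12 |
| 3 | Ladoga splits first, then Saimaa/Baltic | 12 |
| 4 | Saimaa split predates the Arctic split | 11 |
| 5 | Saimaa and Ladoga descend from an unsampled ghost lineage | 13 |
| 6 | model 1 + one admixture pulse gray -> Baltic | 14 |
| 7 | model 1 + continuous asymmetric migration gray <-> Baltic to the present | 15 |
| 8 | model 1 + an ancient bounded migration window (estimated start and end) | 16 |

Parameter counts follow from the parameterisation: model 4 reuses the
ringed-ancestor size for the Baltic+Ladoga ancestor; model 5's ghost lineage
shares the clade-ancestor size; model 7 adds two directional rates plus an
estimated onset time; model 8 additionally estimates the end of the window.
Migration involving the Baltic population is constrained to postdate the
Baltic/Ladoga split, since the population does not exist (backwards in time)
beyond it.

Default parameter values (the shipped "study mimic") place the five current
sizes at 4,600 / 43,000 / 90,000 / 1.2M / 4.9M diploids (Saimaa, Ladoga,
Baltic, gray, Arctic) with split times 16,720 / 15,090 / 192,179 / 4.8M
generations, mutation rate 3.5e-9 per site per generation and two
generations per year. The Baltic size and the ancestral sizes (clade
ancestor 1e5, ringed ancestor and root 2e6) are not constrained by any
single published number; they were chosen once so that expected
per-population diversity rank-orders with current size — the qualitative
regime the diversity-gradient experiments probe. That requires some care: a
large, anciently isolated population (gray) equilibrates to θ=4Nμ, while a
huge but recently isolated one (Arctic) mostly carries ancestral variation,
so the ancestor of the ringed clade must be large enough (2e6) for the
Arctic population's diversity to stay on top. These defaults are
illustrative of the study system, not a reconstruction of unpublished
search ranges.

### Reciprocal monophyly

`reciprocal_monophyly_fraction` simulates a clean two-population split and
scores, per locus, whether each population's haploid sample forms an
exclusive clade. At T = 5·Ne generations with 10 haploids per population the
measured fraction is ~75%, consistent with the classic allopatric-speciation
expectation that a majority of loci are reciprocally monophyletic after
4–5 Ne generations; the fraction is monotone in T, ~0 under panmixia and ~1
at T = 100·Ne.

## Filtering (`variant_filter`)

Rule order is fixed: (1) biallelic-only at read; (2) site QUAL > 30;
(3) summed site depth ≤ 2 × mean site depth of the input matrix;
(4) genotype masking for DP < 10 or GQ ≤ 30; (5) removal of sites
heterozygous in more than 14 individuals (an absolute count, matching a
22-individual cohort; a fractional variant is exposed for other cohort
sizes); (6) removal of sites with any missing genotype. Removed sites are
attributed to the first failing rule, making reports auditable; the source
filters are listed without an order, so this ordering is this package's
convention. The depth threshold is recomputed from the current input, so
exact idempotence is not guaranteed in pathological depth distributions; on
Poisson-depth data it holds and is tested.

LD pruning scans 50-SNP windows advanced by 10 SNPs within each scaffold
and, for any retained pair with squared Pearson dosage correlation above
0.1, removes the later site. This deterministic tie-break is documented as
a divergence from PLINK's heuristic, whose exact removal rule is not
reproduced. Monomorphic sites have undefined correlation and are always
retained.

## Diversity statistics (`diversity`)

"Polymorphic within a population" means both alleles observed among that
population's genotypes; sites fixed for the alternate allele are fixed
differences, not polymorphism (a documented choice — the usual shorthand in
the field leaves this ambiguous). SNP-sharing partitions assign each
site polymorphic anywhere to the exact subset of populations in which it is
polymorphic (the multi-set Venn decomposition), so subset counts sum to the
union. Downsampled polymorphism enumerates all C(n, k) subsets exactly
(cohorts here are ≤ 5). Observed heterozygosity takes an explicit
denominator: variant-only sites, or a caller-supplied callable total that
stands in for materialising invariant columns. Mitochondrial divergence is
the uncorrected p-distance in percent with pairwise deletion of N/gaps.

## PCA (`structure`)

Centred (optionally per-site standardised) alt-dosage SVD; the default is
unit variance, matching the standardising default of common population-
genetic PCA implementations. Component signs are fixed by making the
largest-magnitude coordinate positive. One empirical caveat the synthetic
experiments reproduce: with five populations there are four
between-population axes, and the two leading PCs capture only the two
strongest contrasts (here the gray-seal louse and Saimaa axes), so weakly
differentiated populations can coincide in the PC1–PC2 plane. The
clustering test therefore scores silhouettes over the leading four
components with centre-only scaling, under which every population separates
(unit-variance scaling up-weights the many rare variants private to the
largest population and inflates its within-cluster spread).

## ABBA-BABA tests (`dstat`)

Polarization retains only sites where every outgroup individual is
homozygous for the same allele (that allele is ancestral); ingroup derived
frequencies are dosage fractions. D uses the frequency-based per-site
products ABBA = (1−p1)p2p3, BABA = p1(1−p2)p3; the admixture fraction f
divides the observed Σ(ABBA−BABA) by the same sum computed with the donor
population split into two deterministic halves (alternating individuals in
population-map order; even indices to the P2 slot). Standard errors are
delete-one block jackknives over contiguous 1-Mb windows within scaffolds
(draft-assembly scaffolds are typically shorter, so blocks coincide with
scaffolds); SE = sqrt[(B−1)/B Σ(θ₋ⱼ − mean)²], Z = θ/SE. Monomorphic sites
contribute zero and are retained.

Calibration on synthetic data: under the no-gene-flow demography |Z| < 3 in
20/20 replicates of 2,000 loci; under a 5% pulse from the gray-seal louse
population into the Baltic population, f̂ averages within ±0.02 of 0.05
with Z > 3 for every Baltic-recipient quartet and non-significant D for
Saimaa/Ladoga recipients; the mean jackknife SE matches the replicate SD of
D across 50 simulations within ~1%.

## SFS demographic inference (`sfs_demography`)

The observed data are a k-dimensional folded SFS. Folding convention: a
cell is canonical when its total derived count is below half the total
allele count; at exact ties the lexicographically smaller of cell and
complement receives the full count (the reference tools do not print their
tie rule, so this package fixes its own deterministic one). Monomorphic
corners are masked, and in a folded spectrum all non-canonical cells are
masked as well.

Expected cell probabilities under a candidate demography are Monte-Carlo
estimates over `n_rep` independent locus genealogies. Rather than dropping
mutations, tskit's branch-mode allele-frequency spectrum gives, per
genealogy, the exact expected branch length subtending each joint frequency
class; under infinite sites, cell probabilities are proportional to the
mean of those lengths. This Rao-Blackwellised estimator needs far fewer
replicates than pattern counting for the same accuracy. Probabilities are
normalised over unmasked cells — a SNP-only composite likelihood in which
absolute θ (hence sequence length) cancels, which is why constant scalings
of all sizes and times are only identified through shape, and why the
scaled-down recovery experiments free parameters that change the shape.

The fit criterion is `L10 = Σ m_cell log10 max(p_cell, p_floor)` with
`p_floor = 1/(10 n_rep)` guarding observed cells that no simulated genealogy
reached. Model selection uses `AIC = 2k − 2 ln(10) L10`: recomputing the
published eight-model ranking from its printed log10 likelihoods and
parameter counts under this convention reproduces the printed ΔAIC column
to < 0.1, which is the arithmetic check shipped in the acceptance script.
`k` for a fit made here is the number of parameters actually freed.

Optimisation replaces the reference tool's conditional-maximisation cycles
(whose internals are not published) with seeded multi-start Nelder-Mead on
log10-transformed sizes/times (linear for [0,1] fractions), with common
random numbers: every likelihood evaluation inside one fit reuses the same
genealogy seed, making the Monte-Carlo surface continuous in the parameters
and hence optimisable by a derivative-free method. Out-of-bounds proposals
are rejected with infinite objective. Restart count, replicate count and
bounds are configuration; everything is deterministic given the seed.

Confidence intervals come from a block bootstrap: 1-kb blocks of sites are
resampled with replacement to the original block count and each replicate
SFS is refitted. Because the expected spectrum depends on the parameters
but not the data, the refits share one cached likelihood surface: cell
probabilities are precomputed (with the point fit's genealogy seed —
common random numbers) on a parameter grid around the estimates, and each
replicate takes the argmax over that grid (`likelihood_surface` exposes the
cache so one surface can score many datasets). Replicate scatter therefore
reflects data resampling, not Monte-Carlo noise, and resampling degenerate
data reproduces the point estimate exactly. An earlier design that
re-optimised every replicate with a warm-started simplex search collapsed
onto local modes of the rugged Monte-Carlo surface and badly understated
the intervals; the grid-cache design replaced it.

Two interval flavours are reported: the raw 2.5/97.5 percentiles of the
replicates, and a normal-method interval (estimate ± 1.96·SE of the
replicates, on the log scale for sizes/times). With few replicates the
percentile interval is order-statistic-limited — the extreme quantiles of B
draws cover a new draw with probability at most ≈ (B−1)/(B+1), i.e. ~90.5%
at B = 20 — so at small `n_boot` the SE-based interval is the calibrated
95% CI, and it is what the shipped coverage experiment scores (measured
coverage 92–93% over 100 simulated datasets). The coverage experiment uses
100-locus datasets: the data variance must dominate the residual
Monte-Carlo noise of the surface for a data-driven bootstrap to be
meaningful; with much larger datasets the composite-likelihood information
outruns what the shared surface can calibrate and the intervals undercover
— a practical caveat of simulation-based composite likelihoods to keep in
mind when choosing `n_rep`.

Parameter thinning for model selection keeps one uniformly chosen SNP per
1-kb block (`thin_one_per_block`); parameter estimation uses all SNPs.
Natural-unit conversion assumes μ = 3.5e-9 per site and generation and two
generations per year: years = generations / 2 (192,179 generations ↔
96,090 years), and migrant numbers N_m = N_recipient × m.

## Problem sizes used by the shipped experiments

Chosen as the package's own desk-scale defaults: diversity-gradient and
clustering checks use 500–3,000 loci × 1 kb over the full demography (×3
seeds); introgression calibration uses 20 × 2,000 loci (null) and
10 × 5,000 loci (5% pulse); parameter recovery fits two free parameters on
~87,000 SNPs with n_rep = 4,000; bootstrap coverage uses 100 datasets of
100 loci (shared 2,000-replicate surface) with n_boot = 20; the
reciprocal-monophyly experiment uses 1,000 loci
× 3 seeds. The acceptance script reruns only the model-ranking arithmetic
and the monophyly experiment; everything else lives in the test suite.

## Known limitations

- No intra-locus recombination and no linked selection; block/locus
  independence is assumed rather than modelled.
- The composite likelihood treats SNPs as independent; its absolute scale
  is not a true log-likelihood, and AIC differences inherit that caveat
  (as they do in the tools this emulates).
- The Monte-Carlo expected SFS floors unreached cells, which slightly
  flattens the surface for very rare cells at small `n_rep`.
- The noise model for DP/GQ/QUAL is deliberately schematic (see above).
- PLINK's exact LD-pruning heuristic and the reference tool's ECM optimiser
  are intentionally not reproduced; both substitutions are documented here.
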