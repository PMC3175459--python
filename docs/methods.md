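# Methods

`vcqtl` implements two-step variance-component QTL linkage mapping for
outbred two-line F2 intercrosses, together with a gene-dropping simulator of
the study design that generates all of its own test data.

## The model

For a quantitative trait measured on F2 animals,

    y = Xb + u_a + u_q + u_c + e

where `Xb` collects fixed effects (slaughter/fattening batch, sex) and
covariates (e.g. carcass or live weight, chop weight), `u_a ~ N(0, σ²_a A)`
is the additive polygenic effect with `A` the pedigree numerator
relationship matrix over the three-generation pedigree, `u_q ~ N(0, σ²_q
G(p))` is the QTL effect at genome position `p` with `G(p)` the
marker-conditional IBD relationship matrix, `u_c ~ N(0, σ²_c I_litters)` an
optional common-litter environmental effect, and `e ~ N(0, σ²_e I)`.

The polygenic model (H0: no `u_q`) is fitted once per trait; the QTL model
(H1) is refitted at every scan-grid position.  The detection statistic is
`LRT(p) = 2(logL_H1(p) − logL_H0) ≥ 0`, and only the per-chromosome maximum
is tested against significance thresholds; secondary peaks are reported
descriptively.  The proportion of variance attributed to the QTL is
`σ²_q / (σ²_a + σ²_q + σ²_c + σ²_e)` at the maximum.  A −1 LOD support
interval (log-likelihood within `ln 10` of the maximum, forced contiguous
through the maximum) approximates a 95% confidence interval for position.
Per-individual QTL genotypic effects are the BLUP solutions of the
mixed-model equations for the IBD term at the maximum.

### Modelling assumptions

- No dominance QTL variance and one QTL term per model; a single-trait
  (univariate) analysis.
- Founder gametes are mutually non-IBD, irrespective of founder line:
  both parental lines are outbred with known admixture history, so no
  within-line allele homogeneity is assumed.
- Haldane map function throughout (`r = (1 − e^(−2d))/2`, `d` in Morgans):
  crossovers without interference.

## IBD matrices by MCMC over segregation indicators

The hidden state per linkage group is the set of segregation indicators
`s(m, l) ∈ {0, 1}` for every non-founder meiosis `m` and locus `l`
(0 = grandpaternal).  The prior is uniform at the first locus and a Markov
chain across loci with Haldane switch probabilities.  Conditional on the
descent graph at one locus, the observed multi-allelic genotypes are
reproducible iff some assignment of alleles to founder gametes ("founder
slots") satisfies every genotype — the classic founder-allele-graph
existence check, implemented by constraint propagation with at most two
trials per free graph component.  The sampler targets the transmission
prior restricted to consistent states.

Proposals mix single-indicator flips with whole-meiosis tail flips (all
loci from a random start onward, crossing exactly one inter-locus
transition).  Acceptance uses the Barker rule `σ(Δ log prior)` times the
0/1 consistency factor; Barker keeps the chain aperiodic even where the
prior ratio is 1 (a Metropolis rule would alternate deterministically on an
uninformative single-locus group).  The chain is initialised by sequential
imputation in pedigree order with random tie-breaking and restarts; failure
to initialise signals Mendelian-inconsistent genotypes.  Chains run per
linkage group with seeds derived from the master seed, `20,000` iterations,
10% burn-in and thinning 10 by default (one iteration = one proposal sweep
over all meioses).

At each grid position (every 4 cM by default, augmented with declared
causal-locus positions) the indicator is drawn per retained sample through
the Markov bridge between flanking markers; `G(p)` entries are sample means
of half the number of IBD gamete pairs (diagonal `1 + P(own gametes IBD)`).
Matrices are accumulated through founder-slot count matrices and a single
rank-k update per sample block, and stored per `(group, position)` in one
`.npz` archive so that threshold simulations and per-trait scans reuse them.

Exactness checks: at a fully informative marker the matrix equals the
realized descent exactly; with all genotypes blanked its expectation over
chains equals `A`; on an 8-meiosis, 3-locus pedigree it matches exhaustive
enumeration of all descent states (organised as a transfer matrix over
per-locus configurations) within Monte-Carlo error.

## AI-REML

Variance components are estimated by residual maximum likelihood.  The data
are first projected onto an orthonormal basis of the null space of `X'`
(error contrasts), turning REML into unrestricted ML on the projected
problem; the conventional REML log-likelihood
`−½[log|V| + log|X'V⁻¹X| + y'Py]` is recovered through the identity
`log|V| + log|X'V⁻¹X| = log|X'X| + log|T'VT|`.  Updates are
average-information (AI) Newton steps with:

- projection of infeasible components onto a floor of `1e−8 ×` the sample
  phenotypic variance (so boundary optima are reached in one step, not by a
  geometric crawl), with step halving enforcing monotone ascent;
- an EM-style multiplicative fixed-point fallback when no damped AI step
  ascends;
- an active-set rule freezing floored components with non-positive scores
  (the Karush–Kuhn–Tucker condition for a boundary optimum).

Convergence requires relative log-likelihood change `< 1e−8` and relative
free-parameter change `< 1e−6`; the maximum is 200 iterations and
non-convergence is flagged, not raised.  Components at the floor are
reported as 0.  Fixed-effect GLS solutions and BLUPs of every random term
are computed at the optimum on request.  Sampling errors use the inverse of
the AI matrix (`SE_i = √[(AI⁻¹)_ii]`); the ratio estimate/SE is reported
per component, 0 at a boundary and undefined for a singular AI matrix.
A quality-control flag marks positions where the H1 total variance deviates
from the H0 total by more than 2% (variance inflation).

The engine caches the contrast projection and projected kernels per fixed
design, so a genome scan or a 500-replicate null study re-solves only the
per-position iterations.  In the null-threshold loop, positions whose QTL
score at the H0 optimum is non-positive are recorded as `LRT = 0` without
iterating — this reproduces exactly the active-set decision the first H1
iteration would take.

Fixed-effect factor levels with fewer than 2 records are merged into the
preceding level in run order (logged); records missing the response, a
factor or a covariate are dropped for that model only.

## Significance thresholds

Chromosome-wise thresholds are empirical quantiles (nearest-rank: rank
`⌊(1−α)n⌋ + 1`) of the per-chromosome maximum LRT over phenotypes simulated
under the polygenic-only null (`h² = 0.3`) on the *same* IBD matrices and
pedigree.  Breeding values follow the pedigree recursion (founders
`N(0, σ²_a)`, offspring = parent mean + Mendelian sampling
`N(0, ½σ²_a(1 − F̄_parents))`), which realises covariance `σ²_a A` exactly
without factorizing `A`.  Thresholds are computed once per map/design and
reused across traits regardless of per-trait record counts.  Genome-wise
levels map to chromosome-wise levels by the Šidák form
`1 − (1 − α)^(1/18)`; for `α = 0.05` this gives the 0.285% chromosome-wise
level (the plain Bonferroni form would give 0.278%; only the Šidák form
reproduces the 0.285% figure, and neither form reproduces the printed
"0.058%" for the 1% genome-wise level — both give ≈ 0.056%).  The χ² with
2 df (1% quantile 9.21 = −2 ln 0.01) serves as the theoretical upper-bound
reference; empirical 1% thresholds land below it, in the reported 7.7–9.5
range for mid-size groups.

The desk-scale threshold study uses the reduced design of the original
analysis: ~305 F2 in 4 paternal half-sib families, one ~120 cM group with
8 markers at 17 cM spacing, IBD every 4 cM computed once, and (at desk
scale) 500 phenotype replicates instead of 5,000; the Monte-Carlo error of
each quantile is reported alongside (order-statistic spread at ±1 SE of the
tail probability, ≈ ±0.5–1 LRT units for the 1% quantile at 500
replicates).  The quantile also varies with the simulated marker/pedigree
realisation itself, much as the original thresholds varied across
chromosomes.

## The synthetic study design

`reference_design()` freezes the emulated population: 16 F0 sires of one
line × 25 F0 dams of another → 18 F1 boars and 72 F1 sows (each boar mated
to a group of full-sib sows that are never his own sibs, one to three
litters per sow) → ~1,000 F2 in 32 slaughter batches; 18 autosomes carrying
170 microsatellite-style markers at exactly 17 cM spacing; two planted
mutations — a recessive one at founder-line frequency 0.08 (group 6, 74 cM,
large early-pH effect) and a dominant one at frequency 0.03 (group 15,
large glycolytic-potential effect); trait presets with means/SDs 159.4/24.8
(glycolytic potential, μmol/g) and 6.55/0.18 (pH at 45 min).

Choices where the study design is not fully specified, made once:

- **Marker informativeness.** 4 alleles per microsatellite with distinct
  line frequency profiles (∝ 1..4 in one line, reversed in the other; mean
  heterozygosity ≈ 0.70), emulating markers pre-screened for information
  content.  Configurable per design.
- **Mutation planting.** A founder-line frequency `p` is realised as a
  fixed count `max(1, round(2np))` of mutant copies among that line's
  founder gametes, so a declared mutation always enters the pedigree —
  the emulated study analysed mutations it had observed.  With the allele
  in one line only, the expected F2 allele frequency is `p/2`.  An optional
  `require_segregating` redraw conditions on the realised F2 frequency
  landing within [0.5, 2]× that expectation, mirroring analyses conditioned
  on observed segregation; the carrier-contrast studies use it.
- **Batch/sex/covariate structure.** F2 are assigned to 32 batches in birth
  order; batch effects are N(0, SD ≈ 5% of trait variance in the presets);
  covariates are independent normals with a linear effect.
- **Polygenic values** use the same pedigree recursion as the null
  simulator (exact `A` covariance).

What the simulator does **not** emulate: genotyping error and allele-binning
error (all genotypes pass Mendelian checks by construction), selection or
non-random mating, crossover interference, sex-specific maps, missing
genotypes beyond a uniform missingness rate, and real trait measurement
error structure.  Passing tests therefore demonstrate correctness of the
estimation machinery under the stated generative model, not robustness to
real-data artefacts.

## Mendelian checking

Trio checks (child shares one allele with each typed parent, drawable from
distinct parents) are followed by Lange–Goradia-style genotype elimination
run to a fixpoint, with joint (sire, dam) screening per nuclear family and
one dummy allele representing unobserved alleles (so untyped ancestors never
trigger false positives).  Genotypes already flagged by the trio screen are
masked during elimination to prevent cascades, and an emptied family is
attributed minimally: an individual is reported only if masking its genotype
alone restores consistency (falling back to the whole emptied set).  The
default policy for downstream analysis is to blank the offending genotype,
not to drop the individual.

## Numerical and procedural choices

- Matrix row order is pedigree topological order, fixed once per run.
- Ties in the maximum LRT break toward the smaller cM coordinate.
- Flanking markers of a maximum are the nearest map markers at ≤ and ≥ its
  position.
- Positions whose H1 fit fails or does not converge are flagged and carry a
  missing LRT; support intervals do not extend across them.
- Support intervals are forced contiguous through the maximum.
- Relationship matrices are validated as symmetric, diagonal in [1, 2],
  off-diagonal in [0, 2], PSD up to a stated jitter.
- Constant-response (zero-variance) traits yield fully flagged,
  non-informative scans rather than errors.
- All randomness flows from explicit seeds; per-group chain seeds derive
  from the master seed by group index, and identical inputs plus seed give
  bit-identical outputs.

## Desk-scale problem sizes

The shipped test suite exercises the full pipeline at sizes chosen to keep
a complete run within a desktop coffee break while preserving each check's
statistical meaning: the threshold study uses the 305-animal reduced design
with 500 null replicates (the quantile's Monte-Carlo error is accounted
for); parameter recovery uses n = 1,000 F2 with 25 phenotype replicates on
one genotype set (IBD matrices, like in the emulated study, are computed
once and reused); carrier-contrast signatures use ~320–360 F2 with 25
genome replicates and reduced MCMC iteration counts (2,500) whose IBD
matrices at the genotyped causal locus are already exact.

## Known limitations

- The MCMC sampler targets the transmission prior restricted to consistent
  descent states; it does not weight states by the number of compatible
  founder-phase assignments or founder allele frequencies.  At fully
  informative loci the two targets coincide; at partially informative loci
  the restricted-prior posterior is an approximation to the full
  single-locus likelihood weighting.  The exhaustive-enumeration oracle
  targets the same law, so tests verify the sampler against its declared
  estimand.
- No exact multipoint algorithms (Lander–Green / Elston–Stewart) are
  provided for large pedigrees; exact computation exists only in the test
  oracle for tiny pedigrees.
- Dense O(n³) REML iterations cap practical model sizes at a few thousand
  records; this matches the intercross designs the package targets.
- Two-QTL models, epistasis, dominance QTL variance and multi-trait models
  are out of scope.
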