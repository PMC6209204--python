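# Methods

This note documents the models and procedures implemented in `pedprio`, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Phenotype model

Diagnoses come from a fixed vocabulary (BD I/II/NOS, recurrent and
single-episode MDD, alcohol abuse, healthy) and are mapped to analysis
classes by a scheme object.  The *broad* scheme (segregation tables) keeps
non-BD psychiatric diagnoses as a separate `OTHER_PSYCH` class; the
*strict_linkage* scheme (default for linkage) sets them to `UNKNOWN`, so
allele-sharing statistics neither reward nor penalize them.  `married_in`
is an explicit input flag, never inferred: who counts as "related by
marriage only" is a study-design fact, not a property of the genotypes.

## Prioritization funnel

All stages are conjunctive predicates; stage order only shapes the
intermediate counts (the tests verify the final set equals the simultaneous
conjunction).  Choices that the data model forces:

- *Genotype evidence*: a passing call is heterozygous with alt-read
  fraction in [0.25, 0.75], depth ≥ 10 and quality ≥ 10.  The quality
  threshold is applied to the per-sample genotype quality; site-level
  quality may be supplied in its place when per-sample values are absent.
  The allele-balance band is applied per evaluated sample.
- *Shared-by-affected*: a variant must be positively observed (passing
  call) in every case; a missing genotype in any case fails the variant.
  The funnel's `genotype_pass` stage keeps variants with evidence in at
  least one case; the sharing stage then requires all.
- *Rarity*: strict `<` against the reference-exome MAF at 0.1%; a variant
  absent from the reference panel counts as rare.  The relaxed candidate
  list uses non-strict `≤` at 5% with a ≥ 1/5 consensus, exposed as config
  (`maf_inclusive`).
- *Consensus*: P ("possibly damaging") counts as damaging for the SNV rule;
  NA counts as non-damaging for SNVs and as non-D for indels.  Variants
  with an empty prediction vector are an error, not a silent pass.
- An optional blacklist of (chrom, pos, ref, alt) tuples models in-house
  artifact databases whose contents are not reproducible.
- Carrier status derived from calls treats hom-alt as carrier (≥ 1
  alternate allele with passing depth/quality); the allele-balance band is
  a heterozygote criterion and is not applied to hom-alt calls.
- Obligate-carrier inference is deliberately not automated; carrier status
  comes only from genotypes.

## Polygenic risk scores in families

Scoring orients every effect positive (negative β flips the effect allele
and complements the dosage), so the scaled score
`Σ β_i d_i / (2 Σ β_i)` is a relative risk load in [0, 1] — 0 means no risk
allele carried at any scored SNP, 1 means homozygous for all.  Clumping is
greedy by ascending p (ties broken by SNP id) with defaults r² = 0.1 within
500 kb; these defaults are ordinary practice and exposed as parameters.

The mixed model is `y = Xβ + g + e`, `Var(g) = σ²_g A`, `Var(e) = σ²_e I`,
with `A` the VanRaden-standardized genomic relationship matrix (or 2×
pedigree-expected kinship).  REML is profiled over λ = σ²_g/σ²_e after one
eigendecomposition of `A`: a coarse grid on log λ (±12, 49 points) followed
by bounded scalar minimization, with an explicit collapse to the λ = 0
boundary when it is not beaten.  Non-positive-definite `A` is bent by an
eigenvalue shift before fitting.  Binary phenotypes are treated on the
observed 0/1 scale, as the common family-based PRS workflow does; no
liability-scale transform is applied.  The default residual passed to the
association step is *environmental* (fixed effects and the BLUP of `g`
both subtracted); full residuals (fixed effects only) are available behind
a flag.

The association `residuals ~ PRS` reports the OLS slope, SE and R²; a
percentile 95% CI from ordinary nonparametric pair resampling (default
2,000 replications); a one-sided analytic p (upper normal tail of
slope/SE, alternative slope > 0, i.e. affected members carry more risk
load); and a permutation p `(1 + #{permuted slope ≥ observed}) / (1 + n)`
(default 10,000), permuting the residuals — permuting the PRS is
equivalent.  A perfect fit (zero residual variance) returns p = 0 rather
than dividing by zero.  The threshold sweep runs the ten conventional GWAS
inclusion thresholds (5e-8 … 0.2) and flags Bonferroni significance at
α/10; thresholds with no qualifying SNPs yield an undefined-flagged result,
not an exception.  Which contrast is analysed (cases vs healthy relatives,
or vs all non-BD members) is the caller's choice of phenotype vector; the
package does not fix it.

## Non-parametric linkage

Single-marker only, by design: the linkage workflow prunes markers to
near-independence (500 kb window, r² ≤ 0.01) precisely so that multipoint
machinery adds little; within that regime an exact single-marker treatment
is honest and fully auditable.  Multipoint Lander–Green computation is out
of scope.

The inheritance-vector space (2 bits per non-founder) is enumerated in full
up to 14 meiosis bits; larger pedigrees raise an error advising
subdivision.  No founder-couple symmetry reduction is applied: vectorized
enumeration is fast within the bound, and the plain representation keeps
the scoring bookkeeping transparent.  The marker likelihood sums over
founder-allele slot assignments; two exact accelerations matter in
practice: the assignment grid is cached per alphabet size, and alleles
never observed among typed members are collapsed into one pooled
pseudo-allele (the likelihood only tests slot-vs-observed equality, so the
collapse is lossless).  Mendelian inconsistencies are caught by a typed-trio
pre-scan that names the offending trio; jointly inconsistent data without a
single bad trio still raise an error when the total likelihood vanishes.
Allele frequencies are taken from marker metadata or estimated from the
sample when absent.

`S_pairs` sums IBD allele sharing over affected pairs (maximum bipartite
matching of the two slot pairs, correct under inbreeding); `S_all` is the
Whittemore–Halpern statistic `2^-a Σ_h Π b_f(h)!` over the `2^a` ways of
picking one allele per affected.  Null moments come from exact enumeration
over uniform vectors, giving `Z = (E_posterior[S] − μ₀)/σ₀`.  For null
(unlinked) markers the mean of Z is 0 but its variance is below 1 —
shrinkage of the posterior expectation toward the null mean at imperfectly
informative markers; the calibration tests use six-allele markers, where
the variance is ≈ 0.8.

Kong–Cox combination maximizes over δ ≥ 0 (one-sided): the linear model
`Π (1 + δ γ_i Z_i)` with δ bounded where `1 + δ γ_i z` would hit zero on
any family's null support, and the exponential model
`Π exp(δ γ_i Z_i)/c_i(δ)` with `c_i` computed from the family's exact null
score distribution.  With several families the default weights are equal
with Σγ² = 1.  LOD = log₁₀ likelihood ratio at δ̂ (δ capped at 30; at a
fully shared maximal vector the supremum −log₁₀ P(Z = z_max) is approached
within the cap); p-values use the one-sided ½χ²₀ + ½χ²₁ mixture, so
LOD = 0 reports p = 0.5.  The per-pedigree LOD ceiling evaluates the score
at the maximal-sharing vector with a point-mass posterior.  Suggestive
linkage is conventionally flagged at LOD > 2.2.

## Population substructure

The exact Hardy–Weinberg test conditions on the allele counts and sums the
probabilities of all heterozygote counts no more probable than the one
observed, computed in log-gamma space and normalized (monomorphic tables
return p = 1).  The substructure filter applies MAF ≥ 0.05, HWE p ≥ 1e-3,
masks the extended MHC (chr6 25–35 Mb) and the common chromosome-8
inversion (7–13 Mb) whose long-range LD distorts ancestry axes, then
windowed pruning (200-SNP window, 100-SNP step, drop r² > 0.2); the filter
is idempotent.  IBS similarity is the mean shared-allele fraction (0, ½, 1
per marker) over pairwise-complete markers; MDS is Torgerson
double-centering eigendecomposition of the squared *distance* matrix
(1 − similarity), keeping top-k positive components, with coordinate
columns divided by their SD for plotting.  A reference cohort (e.g. a
public panel) enters simply as additional rows.  Related clusters are
collapsed to one representative by single-linkage above a similarity
threshold, tie-broken to the lexicographically smallest id.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested:

- *Pedigrees*: a founding couple; per-couple sibship ~ round(N(2.5, 0.7))
  truncated at 1; a regulated number of children (≈ half, clamped to 1–3
  couples) marry a new founder and reproduce.  The clamp keeps
  six-generation pedigrees near the 25–45-member scale of real multiplex
  families instead of letting a branching process compound; sizes are
  reproducible per seed.
- *Rare variant*: one founder heterozygote, Mendelian ½-transmission.
  Phenotypes: BD with probability 0.7 for carriers (incomplete penetrance,
  as observed for all real candidate alleles) and 0.05 for non-carriers
  (phenocopies), otherwise another psychiatric phenotype at a 0.10 base
  rate so segregation tables have all columns populated, else healthy.
  A penetrance table rather than a full joint liability model: it makes
  carrier-conditional rates exact and testable.
- *Exome tables*: the causal variant is carried (as a passing het call) by
  exactly the ground-truth carriers, has no reference-panel MAF and four
  guaranteed damaging calls; ~300 background variants are each gene-dropped
  from a random founder (family-realistic sharing), with a log-uniform MAF
  spectrum and tool calls sampled at 0.85 concordance given a latent
  30%-damaging status.
- *Array genotypes*: founder haplotypes follow a latent-block model — each
  SNP copies a per-block Bernoulli(½) latent with flip probability
  ε = (1 − c^¼)/2, giving expected pairwise r² = c within blocks (default
  0.4) and ~0 between; offspring inherit whole parental haplotype blocks,
  so trios are Mendelian-consistent by construction.  No recombination maps
  and uniform 0.5 allele frequencies: adequate for LD-pruning, GRM and
  linkage tests, not for frequency-spectrum-sensitive analyses.
- *GWAS*: a 25% causal fraction with true effects scaled so the true score
  explains `h2_prs` (default 0.3) of unit liability; estimated betas add
  sampling noise for a notional 50,000-sample discovery study, so p-value
  thresholding behaves realistically.  Cohorts for association tests are
  unrelated individuals with liability = true score + N(0, 1 − h2_prs).

When a simulated family is analysed end to end, the sequenced "cases" are
the BD-affected carriers from the ground truth — mirroring how a real study
selects cases from the segregating lineage; with phenocopies present,
affected non-carriers exist and are excluded from sequencing the same way.
Families with fewer than two such cases are skipped and replaced (seed
advanced deterministically).

What passing tests do and do not show: the generator has no sequencing
artifacts, batch effects, population stratification within families,
genotyping error, or diagnostic uncertainty, so green calibration results
demonstrate the statistics are implemented correctly under their stated
assumptions — not that those assumptions hold in any particular real
cohort.

## Problem sizes used in the test suite

Simulation-backed checks are sized to make their tolerance bands
meaningful while keeping the suite quick: 1,000 gene-dropped biallelic
null markers (mean Z_all) on a fixed nine-member three-generation
pedigree plus 300 six-allele markers (variance band) on a compact one;
10⁵ Monte-Carlo gene drops for the posterior cross-check; 500 null and
100 powered PRS replicates with 199/999 permutations per replicate (the
API defaults remain 2,000 bootstrap / 10,000 permutation replications —
per-replicate permutation counts only set the p-value granularity, which
999 already makes exact at the 0.05 level); bootstrap coverage over 200
replicates at n = 50; and exhaustive HWE verification against an
exact-rational oracle for all tables up to 25 individuals.

## Known limitations

- Single-marker NPL understates the information a multipoint method would
  extract from dense maps; it is intended for heavily pruned panels.
- The exponential Kong–Cox LOD at a perfectly informative, fully shared
  marker approaches its supremum only as δ → ∞; the δ cap at 30 recovers
  it to ~1e-9 in LOD units.
- The REML profile assumes one genetic variance component; no
  gene-environment or dominance components.
- Bilineal-pedigree membership (who belongs to the offspring branch) is
  explicit input, not derived.
- The bundled example pedigree reconstructs an anonymized published family
  from its printed counts; its per-individual structure is synthetic and
  labelled as such.
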