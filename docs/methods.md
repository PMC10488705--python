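# Methods

`cyp2c9pgx` models the chain from unphased CYP2C9 genotypes to clinical
impact metrics in admixed populations. This note documents the models,
their assumptions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## The variant panel and star-allele space

The panel is five biallelic SNPs on NC_000010.11, each tagging one variant
star allele: rs1799853 (g.94942290C>T, *2), rs7900194 (g.94942309G>A, *8),
rs28371685 (g.94981224C>T, *11), rs1057910 (g.94981296A>C, *3) and
rs28371686 (g.94981301C>G, *5). The reference allele *1 is assigned by
default — absence of all panel variants on a haplotype. A haplotype
carrying two or more panel variants lies outside the six-allele space and
is reported as "undefined"; no such haplotype is catalogued for this panel
and none arises in the star-restricted analyses.

Activity values follow the classification used for the source frequency
tables: *1 = 1.0 (normal), *3 = 0.0 (no function), and *2, *5, *8,
*11 = 0.5 (decreased function). Current PharmGKB/CPIC reference material
lists *5 as no-function; the packaged JSON config makes the activity values
editable, so either convention is a one-line change. The default keeps
*5 = 0.5 because the packaged frequency tables pool *1/*5 with the AS = 1.5
diplotypes.

Individuals with a missing genotype at any panel locus are excluded from
phasing by default (an impute-as-reference flag exists but is off):
assigning *1 by absence of variants is only sound at typed loci.

## EM phasing and diplotype posteriors

Haplotype frequencies are estimated by the standard multinomial EM
(gene counting). For individual g with compatible unordered haplotype
pairs {(h_i, h_j)}, the E-step weights each pair by

    w_ij ∝ (2 if i ≠ j else 1) · f_i · f_j,

normalised within the individual; the M-step sets each frequency to its
expected haplotype count over 2N. The observed-data log-likelihood is
non-decreasing across iterations (property-tested); convergence is a
log-likelihood change below 1e-8, with a 1000-iteration cap.

Design choices:

- **Haplotype space.** Default is star-restricted (the six star-defining
  vectors), since observed diplotype tables contain only star pairs; full
  2^L enumeration is available for sensitivity analysis. In the
  star-restricted space every genotype of this panel has a unique phase
  (the five variants each define a different allele), so ambiguity — and a
  posterior below 1 — only arises in full-enumeration mode for multiple
  heterozygotes.
- **Initialisation.** Product of per-locus allele frequencies projected
  onto the space, uniform fallback; deterministic, no random restarts. At
  this problem size the likelihood is well-behaved and EM converges to the
  same optimum as an independent constrained maximizer (tested to 1e-3).
- **Numerical hygiene.** Frequencies below 1e-12 are clamped to zero and
  the vector renormalised, so posteriors never divide by numerical dust.
- **Calling.** Each individual gets the maximum-posterior diplotype; ties
  (possible only with exactly equal frequencies) break toward the
  numerically smaller star names. Inclusion requires posterior ≥ 0.95,
  inclusive at the boundary.

## Phenotype and recommendation mapping

The activity score (AS) of a diplotype is the sum of its alleles' activity
values, giving the grid {0, 0.5, 1.0, 1.5, 2.0}. AS = 2 → normal
metabolizer (NM); AS ∈ {1.0, 1.5} → intermediate (IM); AS ∈ {0, 0.5} →
poor (PM). AS = 0 does not occur in the packaged tables but is mapped for
completeness. EHR Priority Result Notation dichotomises NM →
Normal/Routine/Low Risk and IM/PM → Abnormal/Priority/High Risk.

CPIC NSAID recommendation buckets follow the AS grid: AS = 2 → usual
starting dose (Strong), AS = 1.5 → usual starting dose (Moderate),
AS ≤ 1.0 → adjust the initial dose or drug choice, with drug-specific
actions (meloxicam: reduce dose at AS = 1.0, alternative drug for PMs;
piroxicam: alternative drug, Moderate; tenoxicam: alternative drug,
Optional; other NSAIDs: lowest starting dose / reduced dose, Moderate).
The phenytoin guideline is surfaced only as an informational note for PMs,
with the explicit caveat that HLA-B*15:02 is not modelled.

By construction the Strong-usual bucket proportion equals the NM
proportion equals 1 − the High-Risk fraction on every cohort; this
consistency is asserted in tests.

## Count reconstruction from published frequency tables

Published cohort tables print rounded frequencies plus n. Integer counts
are recovered by the largest-remainder rule: start at floor(f·n), then
hand the missing units to the categories with the largest fractional
parts, ties to the earlier category. The result sums exactly to n and
every count is within one unit of f·n; for the packaged tables the
reconstruction is unique (verified exhaustively for the PUR row in tests).

The packaged fixtures cover four 1000 Genomes Admixed-American cohorts
(CLM n=94, MXL n=64, PEL n=85, PUR n=104), the three Brazilian census
race/Color subcohorts (White n=349, Brown n=357, Black n=351) and the
census-weighted Brazilian total (n=1057). Categories are
(*1/*1, *1/*2, *1/*3, *2/*2, *2/*3, *1/var), where *1/var pools *1/*5,
*1/*8 and *1/*11 (all AS = 1.5).

**Known inconsistency.** The published CPIC-bucket row for CLM
(0.213 Moderate / 0.138 Adjust) cannot be derived from the published CLM
diplotype frequencies, which imply 0.223 and 0.128 after count
reconstruction (21/94 at AS = 1.5; 10+0+2 = 12/94 at AS ≤ 1). The package
reproduces the diplotype-table-derived values and documents, rather than
resolves, the discrepancy; CLM is excluded from the bucket reproduction
checks.

**Census weighting.** The overall-Brazilian row is a White/Brown/Black
mixture weighted by census proportions 0.431/0.465/0.093, renormalised
(they sum to 0.989 as printed, covering 98.8% of the population). The
printed overall *1/*1 frequency (0.707) is not exactly reproducible from
the printed subcohort frequencies under either raw (0.701) or renormalised
(0.709) weights, so no reproduction check uses the weighted cohort;
`weighted_aggregate` implements the renormalised convention.

## Statistics

- **HWE.** Per-locus chi-square of observed genotype counts against
  (p², 2pq, q²)·N, df = 1, p-values from the asymptotic distribution; a
  monomorphic locus returns chi2 = 0, p = 1 by convention. Type-I error is
  calibration-tested at 5% ± 2% on 1000 simulated HWE loci.
- **Contingency tests.** Pearson chi-square without continuity correction
  (scipy), df = (r−1)(c−1), checked against an explicit (obs−exp)²/exp
  double loop.
- **Effect size.** Cramér's V = sqrt(χ²/(n·df_min)), df_min = min(r−1, c−1).
  Interpretation labels use Cohen's 0.10/0.30/0.50 thresholds divided by
  sqrt(df_min) (configurable); V = 1 on any diagonal table and V is
  invariant to row/column permutation (tested).
- **Pooling.** Mirroring the source tables, alleles *5/*8/*11 (frequency
  < 0.015 everywhere) pool into one allele class and diplotypes
  *1/*5, *1/*8, *1/*11 (frequency < 0.005) into *1/var for tests.

## The NNG risk model

Among NSAID-exposed patients with overall gastrointestinal-bleeding
probability q, carriers of a High-Risk phenotype (population frequency f)
have event probability q1 and non-carriers q0, constrained by
f·q1 + (1−f)·q0 = q. The effect size ties q1 to q0 either as a risk ratio
(q1 = RR·q0; closed-form q0 = q/(1 + f(RR−1))) or as an odds ratio
(bracketed root-solve on q0 to 1e-12). Then NNT = 1/(q1−q0) among carriers
and NNG = NNT/f.

NNG is strictly decreasing in f, in the effect size and in q (for
effect > 1), and diverges as the effect approaches 1 — all property-tested.
The two parameterizations coincide as q → 0: the relative gap in NNG is
approximately q0·(effect−1) and falls below 2% only for q ≲ 0.005 at
effect sizes up to 3 (about 3% at q = 0.02); the risk-ratio form is the
default because it reproduces all four published NNG values from a single
two-parameter calibration.

**Calibration.** The meta-analytic (q, effect) inputs are configuration,
not constants. `calibrate` recovers them from two (f, NNG) anchors by
nested bracketed root-finding (q ∈ (1e-6, 0.5) inner, effect ∈ (1+1e-6, 20)
outer, with a 256-point scan to bracket the outer sign change), and
verifies both anchors round-trip within 0.5 individuals. The packaged
anchors (f=0.365, NNG=230) and (f=0.071, NNG=989) give q ≈ 0.0214,
RR ≈ 1.698; forward prediction yields NNG 249.7 at f = 115/349 (White
subcohort) and 402.5 at f = 66/351 (Black) — the latter sits on a rounding
boundary and is reported as 403 against a published 402.

**Cost.** Total genotyping cost is NNG × cost-per-sample; the per-sample
cost embeds reagent prices and an exchange rate and is therefore a config
input (batch size is carried as metadata only).

## Synthetic cohorts

`simulate_cohort` draws, per individual, two independent haplotypes from a
star-allele frequency vector — Hardy-Weinberg equilibrium holds by
construction, matching the no-HWE-deviation regime of the packaged tables.
Unphased dosages are derived from the star-defining loci, and truth records
keep the simulated diplotype. `simulate_admixed` adds per-individual
ancestry proportions from a Dirichlet distribution and draws haplotypes
from the ancestry-weighted mixture of population frequency vectors,
reproducing the qualitative gradients seen in admixed Latin American
cohorts (*2/*3 tracking European ancestry, *5/*8/*11 African ancestry).
Default frequency presets (PEL-like, PUR-like, White-/Black-Brazilian-like)
are derived from the packaged count fixtures, with the pooled *1/var mass
split evenly across *5/*8/*11.

What the generator does **not** emulate: genotyping error and missingness
mechanisms, linkage with variants outside the panel (loci are in complete
star-allele phase structure by construction), novel multi-variant
haplotypes, inbreeding or substructure beyond the Dirichlet admixture, and
real ancestry-segment structure. Passing recovery tests therefore show the
estimator is correct under its own model assumptions, not that real
cohorts are free of those complications.

A single seeded NumPy generator drives each simulation; seeds are recorded
in output manifests, and identical seeds give byte-identical outputs.

## Problem sizes used in validation

Deterministic reproduction checks run on the packaged count fixtures
(n = 64–1057). Stochastic checks use 200 replicates of n = 1000 HWE
cohorts for haplotype-frequency recovery (estimates within 3 binomial
standard errors of truth in ≥ 95% of replicates), 1000 simulated loci of
n = 500 for HWE type-I calibration, and n = 3000–5000 admixed cohorts for
the ancestry-gradient checks. These sizes put Monte-Carlo noise well below
the tested tolerances while keeping the full suite fast.

## Known limitations

- Only the six star alleles of the panel are modelled: no CNVs, no
  structural alleles, no genotype calling from reads.
- The EM is plain (no partition-ligation); fine for 5 loci, not meant for
  large locus sets.
- Exact (Fisher/permutation) tests are out of scope; chi-square p-values
  are asymptotic.
- The NNG model inherits the transportability caveats of its inputs: q and
  the effect size come from meta-analyses in other settings, and the
  two-group dichotomy ignores AS gradation within the High-Risk class.
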