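# Methods

`pgxdili` re-implements, as a tested library, the pharmacogenomic
case-control analysis linking NAT2 ultraslow-acetylator (UA) and ATP7B
832R/R genotypes to anti-tuberculosis drug-induced liver injury (AT-DILI),
together with the in-vitro isoniazid(INH)-copper synergy analysis that
motivates the gene-gene interaction. This note records the models, the
defaults and why, the numerical choices, and what the synthetic data do and
do not establish.

## Exact 2x2 inference

All case-control comparisons condition on both margins of the 2x2 table
(a, b; c, d) = (exposed/unexposed cases; exposed/unexposed controls), so the
exposed-case count X follows Fisher's noncentral hypergeometric
distribution with odds parameter psi. The point estimate is the conditional
MLE — the psi solving E_psi[X] = a — and the 95% interval is the
Cornfield-type tail inversion: the lower bound solves P_psi(X >= a) = 0.025,
the upper solves P_psi(X <= a) = 0.025. This matches what `fisher.test` in R
reports and is the estimator behind published "Fisher's exact test" odds
ratios. Mid-P variants are deliberately not used.

Numerics: the pmf is evaluated in log space (log-gamma binomials +
log-sum-exp), so tables with psi up to e^80 stay finite. Root finding is
bisection on log(psi) over [-80, 80] to an absolute tolerance of 1e-10;
boundary counts are handled analytically (a at the support maximum gives
OR = +inf with a finite exact lower bound; at the minimum, OR = 0). The
two-sided Fisher P sums all tables with the observed margins whose central
probability does not exceed the observed one, with a 1e-7 relative cutoff
slack (the standard convention).

One reproducibility caveat worth recording: common statistics software
solves the upper-bound tail equation with a loosely toleranced root finder
on the reciprocal-odds scale, so published upper CI bounds of
near-degenerate tables can carry sub-percent solver slack. Our bounds
satisfy the defining tail equations to 1e-10 (cross-checked against an
independent implementation of the distribution), and the test suite pins
the defining equations rather than any particular solver's output.

Supporting statistics: the Cochran-Armitage trend test uses the standard
score form with additive weights (0, 1, 2) and a two-sided normal P; the
exact Hardy-Weinberg test conditions on allele counts and sums
probabilities of heterozygote configurations no more probable than the
observed one; multiple testing uses Benjamini-Hochberg step-up q-values
(via statsmodels).

## Predictive values

Sensitivity and specificity come from the case-control counts; PPV and NPV
are standardized to an assumed population prevalence p of AT-DILI via
Bayes' rule, because a retrospective design carries no prevalence
information. The default p = 0.05 is the value at which the combined-cohort
counts reproduce all four published predictive values simultaneously
(PPV 60.0% for the combined genotype vs 18.7% for UA alone; NPV 95.6% vs
96.1%) — note the NPV assignment: the combined genotype gives the slightly
*lower* NPV (95.6%), UA alone the higher (96.1%). The significance of the
PPV difference is implemented as a Fisher test on the predicted-positive
compositions of the two markers; this treats the carrier sets as
independent although one nests the other, and is flagged as an assumption.

## NAT2 star-allele calling

Five tagging SNPs distinguish the common Korean NAT2 haplotypes:
rs1041983 (c.282C>T), rs1801280 (c.341T>C), rs1799930 (c.590G>A),
rs1208 (c.803A>G), rs1799931 (c.857G>A). Default allele definitions:
*4 all-reference; *5 = 341C+803G; *6 = 282T+590A; *7 = 282T+857A;
*12 = 803G alone. *19 is not resolvable from these five sites and is
omitted from the default table; the table is YAML-overridable. The rare
rs1805158 (p.R64W) is ignored for phenotype, consistent with its observed
lack of effect on acetylator status.

Diplotypes are resolved by exhaustive enumeration of all unordered
star-allele pairs whose summed site vectors match the unphased dosages
(missing sites unconstrained). Phase ambiguity is resolved by an
EM-estimated haplotype-frequency posterior, weight proportional to
2^[het] * f(h1) * f(h2); EM iterates the multinomial fixed point to a 1e-8
max-change tolerance or 500 iterations, aggregating the at-most 3^5
distinct genotype vectors. Posterior ties go to the lexicographically
smallest pair with an ambiguity flag; any call with more than one pair
above posterior 0.01 is flagged ambiguous.

Acetylator phenotype follows the standard mapping — RA *4/*4; IA *4/x for
x in {*5, *6, *7, *12, *19}; SA *5/*6, *5/*7; UA *6/*6, *6/*7, *7/*7.
Diplotypes outside that list are classified by rule generalization and
flagged `extended_rule`: both alleles in {*6, *7} are UA; a *5 paired with
another reduced-function allele (including *5/*5) is SA; one
normal-function allele (*4, *12) with a reduced allele is IA; two
normal-function alleles are RA. ATP7B rs1061472 and CYP2E1 rs3813867 are
mapped dosage-to-class (K/K, K/R, R/R and *1A/*1A, *1A/*5, *5/*5), with
ATP7B ref/alt orientation normalized against the canonical c.2495A>C
definition. The combined risk genotype is UA together with R/R; unknown
inputs yield False with an uncertainty flag rather than a silent call.

DILI classification from peak liver-function values: ALT >= 5x ULN, or
ALP >= 2x ULN, or ALT >= 3x ULN with total bilirubin >= 2x ULN; a
criterion with missing inputs evaluates false.

## Genotype QC

Calls with known GQ < 20 or DP < 20 are set missing (calls lacking GQ/DP
pass — these fields are optional in the input); variants with more than 10%
missing calls, or exact-HWE P < 1e-6, are removed. HWE is evaluated on
controls by default (cases may legitimately deviate under association);
the group is configurable. Missingness uses the whole-matrix denominator.
Sex chromosomes are dropped before association by default. QC is
idempotent at fixed thresholds.

## Association scans

Common variants (MAF >= 5% on the union of the compared groups — the
reference's denominator is unstated) are tested per variant with allelic
2x2 tables by default (matching trend-model semantics; dominant/recessive
codings by flag) against either treatment-tolerant or population controls;
both the exact Fisher P and the trend P are reported side by side, with
Fisher as the default ranking key. Volcano rows carry log2 OR and -log10 P
with significance tiers at P < 0.01 and P < 0.001; infinite ORs are
clamped one unit beyond the largest finite |log2 OR| and flagged. The
genomic inflation factor is the median chi-square(1) quantile of the P
values over 0.4549.

Rare variants (reference-population AF < 5%) with protein-altering
consequences (missense, nonsense, frameshift, or splicing within 2 bp of
an exon junction) are collapsed per gene into minor-allele-count burden
scores; the case-control difference in mean burden is tested by seeded
permutation (default 10,000 permutations, two-sided (r+1)/(B+1) P) because
the cohorts are too small for asymptotic nulls. Genes enter the report
with more than two qualifying variants. Kernel-based tests (SKAT family)
are out of scope; the burden statistic covers the collapsing design.

## Dose-response and synergy

Viability is (A_treated - A_blank)/(A_control - A_blank) x 100, not
clamped. Cytotoxicity curves use the four-parameter logistic in log10 dose,
Y = Bottom + (Top-Bottom)/(1 + 10^((LogLD50 - X) * Hillslope)), fit by
least squares from the deterministic start (Top = max Y, Bottom = min Y,
LogLD50 = mid-range X, Hillslope = -1) to 1e-8 tolerances; CC50 = LD50 =
10^LogLD50. Fits are exactly scale-equivariant in dose. A fitted positive
Hillslope (viability rising with dose) is flagged non-cytotoxic; flat
responses and transitions far outside the dosed range are fit failures.

Drug-pair interaction uses Loewe additivity: combination dose pairs
(d1, d2) reaching 50% cytotoxicity are scored with the interaction index
d1/D1 + d2/D2 against single-agent CC50s D1, D2. Combination points come
from a ray design (drug-2 dose fixed per ray, 1-D 4PL over drug 1), the
minimal assumption consistent with isobolograms of CC50 pairs; the
checkerboard alternative is not assumed. The qualitative call uses the
mean index with a band tau = 0.2 (synergistic below 1 - tau, antagonistic
above 1 + tau) — the reference analysis makes only a qualitative call, so
tau is this package's own threshold, configurable.

## Synthetic cohorts

The generator draws two NAT2 haplotypes and an independent ATP7B genotype
per individual under Hardy-Weinberg equilibrium, assigns disease by the
multiplicative odds model
odds = baseline * OR_UA^[UA] * OR_RR^[R/R] * OR_int^[UA and R/R],
and fills case/control quotas by rejection (retrospective design). Default
haplotype frequencies (*4 0.5993, *5 0.045, *6 0.2207, *7 0.13, *12 0.005;
ATP7B alt 0.3742) are back-solved under HWE from the Korean population
reference genotype-class frequencies — (0.2207+0.13)^2 = 12.3% UA,
0.3742^2 = 14.0% R/R, product = 1.7-1.8% co-occurrence — and are
config-overridable. Default effect sizes OR_UA 5.6, OR_RR 2.0, OR_int 2.9
put the combined-genotype odds ratio near 32.5, the study's headline
estimate; baseline odds 0.05 gives a realistic AT-DILI attack rate.
NAT2 and ATP7B are simulated independent (chromosomes 8 and 13); filler
variants are drawn independent of status with uniform MAF in [0.05, 0.5];
no linkage disequilibrium is simulated.

Liver-function values are log-normal with medians and IQRs anchored to the
observed case/control distributions (e.g. case ALT median 349, IQR
257-662 IU/L; control 17, 12-26), truncated so cases always exceed the
5x-ULN ALT criterion and controls stay inside reference ranges. That makes
the generated labels consistent with the biochemical classifier by
construction — useful for pipeline tests, but it means passing tests say
nothing about borderline biochemical presentations, mixed/cholestatic
phenotypes, genotyping error, population structure, or LD, none of which
are emulated.

All randomness flows from one integer seed; outputs are byte-identical
across re-runs.

## Problem sizes used in the test suite

The suite runs exhaustive enumeration oracles for Fisher and HWE tests on
all tables with total up to 40; conditional-MLE/CI defining-equation checks
exhaustively to total 16 plus 300 random tables to total 40; CI coverage on
2000 simulated tables; end-to-end parameter recovery on 100 seeded cohorts
of 720 cases / 2050 controls (ten times the study size); and a 500-variant
null scan for type-I calibration. These sizes were chosen to give stable
binomial tolerances while keeping the default run in the low minutes.

## Known limitations

- Star-allele calling covers the five-SNP Korean tagging panel, not a
  full nomenclature catalog; unusual haplotypes collapse onto the nearest
  definable diplotype or yield no-call.
- The burden test is a plain collapsing statistic; variance-component
  kernel tests and MAF weighting are not implemented.
- The PPV-difference test treats two nested carrier sets as independent
  samples.
- Copy-number calling (e.g. GSTM1 null), annotation generation, read
  alignment and variant calling are out of scope; genotypes enter as
  VCF/TSV.
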