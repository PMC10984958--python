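# pgxdili

Pharmacogenomic case-control analysis of anti-tuberculosis drug-induced
liver injury (AT-DILI): who is at risk of isoniazid hepatotoxicity, and how
much does carrying two interacting pharmacogene genotypes raise that risk?

The package implements, end to end and on plain VCF/TSV inputs:

- **NAT2 star-allele calling** — diplotypes from the five Korean tagging
  SNPs (rs1041983, rs1801280, rs1799930, rs1208, rs1799931) by exhaustive
  enumeration with an EM haplotype-frequency posterior for phase-ambiguous
  genotypes, mapped to acetylator phenotype (RA/IA/SA/UA); ATP7B rs1061472
  (p.K832R) and CYP2E1 rs3813867 genotype classes; the combined
  NAT2-UA + ATP7B-832R/R risk-genotype flag; biochemical DILI criteria
  (ALT ≥ 5×ULN, ALP ≥ 2×ULN, or ALT ≥ 3×ULN with bilirubin ≥ 2×ULN).
- **Exact 2×2 inference** — for a table (a,b;c,d) with fixed margins the
  exposed-case count follows Fisher's noncentral hypergeometric
  distribution with odds parameter ψ; the package reports the conditional
  MLE ψ̂ solving E_ψ[X] = a, the tail-inversion 95% CI
  (P_ψ(X ≥ a) = α/2, P_ψ(X ≤ a) = α/2), the two-sided Fisher P, exact
  Hardy-Weinberg and Cochran-Armitage trend tests, BH-FDR q-values, and
  prevalence-standardized PPV/NPV.
- **Association scans** — per-variant exact scans of common variants
  (MAF ≥ 5%) against treatment-tolerant or population controls with
  volcano/QQ summaries and the inflation factor λ; gene-collapsed
  rare-variant burden tests with seeded permutation P values.
- **Dose-response synergy** — 4PL viability fits
  (Y = Bottom + (Top−Bottom)/(1 + 10^((LogLD50−X)·Hillslope))), CC50
  extraction, and Loewe-additivity isobologram interaction indices
  (d1/D1 + d2/D2) for drug-pair synergy calls such as isoniazid-copper.
- **Synthetic cohorts** — Hardy-Weinberg star-allele cohorts at Korean
  population genotype-class frequencies (UA ≈ 12.3%, 832R/R ≈ 14%,
  co-occurrence ≈ 1.8%) under a logistic disease model with main-effect
  and interaction odds ratios, byte-reproducible from a single seed, so
  every pipeline stage is testable without any external data.

## Worked example

Exact inference on the combined-cohort carrier counts (20 of 72 AT-DILI
cases vs 13 of 205 treatment-tolerant controls carrying NAT2 UA):

```sh
$ pgxdili table2x2 --a 20 --b 52 --c 13 --d 192
{
  "or": 5.634924700998395,
  "ci": [
    2.4809765784477675,
    13.227910034060722
  ],
  "p": 7.246477328420214e-06,
  "ppv": 0.18735148967282048,
  "npv": 0.9609975266724231
}
```

The odds of AT-DILI are about 5.6-fold higher in ultraslow acetylators
(95% CI 2.5-13.2, exact P = 7.2e-6); standardized to a 5% population
prevalence, UA carriage alone has a positive predictive value of 18.7%.
Running the full risk-genotype report over the packaged study counts
(`pgxdili report`) shows the interaction: carriers of both NAT2 UA and
ATP7B 832R/R have OR 32.4 (95% CI 4.5-1435) versus tolerant controls, and
their PPV rises to 60.0% at the same prevalence while the NPV stays
essentially unchanged (95.6% vs 96.1%).

A full synthetic round trip — simulate a cohort, QC it, call genotypes,
and rebuild the report from the calls:

```sh
pgxdili simulate --seed 17 --out sim/
pgxdili qc --vcf sim/cohort.vcf --pheno sim/phenotypes.tsv --out qc/
pgxdili call --vcf qc/qc.vcf --out calls.tsv
pgxdili report --calls calls.tsv --pheno sim/phenotypes.tsv
```

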