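# synostat

Statistical toolkit for establishing a dominant, incompletely penetrant
disease gene from cohort resequencing and family follow-up, built around
the genetics of craniosynostosis (CRS, premature cranial-suture fusion)
and the BMP-pathway inhibitor *SMAD6*.

It is aimed at statistical geneticists and clinical-genomics analysts who
have (a) a table of candidate variants with gnomAD-style population allele
counts and in-silico predictor scores, (b) proband phenotypes (suture
class, syndromic status), and (c) nuclear pedigrees with carrier status
and, optionally, genotypes at a common modifier SNP.

## What it computes

* **Rare + damaging stratification.** A variant is kept iff
  AF_max < AF_max_credible and it is predicted loss-of-function or has
  deleterious score DS ≥ 4/6. AF_max is the greater of the maximum
  per-population allele frequency (populations with ≥ 2 observed alleles,
  excluding "Other") and the overall allele frequency. The frequency
  ceiling follows the standard dominant-model closed form

      AF = prevalence · genetic_contribution · allelic_contribution
           · inheritance_factor / penetrance

  (defaults give 4.5 × 10⁻⁵). A 5′UTR helper reports whether a point
  substitution creates a new upstream ATG and whether it is in frame with
  the main ORF.
* **Cohort burden.** Prevalence tables by suture class × syndromic
  status, LoF enrichment versus a reference population (fold and
  one-tailed Fisher P), subtype rate ratios (two-tailed Fisher P), and
  Spearman rank correlation for score-versus-assay concordance.
* **Family genetics.** De novo / maternal / paternal transmission
  summaries, sib recurrence, penetrance = recurrence ÷ transmission
  probability, the TDT χ² = (b−c)²/(b+c) on modifier-SNP transmissions,
  and the two-locus carrier association (risk-allele present vs absent ×
  affected vs unaffected) with cross-study table merging.
* **Synthetic cohorts.** Seeded generators for variant tables and
  pedigrees with known ground truth, plus Monte-Carlo operating
  characteristics (type-I error / power of the two-locus test, penetrance
  estimator bias).

## Worked example

```python
from synostat import (
    lof_enrichment, subtype_contrast, estimate_penetrance, sib_recurrence,
    tdt, merge_two_locus, two_locus_p, two_locus_table,
)
from synostat.datasets import (
    COHORT_LOF, REFERENCE_LOF, two_locus_carriers_this_study,
    two_locus_timberlake,
)

e = lof_enrichment(*COHORT_LOF, *REFERENCE_LOF)   # 9/1590 vs 9/29066 alleles
print(f"LoF enrichment {e.fold:.1f}-fold, one-tailed P = {e.p_value:.1e}")

ratio, p = subtype_contrast(12, 207, 3, 316)      # metopic vs sagittal
print(f"metopic vs sagittal rate ratio {ratio:.1f}, two-tailed P = {p:.3f}")

pen = estimate_penetrance(sib_recurrence(2, 25), transmission_prob=0.5)
print(f"sib recurrence {pen.recurrence:.0%} -> penetrance {pen.penetrance:.0%}")

chi2, p = tdt(12, 7)
print(f"TDT chi2 = {chi2:.2f}, P = {p:.2f}")

table, _ = two_locus_table(two_locus_carriers_this_study())
merged = merge_two_locus(table, two_locus_timberlake())
print(f"merged two-locus one-tailed P = {two_locus_p(merged):.4f}")
```

prints

```
LoF enrichment 18.3-fold, one-tailed P = 8.4e-08
metopic vs sagittal rate ratio 6.1, two-tailed P = 0.002
sib recurrence 8% -> penetrance 16%
TDT chi2 = 1.32, P = 0.25
merged two-locus one-tailed P = 0.0019
```

— i.e. heterozygous LoF alleles are ~18-fold enriched in the cohort over
the population reference; rare damaging variants are 6.1× more frequent in
metopic than sagittal synostosis; the 8% recurrence among carrier-parent
offspring implies ~16% penetrance under 50% transmission; this cohort
alone shows no modifier-SNP transmission distortion (P = 0.25), while the
association pooled with the earlier study remains significant (P ≈ 0.002).

## Command line

```bash
synostat stratify --variants variants.tsv --config cfg.yaml \
    --out kept.tsv --report report.tsv
synostat burden   --probands probands.tsv --kept kept.tsv --out burden.json
synostat families --ped cohort.ped --meta meta.tsv --out families.json
synostat twolocus --ped cohort.ped --meta meta.tsv \
    --merge-with prior.json --out twolocus.json
synostat simulate variants --seed 7 --out sim.tsv
synostat simulate families --seed 7 --ped-out sim.ped --meta-out sim.tsv
synostat simulate oc --seed 7 --out oc.json
```

Formats: TSV tables (`NA` for missing), 6-column PED pedigrees with a
metadata sidecar TSV, YAML/JSON configs, JSON + markdown reports. Exit
codes distinguish schema (2), data (3) and config (4) errors.

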