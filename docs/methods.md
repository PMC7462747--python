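# Methods

## Scope and model

`synostat` implements the statistical workflow used to establish a
dominant, incompletely penetrant disease gene from cohort resequencing and
family follow-up, with craniosynostosis (CRS) and the inhibitory SMAD
*SMAD6* as the motivating setting. The workflow has four stages:

1. **Variant stratification.** A candidate variant is kept iff it is
   *rare* and *damaging*. Rarity compares AF_max — the greater of (a) the
   maximum per-population allele frequency among reference populations
   carrying at least `min_population_allele_count` (default 2) alleles,
   excluding the catch-all "Other" population, and (b) the overall allele
   frequency — against a maximum credible population allele frequency,
   with strict `<` at the boundary. Damage is predicted loss-of-function
   (frameshift, stop-gain, canonical splice donor/acceptor) or a
   deleterious score DS ≥ 4, where DS counts how many of up to six
   in-silico missense predictors call the variant deleterious.
2. **Cohort burden.** The kept variants are tabulated by suture class and
   syndromic status; LoF burden is contrasted with a reference population
   and suture subtypes with each other, by Fisher's exact test.
3. **Family genetics.** Pedigrees classify each proband's variant as de
   novo or parentally transmitted; sib recurrence among the transmitting
   parents' other offspring, divided by the 50% transmission probability,
   estimates penetrance; a common modifier SNP is tested by TDT and by a
   two-locus carrier association.
4. **Synthetic cohorts.** Seeded generators emulate the variant table and
   the nuclear families so every stage is testable end-to-end against
   known ground truth.

## Maximum credible allele frequency

For a dominant model the ceiling on a causative allele's population
frequency is

    AF_max_credible = prevalence × genetic_contribution
                      × allelic_contribution × inheritance_factor
                      / penetrance

with `inheritance_factor = 0.5` converting a heterozygous-case frequency
to an allele frequency. The shipped defaults (prevalence 1/2000,
penetrance 0.2, gene-level contribution 0.06, allelic contribution 0.6)
give 4.5 × 10⁻⁵; the two contribution terms jointly encode a genetic
heterogeneity share of 3.6% for the most frequent single allele, chosen so
the closed form reproduces the conventional CRS threshold. All five
factors are user configuration — the formula, not the defaults, is the
contract.

## Predictor ensemble

The six-predictor set is configuration (name, threshold, direction). The
shipped default — SIFT < 0.05, PolyPhen-2 HDIV > 0.452, LRT < 0.001,
MutationTaster > 0.5, FATHMM < −1.5, PROVEAN < −2.5 — is a conventional
missense panel and explicitly provisional; analyses with a different
annotation stack should supply their own panel in the config file.
Unavailable scores never count toward DS but are reported, so DS 4 with 4
available calls is distinguishable from 4/6. A missense variant with no
available predictors is flagged unevaluable and not kept.

## Exact-test conventions

* One-tailed Fisher P is the hypergeometric tail on the side of the
  observed association, except for the two-locus test, whose direction is
  fixed a priori as "risk allele increases manifestation" (the prior
  study's hypothesis), not chosen from the data.
* Two-tailed Fisher P sums all tables (fixed margins) with point
  probability ≤ the observed table's — the convention of mainstream
  statistical software, and the one that yields P = 0.002 for the
  metopic-versus-sagittal contrast.
* Degenerate tables (a zero margin) return P = 1.
* The TDT χ² is (b−c)²/(b+c) with **no** continuity correction: on 12
  transmitted versus 7 untransmitted alleles this gives χ² = 1.316,
  P = 0.251, whereas the Yates-corrected statistic (0.84, P = 0.36) does
  not match the conventional reporting for these counts.
* LoF enrichment is computed on allele denominators (2 × probands against
  the reference allele number); with the counts of interest a
  per-individual computation gives the same fold to 3 significant figures.

Fisher's exact test, the χ² tail and Spearman's ρ are delegated to
`scipy.stats`; the test suite checks them against independent hand-written
oracles (hypergeometric enumeration with exact rationals on every 2×2
table with N ≤ 30; midrank-and-Pearson for ρ).

## Penetrance estimation and its caveat

Penetrance is recurrence ÷ transmission probability, capped at 1 with a
flag. The estimator deliberately reproduces the field's simple arithmetic
(2/25 ÷ 0.5 = 16%) and makes its assumptions explicit: unaffected
offspring are not genotyped, so the 50% transmission rate is assumed
rather than observed, and proband ascertainment is assumed to be
proband-indexed (sibs are an unselected sample of carrier-parent
offspring). No correction for ascertainment of the probands themselves is
attempted.

## Synthetic-data generators

**Variant tables.** Pathogenic variants are effectively absent from the
reference (≤ 1 allele overall, so AF_max < 4.5 × 10⁻⁵ by construction)
and are LoF with probability 0.5, otherwise missense with each predictor
exceeding its threshold independently at 0.9; benign variants draw a true
AF log-uniformly on [10⁻⁶, 10⁻²] (straddling the rarity threshold),
binomial per-population allele counts at gnomAD-scale allele numbers
(240 000 total across six populations), and benign panels at 0.15 per
predictor. Consequently the joint filter has sensitivity 1.0 for simulated
pathogenic LoF by construction, ≈0.98 for pathogenic missense
(P[Bin(6,0.9) ≥ 4]), and specificity ≈0.99 for benign variants. The
generator does not emulate linkage between variants, sequencing error, or
annotation disagreement — passing tests say the *statistics* behave as
designed, not that real annotation pipelines are this clean.

**Families.** Each family has one clinically unaffected carrier parent
(or, at a configurable de novo rate, noncarrier parents), 1–4 offspring,
50% transmission, and affection of carrier offspring at the configured
penetrance. Modifier genotypes follow Hardy–Weinberg at risk-allele
frequency 0.327 (the non-Finnish European frequency of the modifier SNP);
a modifier effect is parameterized as a penetrance pair
(with / without the risk allele, dominant coding). Under ascertainment the
first offspring is the proband — an affected carrier by construction,
genotype drawn ∝ HWE × genotype-specific penetrance — and the carrier
parent's genotype is drawn ∝ HWE × (1 − penetrance), both exact
consequences of conditioning on the observed phenotypes. This
proband-indexed design keeps sib recurrence unbiased for
transmission × penetrance, which ascertainment on "≥ 1 affected
offspring" would not (it truncates the affected count at 1 and biases
recurrence downward). Under the null (no modifier effect) both
conditionings are inert and genotype is independent of affection, so the
one-tailed two-locus exact test's type-I error is bounded by α.

**Operating characteristics** are Monte-Carlo: per replicate the family
generator runs with a seed drawn from one root generator, the two-locus
table is built over all carriers (unaffected carrier parents plus carrier
offspring), and rejection at α, penetrance bias, and RMSE are averaged.
Default problem sizes — 15 families (~30 carriers) per replicate, 500–1000
replicates, 500 families for parameter recovery — were chosen to mirror
the scale of the motivating study while keeping each run in seconds.

## Numerical and degenerate-input choices

* Rarity is strict `<`; DS threshold is `≥`.
* Predictor "exceeds" is strict in the deleterious direction.
* Spearman's ρ uses midranks; a constant vector yields NaN (undefined)
  rather than an arbitrary value.
* Zero reference counts make enrichment +inf with an explanatory note,
  never an exception.
* Families with both parents carriers are surfaced as an `anomalous`
  transmission category, never silently assigned or dropped.
* TDT allele resolution is purely Mendelian: a double-heterozygous pair
  with a heterozygous child is counted as unresolved, never imputed, and
  Mendelian inconsistencies are flagged per parent–offspring pair.
* uATG detection considers only ATG trinucleotides that overlap the edited
  base and are absent from the unedited sequence; frame is judged by
  whether the distance between the new and the main start codon's A is a
  multiple of 3.

## Known limitations

* No annotation engine: consequence classes and predictor scores are
  consumed, not computed, and HGVS strings are opaque identifiers.
* No segregation likelihoods, haplotype phasing, linkage analysis, or
  multiple-testing correction across subtype contrasts.
* The penetrance estimator inherits the uncorrected-ascertainment caveat
  above; the example datasets reconstruct published marginal counts, so
  individual-level detail in those fixtures is synthetic by construction.
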