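# Methods

## The segregation model

The unit of inference is the (variant, family) pair under a dominant
carrier model: an individual carries a variant if they have at least one
alternate allele; homozygous carriers are not distinguished from
heterozygous ones. A variant **completely segregates** in a family when

1. every affected member with a non-missing genotype is a carrier,
2. there are at least two affected carriers, and
3. every unaffected carrier is at least Δ years younger than the reference
   age at onset.

Condition (1) excludes, rather than penalises, affected members whose
genotype was masked by QC: a missing genotype is treated as "unobserved",
not as a non-carrier. Condition (2) is a floor that prevents a single
genotyped affected carrier from counting as segregation. Condition (3)
encodes censoring: an unaffected carrier well below the family's onset age
may simply not have reached it, while an unaffected carrier at or beyond
it is evidence against co-segregation. The comparison is inclusive —
exactly Δ years younger qualifies.

Two readings of "the family's onset age" are implemented:

- `carrier_mean` (default): the mean onset of the affected **carriers of
  the variant under test**;
- `family_mean`: the mean onset over all affected members.

They differ only when some affected members are excluded by missing
genotypes; both are exposed because the two phrasings are natural and a
cohort analysis should state which it used.

**Incomplete segregation** is deliberately a cohort-scope label, pooled
across families within one cohort: ≥ 4 affected carriers, strictly more
affected than unaffected carriers, and every unaffected carrier passing
the buffer against their own family's reference onset. It never
contributes to a family's explanation label; it flags variants worth
follow-up that no single family can establish.

**Cross-family consistency**: when a variant completely segregates in one
family but is also carried in another family where it does not, strict
mode (default) demotes the variant everywhere unless all carriers in the
other families are affected; lenient mode additionally tolerates
unaffected carriers who pass the age buffer. The strict default reflects
the stronger published phrasing of the rule; the lenient mode reflects the
buffer logic used everywhere else. Demotions are logged.

Members with unknown affection are excluded from both the all-affected
test and the unaffected-carrier test. They carry no usable phenotype
information under this rule set; recode them upstream to include them.

## Family explanation labels

Per family, mutually exclusive and exhaustive:

- `RARE_EXPLAINED` — at least one damaging variant completely segregates
  (APOE status irrelevant; rare variants take precedence);
- `APOE_ONLY` — no such variant, but APOE ε4 completely segregates;
- `UNEXPLAINED` — neither.

## APOE ε4

Diplotypes are called from unphased rs429358 (T>C) and rs7412 (C>T)
dosages by allele counting: each rs429358-C allele contributes an ε4
haplotype, and rs7412-T alleles among the remaining haplotypes contribute
ε2, the rest ε3. The double heterozygote is phase-ambiguous (ε2/ε4 versus
the rare ε1/ε3) and is resolved to ε2/ε4 on population-frequency grounds
with an `ambiguous` flag; a config option excludes ambiguous individuals
instead. Genotype pairs that would imply an ε1 haplotype are mapped to the
nearest diplotype in {ε2, ε3, ε4}; ε1 is not modeled. Default GRCh38
coordinates for the two SNPs ship as overridable configuration constants.

ε4 "segregation" uses the identical three-condition rule, including the
unaffected buffer. Because ε4 is common, an alternative reading ignores
unaffected ε4 carriers entirely; that is available via
`apply_buffer=False` and changes only condition (3).

## QC and prioritization conventions

All boundaries are explicit and tested:

| filter | rule | boundary behaviour |
|---|---|---|
| genotype mask | missing iff DP < 10 **or** GQ < 20 | DP = 10, GQ = 20 kept |
| site call rate | drop iff missing fraction > 2% | exactly 2% kept |
| rarity | keep iff gnomAD AF < 1% | AF = 1% dropped; absent AF kept + flagged |
| damaging missense | CADD phred > 20 | CADD = 20 not damaging |
| LoF | stopgain, stoploss, frameshift, splice acceptor/donor | splice_region is *not* LoF |

The stated genotype filter is interpreted as masking what is filtered out
(DP < 10 or GQ < 20); the call-rate filter is per-variant across samples,
not per-sample. Missense without a CADD score cannot qualify (logged).
A `require_pass` flag honours the VCF FILTER column when upstream variant
recalibration is in play; it defaults to off because the packaged inputs
are synthetic and carry PASS throughout. Multi-allelic records are split
into one site per alternate allele, with dosages recoded per allele and
DP/GQ carried over. Coordinates are VCF 1-based; BED inputs are 0-based
half-open.

## LD estimators

- `genotype_r2`: squared Pearson correlation of dosages over
  pairwise-complete samples. Symmetric, invariant to ref/alt relabeling;
  undefined (raised) for constant vectors or < 2 complete pairs.
- `em_haplotype_r2`: two-locus EM over the 3×3 genotype table. Only the
  double-heterozygote cell is phase-ambiguous; the E-step splits it
  between cis and trans in proportion to current haplotype products.
  Frequencies stay on the simplex at every iteration; convergence
  tolerance 1e-8 on the max frequency change, cap 1000 iterations
  (non-convergence raises, with the last estimate attached).
  r² = D²/(pA·qA·pB·qB).

On phased-equivalent data (no heterozygotes) the two reduce to the same
haplotype-frequency computation and agree to numerical precision; on
unphased HWE samples they agree asymptotically but differ at O(n^-1/2) in
finite samples. LD is computed across all genotyped cohort members by
default — the cohorts are families, so this correlates related genomes; a
founders-only option trades bias for variance. The binary "in LD" flag
defaults to r² ≥ 0.2 and is reported alongside the continuous r², because
any single cutoff for a rare-common pair is arbitrary: with a rare variant
(AF < 1%) and a common index SNP, attainable r² is bounded well below 1,
so segregating variants typically show r² ≪ 0.2 even when the index SNP
co-segregates perfectly within the carrier families. Index-SNP
co-segregation (the complete rule applied to the index SNP itself) is the
more informative statistic at these frequencies and is reported per
variant.

## Reporting

Percentages are printed to one decimal, rounded half-away-from-zero, and
always recomputed from integer counts. The variant report has one row per
(variant, cohort) with at least one completely segregating family; family
counts, affected-carrier and unaffected-carrier sums are per-row additive
over families, and row order is deterministic (chromosome, position,
alternate allele, cohort). Distinct-variant counts deduplicate on
chrom:pos:ref:alt per cohort — a variant present in both cohorts counts
once in each — and distinct-gene counts deduplicate on the gene symbol.

The packaged transcriptions of the source study's variant tables and
printed integer counts (`famseg/data/`) are reporting-test inputs and a
default locus list only; the classifiers never read them. The printed
family-class counts do not exactly partition the printed family totals
(an internal inconsistency of the published tallies, e.g. 38+64+99 = 201
for a 197-family cohort and an abstract figure of 91 APOE-only families
against 93 in the results text); the fixtures carry the results-section
integers and are used strictly as numerator/denominator pairs, not forced
into a partition.

## The synthetic-data generator

`famseg.simulate` emulates the *structure* of a two-cohort late-onset fAD
study: two cohorts of multiplex families (4–8 members, 2–4 affected, at
least one unaffected), affected onset ages drawn from Normal(75.2, 8.0)
years on a 0.1-year grid (clipped to 45–105), unaffected exam ages from
Normal(72, 10), and family classes planted at fractions (0.175, 0.226,
0.599) matching the emulated study's observed proportions. Per family it
plants: a private rare damaging variant carried by all affected members
(rare-explained families; 30% LoF, otherwise missense with CADD in
20.5–45; gnomAD AF in 1e-4–5e-3), optional buffer-qualifying unaffected
carriers (p = 0.3), APOE ε4 segregation (all APOE-only families, and 30%
of rare-explained families to exercise co-segregation), decoy
non-segregating damaging variants (p = 0.2 in other families), one
cohort-level incomplete-segregation variant (five affected carriers spread
one-per-family so no family reaches the two-carrier floor, plus one
qualifying unaffected carrier), common index SNPs (HWE, AF 0.2) that
mirror the rare variant's carriers in half the rare-explained families,
and filter decoys (a common damaging-looking variant, a low-CADD missense,
a synonymous site). Unaffected ages near planted carriers deliberately
straddle the Δ = 5 buffer boundary, including exact-boundary cases.

Deliberate non-features: Mendelian transmission is not simulated (carrier
status is assigned to satisfy the planted pattern; parent ids are
cosmetic), there is no population structure, no genome-wide site count,
no sequencing-error model beyond the three QC-noise rates (P(DP < 10),
P(GQ < 20), P(missing) per genotype call), and one annotation dialect.
Passing the recovery tests therefore demonstrates that the classifiers
implement the stated rules exactly — not that the rules are robust to
annotation disagreement, pedigree errors, or relatedness-driven artefacts
in real cohorts.

Everything is driven by one integer seed; identical configurations yield
byte-identical files. Planted complete-segregation and APOE patterns are
re-checked with the package's own classifier before output is produced
(on the clean genotypes, before QC noise injection), so a generator bug
cannot silently ship an inconsistent truth table. Planted qualifying ages
are nudged below the buffer boundary so the inclusive comparison holds in
float arithmetic exactly as the ages are stored.

## Problem sizes

The default analysis drivers use 200 families per cohort and the recovery
checks 500 per cohort (~1300 truth records, ~190 sites per cohort); the
exhaustive classifier-versus-brute-force comparison enumerates every
(affection, age, genotype) configuration for families of 2–4 members
(~22,000 cases) and samples 3,000 more of sizes 5–6. These sizes give
stable statistics (onset-moment checks pass at 3 standard errors; the
EM r² check at n = 10,000 sits within 3 SE of its target) while keeping
the full suite in seconds.

## Known limitations

- No statistical test accompanies a segregation call; the output is a
  deterministic classification, as in the emulated design.
- Penetrance, phenocopies and age-dependent risk are not modeled beyond
  the onset buffer.
- The EM estimator handles two loci only; no D′, no multi-locus
  haplotypes.
- Annotation is consumed, never computed: transcript choice and
  consequence dialect must be resolved upstream (a YAML synonym map is
  provided for dialect mapping).
- Unknown-affection members are invisible to the classifier by design.
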