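# httrepeat

Analysis pipeline for the *HTT* exon-1 CAG repeat in Huntington disease
(HD) cohorts: sequence-level repeat-structure profiling, correction of
fragment-assay CAG mis-estimation on non-canonical alleles, a somatic-
expansion index from capillary fragment traces, residual age-at-onset
phenotyping, and the modifier-association statistics built on top —
together with a seeded synthetic-cohort generator so every stage runs and
is tested without access to patient data.

It is written for statistical geneticists working on repeat-expansion
disorders who need the bespoke computations of an HD onset-modifier
analysis as reusable, tested code.

## The science in brief

HD onset age falls steeply with the inherited CAG repeat length, modelled
here as ln(AO) = a + b·CAG; the analysis phenotype is the **residual**
onset, observed minus expected years.  The repeat region is
`CAG_n CAA_1 CAG_1 CCG_1 CCA_1 CCG_7 CCT_2 …` on canonical chromosomes, so
polyglutamine = n + 2; CAA-loss alleles encode n glutamines and
CAACAG-duplication alleles n + 4.  The standard PCR sizing assay reads
CAA-loss alleles 2 CAG too short and duplication alleles 1–2 too long,
which corrupts the residual phenotype for carriers and manufactures
spurious association signals at SNPs tagging those haplotypes — removed by
recomputing residuals from the true, sequence-confirmed CAG.

Somatic expansion is scored from GeneMapper-style peak tables as the
**peak proportional sum**: per-plate linear calibration of fragment size
to CAG units, 500 bp / 50 RFU peak filters, then the summed height of
peaks right of the main allele divided by the main-peak height.
Enrichment of a modifier allele among high expanders is tested by
chi-square deviation of top-quartile genotype counts from Hardy-Weinberg
expectation at the full-cohort allele frequency:
chi² = Σ(O−E)²/E on (n(1−q)², 2nq(1−q), nq²), 2 df.

## Worked example

```python
import numpy as np
from httrepeat import modifier_stats as ms, repeat_model as rm

# A CAA-loss chromosome: the assay under-reads the CAG tract by 2
s = rm.parse_structure("CAG_44 CCG_12 CCT_2")
rm.classify_structure(s)                        # StructureClass.CAA_LOSS
rm.fragment_assay_estimate(44, rm.StructureClass.CAA_LOSS)   # 42
rm.polyglutamine_length(s)                      # 44 (no CAACAG: polyQ = n)

# HWE enrichment of a modifier allele among the 1,753 highest expanders
obs = ms.GenotypeCounts(915, 684, 154)
res = ms.hwe_chisq(obs, ms.hwe_expected_counts(1753, 0.257))
print(res.expected_display, round(res.statistic, 2), res.df, res.p)
```

prints

```
(968, 669, 116) 15.8 2 0.00037012043125468245
```

i.e. against expected counts 968/669/116 the observed genotypes deviate
with chi-square 15.80 on 2 df, p < 0.0004 — an excess of minor-allele
carriers among high somatic expanders.

## The analysis

Numbered drivers under `analysis/` run the full pipeline on the synthetic
cohort and write their tables under `results/`:

1. `01_simulate_cohort.py` — 9,064 subjects, genotypes, onsets, fragment
   traces (run this first; later steps read its outputs).
2. `02_profile_reads.py` — amplicon read simulation and repeat genotyping
   across all structure classes (recovers 5/5 demonstration genotypes at
   0.5% base error).
3. `03_score_expansion.py` — peak proportional sums, top expansion
   quartile, HWE enrichment of rs701383 (the generator couples expansion
   to its dosage).
4. `04_onset_association.py` — residual phenotype, 30%/30% dichotomy
   (2,719 + 2,719), modifier association, and the mis-estimated-CAG
   artifact before/after true-CAG correction.
5. `05_tag_snps.py` — conditional analysis on a toy LD locus and the
   declarative 5AM/15AM/19AM tag-SNP rules.

A thin CLI (`httrepeat simulate|profile-reads|trace-score|phenotype|
hwe-top-quartile|tag-snps`) exposes the same steps on files.

See `docs/methods.md` for the models, defaults and their rationale.

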