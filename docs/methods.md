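# Methods

## The problem

Huntington disease (HD) is caused by an expanded CAG repeat in *HTT* exon 1,
and age at motor onset falls steeply with inherited repeat length.  The
repeat region is not a pure CAG tract: on most chromosomes the uninterrupted
CAG run is followed by a single CAACAG before the proline-rich flank, so the
encoded polyglutamine segment is two residues longer than the CAG run.
Rare chromosomes lack the CAA interruption (CAA-loss) or carry two tandem
CAACAG units (CAACAG-duplication), decoupling polyglutamine length from
uninterrupted CAG length — and fooling the standard PCR fragment-sizing
assay, which is calibrated on canonical standards.  This package implements
the computational machinery needed to work with that structure: sequence-
level repeat profiling, the assay error model and its correction, a somatic-
expansion index from fragment traces, residual-onset phenotyping, and the
modifier-association statistics built on top, together with a seeded
synthetic-cohort generator so the whole pipeline is testable end to end.

## Repeat structures and the assay model (`repeat_model`)

A repeat region is an ordered list of trinucleotide runs (`CAG_42 CAA_1
CAG_1 CCG_1 CCA_1 CCG_7 CCT_2`).  Classification looks only at the
glutamine-codon segment starting at the leading CAG run: exactly one CAACAG
is canonical, none is CAA-loss, two tandem CAACAGs is duplication, anything
else is `other`.  Polyglutamine length is the contiguous glutamine-codon
count from the leading run, so the offsets over uninterrupted CAG are
exactly 0 / +2 / +4 for CAA-loss / canonical / duplication.

The fragment-sizing assay model is deterministic per class: canonical
alleles are sized correctly, CAA-loss alleles are underestimated by 2 CAG,
duplication alleles overestimated by 2, or by 1 when the PCR primer
mis-primes on the duplicated CAACAG.  Which duplication chromosomes
mis-prime is not predictable from the structure alone, so mis-priming is an
explicit boolean input (and a Bernoulli(0.5) draw in simulation — no rate
is established, so a maximally uninformative default was chosen).
`correct_estimated_cag` is the exact inverse, checked exhaustively over
36–60 CAG for every class.  `other` structures are parsed and classified
but rejected by the assay model: no estimation rule exists for them.

## Read profiling (`read_profiler`)

The forward scanner anchors at the first `CAGCAGCAG` occurrence, fixes the
reading frame there, consumes successive triplets, and stops when the next
nine bases are the invariant `CAGCTTCCT` terminator (complete profile) or
at read end (incomplete).  Anchor and terminator matching are exact — no
mismatch tolerance and no base-quality filtering.  A pair is retained only
when both mates, each profiled in sense orientation (orientation is
auto-detected, so profiling is invariant to which mate is the sense read),
yield identical run lists; this double-profiling acts as the error filter,
at the cost of discarding most pairs at realistic error rates (~75% at
0.5%/base over a ~260 bp window), which is why per-allele coverage matters.

Genotype calling projects the histogram of retained structures onto
uninterrupted CAG length using only profiles whose leading CAG run
demonstrably ended within the read (a later run or the terminator follows
it); an unterminated CAG run is only a lower bound and would bias the
length distribution toward truncations.  The two most frequent lengths are
called (one, for unimodal histograms, gives a homozygote); equal counts are
broken deterministically toward the longer CAG with a tie flag.  Each
called length then gets the highest-count terminator-complete structure of
that length; if none exists the genotype is flagged incomplete.

The reverse (WGS) scanner anchors on `CAGCTTCCT` and walks 3'→5' in frame
until three consecutive CAG triplets appear.  Complete sequences are
aggregated, and sequences representing 14% *or less* of aggregated
complete reads are filtered out (the boundary share of exactly 0.14 is
removed).  The filter denominator is the count of complete sequences:
only complete sequences are aggregated in the preceding step, so the
share is defined on those.  One survivor is a homozygote, two a
heterozygote, zero a no-call, more than two an ambiguous flag.

## Somatic-expansion scoring (`trace_expansion`)

Per plate, the called main CAG alleles and their main-peak sizes define an
OLS calibration `cag = b0 + b1*size` (`scipy.stats.linregress`, as in the
original workflow).  Peaks are filtered to size ≤ 500 bp and height ≥ 50
RFU (both boundaries kept), sizes are transformed to CAG and rounded to
the nearest integer (halves away from zero), and peaks colliding on the
same CAG within a sample keep the larger height.  Filtering runs before
assignment; the order only affects which record wins a collision, and this
order is the simpler to reason about.  The peak proportional sum is the
summed height of peaks with assigned CAG strictly greater than the main
allele, divided by the main-peak height — left-of-main products are PCR
stutter and are excluded.  Proportions use peak height, not area; the area
column is retained in the record for an alternate mode.  Quartile ranking
sorts descending with ties broken by sample id; the top quartile has
floor(n/4) members, which reproduces 1,753 of 7,013.  A per-CAG stratified
mode is also provided (the expansion index rises with CAG, so pooled
ranking enriches long alleles in the top quartile); pooled is the default
as it defines the printed group size.

## Residual onset phenotype (`onset_phenotype`)

Expected onset is a pluggable strictly decreasing model over 36–60 CAG.
The default is log-linear, ln(AO) = a + b·CAG, with coefficients fit at
import time to a packaged **synthetic** reference cohort
(`data/synthetic_reference_cohort.tsv`, 400 subjects generated from
ln(AO) = 6.488 − 0.0638·CAG with 0.15 log-scale noise); the fitted default
gives ≈45 y at 42 CAG and ≈27 y at 50 CAG, a realistic HD onset curve.
This keeps the pipeline runnable without asserting anyone's published
coefficients; any model can be supplied as YAML.  A shifted-exponential
form AO = c + exp(a − b·CAG) is available for sensitivity work.

Residuals are observed minus expected onset in natural-scale years.
Recomputation under the true (sequence-confirmed) CAG keeps the
estimated-CAG residual alongside and is idempotent.  The analysis window
keeps subjects with 40–55 CAG (true CAG preferred when present).
Dichotomization sorts by residual and takes floor(0.30·n) subjects into
each extreme group (2,719 + 2,719 at n = 9,064), ties broken by id.

## Modifier statistics (`modifier_stats`)

HWE expected counts use an externally fixed MAF q: (n(1−q)², 2nq(1−q),
nq²).  The chi-square statistic is Σ(O−E)²/E with **2** degrees of
freedom — the MAF comes from the full cohort, not the tested subgroup, so
no estimated parameter is consumed (this is deliberately not the
conventional df = 1 of a within-sample HWE test).

Association is fixed-effect least squares of the residual phenotype on
minor-allele dosage with optional covariates (`statsmodels` OLS).  The
kinship-corrected mixed model used on real cohorts is out of scope here;
fixed effects are valid for the unrelated synthetic cohorts this package
targets.  Conditional analysis appends conditioning-SNP dosages to the
covariates, erroring on perfect collinearity.

The tag-SNP rule engine evaluates declarative rules in order and returns
the first match.  All thresholds are strict inequalities as stated in the
locus definitions; the shipped sets cover 5AM1–3 (MSH3/DHFR), 15AM1–4
(FAN1) and 19AM1–3 (LIG1).  Two interpretation choices: the 15AM3
requirement of p < 1e-5 "in conditional analyses with either rs150393409
or rs35811129" is read as holding in *both* conditional analyses (the
signal is independent of both top SNPs), and 15AM4 carries no direction
constraint (its tagging alleles are near 50% frequency, so minor-allele
direction is ambiguous).  A rule referencing a conditional p-value a SNP
does not carry is inapplicable to that SNP and is skipped with a warning —
in practice SNPs only carry their own locus's conditional results.

## The synthetic cohort generator (`synthetic`)

Defaults are the study conditions the pipeline is designed for: 9,064
subjects; disease-allele CAG on 40–55 with geometrically decaying weights
(decay 0.35/CAG, concentrating mass at 40–44 as in HD cohorts); normal
alleles 15–25; structure mix 98.55% canonical, 0.32% CAA-loss, 1.13%
duplication (matching the observed carrier counts of the two rare tag
haplotypes at cohort scale); onset = model expectation of the *true* CAG
plus additive SNP effects plus N(0, 7 y) noise (residuals are approximately
normal in real cohorts; 7 y is a realistic residual SD); estimated CAG is
the assay model applied to the true structure.  The default modifier panel
mirrors reported tag SNPs (e.g. rs701383, MAF 25.7%, −0.8 y/allele;
rs150393409, 1.4%, −5.2 y).  A rare SNP (rs764154313-like) is given to
every CAA-loss carrier, reproducing the mechanism by which repeat
mis-estimation manufactures a spurious onset-hastening association that
true-CAG correction removes.

Reads are 2×300 bp sense/antisense amplicon pairs with independent
per-base substitution errors (default 0.5%, 100 pairs/allele); the
amplicon (fixed synthetic primer context + repeat + terminator + flank)
fits inside one read for all simulated lengths, and longer regions are
emitted with a truncation flag.

Traces put the main peak at 10,000 RFU with size = 87 + 3·CAG bp (±0.3 bp
jitter), four left stutter peaks decaying by half per CAG, and a
right-of-main expansion tail whose total height fraction equals a
per-subject propensity drawn from a Beta distribution with mean
0.05 + 0.012·(CAG−40), scaled by (1 + 0.25·dosage) of the designated
coupling SNP (rs701383 by default).  The tail is split geometrically over
three peaks so that, at the fractions the scoring is designed to resolve
(≥0.05), every expansion peak clears the 50 RFU height filter and the
known fraction is recoverable to within CAG-rounding error.  All streams
derive from one seed via spawned child generators, so outputs are
byte-identical under a fixed seed.

### What the generator does not emulate

No PCR stutter on the sequencing reads (only substitution errors), no
somatic mosaicism within the read data, no LD structure beyond the toy
proxy construction used for conditional-analysis tests, no population
stratification or relatedness, no missing or mis-recorded onset ages.
Passing tests therefore demonstrate correctness of the computations and
their statistical calibration under the stated generative assumptions, not
robustness to every artifact of real capillary or sequencing data.

## Problem sizes and numerical choices

The test suite exercises the full 9,064-subject cohort for group-size
checks and 200–1,000-replicate studies for calibration properties
(profiler recovery at 100× coverage, type-I error at n = 400, effect
recovery at n = 5,000); these sizes give the properties enough power while
keeping the suite fast.  Tolerances: expansion-fraction recovery within
0.01 (CAG-rounding); injected −4.4 y effect within ±0.5 y (≈2 SE at the
simulated scale); type-I error 0.05 ± 0.02.  Degenerate inputs error
loudly: single-point plate calibrations, zero-variance dosages, empty
histograms, structures without a leading CAG run.

## Known limitations

- The assay model covers the three characterized structure classes only;
  rarer variants are classified `other` and excluded from correction.
- The MiSeq caller's exact-match anchors mean a single error in an anchor
  discards the pair; no mismatch-tolerant mode is provided.
- The expansion index is a bulk measure with a floor at the inherited
  allele; it resolves high-mosaicism individuals, not reduced expansion.
- Logistic modelling of the dichotomous phenotype is provided only through
  the standard statsmodels interface and carries no calibration claims.
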