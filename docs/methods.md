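# Methods

This note documents the models and procedures implemented in `miredit`,
the parameter choices that matter, and what the synthetic data does and
does not establish about real small-RNA-seq experiments.

## Biological model

A-to-I editing is the deamination of adenosine to inosine by ADAR enzymes
in double-stranded RNA. Inosine base-pairs like guanosine, so an edited
adenosine is read as G both by reverse transcription and by sequencers:
editing manifests as an A>G substitution relative to the mature-miRNA
reference (and as an A-T to G-C pair change in cloned, Sanger-sequenced
material). Positions 2-7 of a mature miRNA form the seed, the primary
determinant of target recognition; the package therefore flags every call
as seed/non-seed, with positions 1 and 8 explicitly outside the seed.

All coordinates reported anywhere in the package are 1-based positions in
the mature reference. Sequences are handled as DNA (`U` converted to `T`
on input); mature miRNAs are constrained to 17-24 nt.

## Synthetic study generator

The generator emulates an aging-cohort design: sexes M/F crossed with ages
3/6/15/25/30 months. Its components:

* **Reference** — random 17-24 nt sequences, pairwise Hamming distance
  >= 5 at equal length so that mismatch-tolerant mapping is unambiguous by
  construction. Placement is rejection sampling with a 2,000-attempt bound
  per sequence; an unsatisfiable request (e.g. a distance above the
  sequence length) fails with an explicit error rather than looping.
* **Abundance** — per-miRNA baseline means drawn log-uniformly (default
  range 100-10,000, i.e. ~2 decades of expression); per-sample counts are
  negative binomial with mean `depth x baseline_share x 2^effect` and size
  parameter 25 (count CV ~ 0.2 at high expression, the overdispersion
  regime typical of small-RNA-seq; a Poisson model would make the
  downstream power results look better than real data warrants). Sample
  totals are *not* renormalized after effects are applied, so the ratio of
  group means equals the planted fold change exactly.
* **Effects** — a configurable number of miRNAs receive a log2 fold effect
  (default 2.0, i.e. 4-fold) in every non-3-month group; the 3-month group
  of each sex is the baseline, mirroring the use of 3-month animals as
  controls.
* **Editing** — sites are planted only at A positions of the mature
  (sense) strand, at most one per miRNA, with an edited fraction drawn
  from a configurable range (default 0.05-0.40). Each read of an edited
  miRNA carries G at the site with that Bernoulli probability; inosine is
  always emitted as G.
* **Reads** — each raw read is the mature sequence, then per-base
  substitution error on the insert (default 1e-3, uniform over the three
  alternative bases), then the 19 nt 3' adapter, padded with A to the
  fixed 50 nt read length. FASTQ output uses a constant Phred-40 quality
  (the generator has no quality-degradation model).
* **Determinism** — one master seed; the per-sample generator is
  `SeedSequence(master_seed, spawn_key=(sample_index,))`, so any single
  sample can be regenerated independently and re-runs are byte-identical.
* **Clones** — for the validation arm, synthetic plasmids are random
  vector flanks around the insert in a random orientation, optionally with
  one planted substitution (A>G at a random A by default).

Default depth is 1e5 reads per sample; the depth, like every parameter
above, is a configuration value rather than a claim about any particular
experiment.

What the generator does **not** model: ligation bias, UMI structure,
position-dependent error profiles, quality-score degradation along the
read, 5' isomiRs, indel errors, cross-mapping from a genome background,
and PCR duplication. Passing tests therefore demonstrate correctness of
the algorithms under a clean error model, not robustness to every real
library artifact.

## Read cleaning

The 3' adapter is located by the leftmost exact occurrence of its first
8 nt; the insert is everything before it. Reads with no adapter hit are
dropped — without the adapter the insert boundary is unknown. Filters on
the insert: length in [17, 24], N fraction <= 0 by default, mean Phred
>= 20 when qualities are present. The 8 nt exact seed is deterministic and
loses only reads with an error in those 8 bases (~0.8% at error 1e-3);
no mismatch-tolerant adapter alignment is attempted. A consequence,
asserted in the tests as documented behavior: re-cleaning already-trimmed
inserts drops everything, which protects against silent double-processing.

## Mapping

Alignment is 5'-anchored and ungapped: candidates are references whose
length differs from the read by at most 2 nt (absorbing the dominant 3'
isomiR mode), compared over the shorter length; N in a read can never
match. The unique candidate with the fewest mismatches within `max_mm = 2`
wins; ties between distinct miRNAs are counted as *ambiguous* and excluded
from the count matrix (reported in a side table), keeping editing
denominators interpretable — no fractional assignment. `max_mm = 2` admits
a singly-edited read plus one sequencing error without opening the door to
cross-mapping (the reference generator guarantees distance >= 5 between
equal-length miRNAs). 5' isomiR shifts and indels are out of scope;
isomiRs of one miRNA are merged into a single per-miRNA count.

## Editing detection

Per miRNA, every assigned read contributes its observed base at each
reference position it covers (reference base except where the stored
mismatch record says otherwise). A site is called when, at a position, an
alternative base has

* fraction strictly greater than `3 x error_rate`, and
* at least 5 supporting reads.

Both knobs are configuration values. All substitution types are reported;
`is_a_to_g` flags the ADAR-consistent subset rather than discarding the
rest, so C>T artifacts remain visible. With the defaults and error 1e-3,
a spurious call needs >= 5 reads of the *same* wrong base at one position
*and* a fraction above 0.003 — at depth 1e4 the per-position probability
is below 1e-8, and the measured false-call rate on edit-free simulations
is 0 (`scripts/acceptance.py`).

Group summaries pool the reads of a group's samples, then keep miRNAs with
at least one called site whose mean normalized count across **all**
samples of the dataset is **strictly greater than 3000**. The phrase could
also be read per-group or on raw counts; global-mean-of-normalized-counts
was adopted as the single interpretation and is exposed as
`edit.min_avg_reads`. An *edited read* is one carrying the alternative
base of a called site — stray single-read mismatches at uncalled sites do
not count, otherwise sequencing error would dominate the tallies. Three
quantities are reported per retained miRNA: the edited-read count, the
percent of that miRNA's reads that are edited, and the share of all edited
reads in the group (the doughnut-chart slice; shares sum to 100). The
top list holds the 6 largest edited-read counts, ties broken
lexicographically by miRNA id.

## Normalization and differential expression

Sample factors are median-of-ratios: for sample *j*, the median over
miRNAs *m* of `count(m, j) / geomean_over_samples(count(m, .))`,
restricted to miRNAs with a nonzero count in every sample (a zero makes
the geometric mean degenerate); rows with zeros are still normalized.
Normalized counts are raw counts divided by the factor. An exact algebraic
consequence worth knowing: multiplying one sample's counts by *k*
multiplies its factor *relative to the others* by *k*, while the absolute
factor scales by `k^((n-1)/n)` and the whole normalized matrix by the
common scalar `k^(1/n)` that the geometric means absorb.

Differential expression is a per-miRNA two-sample t-test, Welch by default
(pooled variance is available but unequal group variances are the norm),
on `log2(normalized + 1)` (count-scale t-tests are badly behaved; a
raw-scale option exists). Results carry `log2FC` computed from
normalized-scale group means with the pseudocount, a two-tailed p, and the
three tiers red p <= 0.01, orange p <= 0.05, blue p <= 0.1. Raw p-values
drive the tiers — no multiple-testing correction — but a
Benjamini-Hochberg column is emitted alongside for users who want it.
Degenerate rows (zero variance in both groups) report t = 0, p = 1 when
the means agree and an infinite t with p = 0 when they do not. The
pipeline's standard contrasts are each older age versus 3 months within
sex, and female versus male at each age.

## qPCR

Per sample, `dCt = Ct_target - Ct_reference` (18S rRNA is the study's
housekeeping gene); `ddCt = dCt - mean dCt` of the same-sex 3-month
control group; fold change `E_target^-ddCt` with E defaulting to 2, so the
efficiency-parameterized form and the classic `2^-ddCt` coincide unless an
efficiency in [1.6, 2.2] is supplied (a dual-efficiency ratio using both
target and reference efficiencies is also emitted). Group folds are
computed as `E^-(mean ddCt)`, which makes the control group's fold exactly
1. Group comparisons run on the dCt scale — one-way ANOVA with Tukey HSD —
because averaging exponentially transformed data biases the result. If all
retained observations are one constant, the F ratio is 0/0 and the
convention is p = 1. Array-style screens flag folds > 3.0 as increase and
< 0.3 as decrease, both boundaries strict, and array QC passes at
reverse-transcription control <= 5 with genomic-contamination control
>= 35 (thresholds configurable; the RTC direction is implemented exactly
as specified even though it is inverted relative to common vendor usage).

## Sanger clones

The insert is located by an ungapped sliding-window identity scan of the
reference and its reverse complement across the whole clone; the best
window wins (forward preferred on an exact tie) and must reach identity
>= 0.8, otherwise the clone is flagged "insert not found" and excluded.
Ungapped is deliberate: an indel inside a ~22 nt insert would make
per-position editing calls meaningless, so indel-bearing clones are meant
to fail the threshold rather than be gap-aligned. Every mismatch in the
located window is reported in reference coordinates with reference-strand
bases — an A>G edit cloned antisense appears as C on the clone strand and
is complemented back before reporting, so the call is identical in either
orientation (property-tested over random positions and orientations).

A single colony cannot distinguish editing from PCR or cloning error; the
summary therefore reports per-position recurrence across colonies and
offers a concordance filter (`min_recurrence`, default 1 = off) that keeps
only variants seen in that many colonies of the same animal. Animals with
fewer than three colonies are flagged, not rejected. Inputs are base-called
FASTA plus a metadata TSV; chromatogram parsing is out of scope.

## Numerical and engineering choices

* Ties in the top-6 ranking and in collapsed read tables break
  lexicographically, making every output deterministic.
* TSVs are written with a fixed float format (`%.10g`), so re-running a
  configuration reproduces byte-identical files; the run manifest YAML
  re-validates and reproduces the run.
* Configuration is a typed tree; unknown keys and out-of-range values fail
  before any computation.
* Unit and validation tests run on deliberately small problem sizes —
  depths of 1e4-1e5 reads, 3-50 miRNAs, 10-20 seeds per Monte-Carlo
  check — chosen so the full suite completes in well under a minute while
  keeping every binomial/NB tolerance at 2-3 standard errors.

## Known limitations

* Editing detection is descriptive; no statistical test compares editing
  fractions between groups.
* The abundance cut-off interpretation (global mean of normalized counts,
  strict > 3000) is one reading of an ambiguous rule; alternatives are a
  configuration change away but only this one is defaulted.
* The mapper does not handle 5' isomiRs, indels or genomic cross-mapping;
  it presumes a curated mature-miRNA reference.
* The error model used by the caller is a single uniform per-base rate;
  real position- and context-dependent error spectra will shift the
  effective false-call threshold.
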