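# Methods

## The measurement model

A dedicated macroarray experiment consists of nylon membranes, one per
(sample, replicate), each carrying a spot for every probe: 73 peroxidase
amplicons, a constitutively expressed histone H4 spot used as the
normalization control, and a non-expressed pseudogene spot defining the
background floor. The quantity of interest is the abundance of each
transcript relative to the housekeeping control.

The package models a spot intensity as

    I(g, s, r) = scale(s, r) · baseline(g) · fold(g, s) · ε

where `scale(s, r)` is a global per-membrane factor (hybridization
efficiency, exposure), `baseline(g)` the gene's intrinsic signal,
`fold(g, s)` the biological effect relative to a reference sample, and `ε`
multiplicative spot noise. Normalization divides each spot by the control
spot of the same membrane, which removes `scale` exactly, then averages
the replicate ratios ("ratio first, then mean": the membrane is the
blocking unit, so ratios are formed within a membrane before aggregation;
the alternative mean-of-intensities-then-ratio would not cancel membrane
scale exactly).

**Detection floor.** A gene whose mean ratio does not exceed the
negative-control mean ratio of its sample cannot be distinguished from
background. Its summary value is floored *at* that ratio and flagged
undetected; no background subtraction is performed, because subtraction
can produce non-positive ratios that break every downstream log and fold
computation. Replicate-level ratios are left untouched so the t-test sees
the raw dispersion. A gene undetected in the reference sample of a
comparison has no meaningful fold and is reported `not_evaluable`,
excluded from classification but still counted, so per-comparison tallies
always sum to the family size.

## Differential classification

A comparison's call is

- `up`    iff fold ≥ 1.3 and p < 0.05,
- `down`  iff fold ≤ 0.7 and p < 0.05,
- `stable` otherwise,

with the thresholds read as inclusive and applied to *linear* ratios; the
base-2 log is a display convention only. The test is the classical
two-sided pooled-variance Student t-test on the per-membrane normalized
ratios (n = 3 per group by default). Two degenerate branches are defined
outside scipy: two constant equal groups carry no evidence and return
p = 1; two constant unequal groups (the zero-noise limit) are maximally
significant and return the smallest positive normal float, keeping the
return value inside (0, 1].

No multiple-testing correction is applied — the procedure is a
candidate-generating screen, and the family is small; reports instead
carry the expected false-positive count `n_tests × α`
(`expected_false_positives`).

**A correlation caveat worth knowing.** Because every gene on a membrane
is divided by the *same* control spot, the control's noise propagates
coherently into all ratios of that membrane. Gene-level tests within one
experiment are therefore positively correlated: the observed rejection
rate of a single experiment is an unstable estimate of the marginal
type-I error (we have measured single-experiment null rates between 0.5%
and 12.5% at a marginal rate of 5%). The calibration checks in this
package therefore average over hundreds of independent simulated
experiments. For real data the practical implication is that "k genes
significant" in one membrane set is weaker evidence than k independent
tests would suggest.

**Stage categories.** The "highest block" label generalizes eyeballed
stage-preference tables: find the argmax stage (ties to the earlier
stage), extend contiguously over stages whose value is within
`down_threshold × max` of the peak, and label `Highest in X–Y`; a profile
entirely inside that band is `Stable first–last`. The band reuses the
down threshold so "indistinguishable from the peak" and "not
down-regulated relative to the peak" coincide. This rule is a documented
reconstruction — published stage tables of this kind state no formal
rule, and reproducing any specific published table is not claimed.

**Organ enrichment.** A gene is enriched in group A over group B when the
mean of its per-sample values over A is at least 4× the mean over B *and*
the pooled t-test over all replicate ratios of A versus B is significant.
The mean (not max) summarizes a group; significance is required because a
4-fold ratio of two noisy means is otherwise unfalsifiable.

## The mutant screen

Candidates must (i) be called in the same direction (all `up` or all
`down`) in every mutant line versus wild type — direction concordance is
required explicitly, since a gene flipping sign between lines of the same
transcription-factor family is more plausibly noise — and (ii) carry the
flower/silique enrichment label from the organ filter. The report lists
per-line folds and p-values, both filter outcomes and the final flag;
`candidate ⇔ concordance ∧ enrichment` is an invariant of the table.
Comparisons are made within the flower-bud stage, where the relevant
transcription factors act.

## Synthetic data: what it emulates, what it does not

Defaults are the study conditions: 73 genes named AtPrx01..AtPrx73,
control `HistoneH4`, negative control `pseudogene_I`, five stages
F1/F2/F3/S1/S2, `n_replicates = 3`.

- **Noise law** — multiplicative log-normal with mean 1 and configurable
  CV (default `noise_cv = 0.1`, a choice: replicate dispersion of membrane
  arrays is rarely published beyond ± values). Spot intensities are
  positive and right-skewed, which the log-normal captures; `cv = 0` gives
  the exact deterministic limit used by the recovery invariants.
- **Membrane scale** — drawn uniformly from `[0.5, 2]` per membrane, so
  normalization demonstrably matters; real inter-membrane variability is
  unreported, the range merely spans a plausible factor-of-4.
- **Baselines** — log-uniform over three orders of magnitude
  (`[0.01, 10]` × control signal), mirroring the huge dynamic range of
  family-wide membrane data (published extremes span ~2.4 down to ~0.006
  relative to the control). The lower edge coincides with the default
  background floor (1% of the control signal) so that every gene is
  detectable at baseline; genes can still fall below the floor after a
  planted down-regulation, exactly as real weakly expressed genes do.
- **Background** — the negative control emits 1% of the control signal
  plus noise; membrane background is otherwise not modeled (no
  image-level simulation, intensities are already quantified).
- **Seeding** — one master seed; independent substreams per membrane and
  per promoter via `numpy` seed sequences, so identical inputs reproduce
  identical outputs bit for bit and subsets are stable under extension.

Planted folds are recorded as ground truth together with the class they
imply under the classification thresholds. What the generator does *not*
emulate: spatial artifacts, probe cross-hybridization (real class III
family members share up to 98% nucleotide identity and the real array
relies on carefully chosen low-homology amplicons), saturation, and
correlated biological replicates. Passing recovery tests therefore shows
the *procedure* is correct and well calibrated under the stated noise
model, not that any particular biological dataset would be error-free.

Promoter simulation draws uniform-random background and embeds concrete
realizations of degenerate patterns at known positions (reverse-
complemented for minus-strand plantings). In collision-free mode the
background of every promoter is redrawn until no planted motif matches
outside the planted windows on either strand, making the ground truth
equal to the scanner's full output. One unavoidable subtlety: a
self-reverse-complementary pattern such as the CArG box `CC[W]6GG`
matches its own planted window on both strands (the complement of W is
W), so the mirror twin is part of the truth set.

## Motif scanning conventions

- Patterns are IUPAC strings with `[X]k` repeat quantifiers (`[W]_6_`
  with decorative underscores is also accepted); compilation maps each
  code to its base set and rejects malformed tokens with their position.
- Coordinates are 1-based forward-strand starts within the window;
  minus-strand hits are reported at the forward start of the site. Under
  reverse complementation of the input, hits map to
  `start' = L − start − len + 2` with strands flipped — a law tested
  against a brute-force oracle.
- `N` in a *sequence* matches no pattern letter, including pattern `N`
  (conservative: an ambiguous base call should not create hits). `N` in a
  *pattern* matches the four concrete bases.
- All overlapping hits are reported; presence frequency counts promoters
  with ≥ 1 hit and rounds to the nearest integer percent, ties away from
  zero (2 of 73 → 2.74 → 3).
- Published positions of cis-elements depend on the genome annotation and
  on whether the window is counted from its 5′ end or backwards from the
  start codon; this package documents its own convention and does not
  claim to reproduce any published position table.

## Assays

The pigment formulas are fixed linear combinations
(`OD663×7.15 + OD647×18.71`; `OD530 − 0.25×OD657`) returning
instrument-scale micrograms; per-gram reporting is an explicit division
by recorded fresh mass, never implicit. Anthocyanin can legitimately go
negative for below-blank samples and is flagged rather than clamped.
Lignin uses an ordinary-least-squares line fitted to ≥ 2 alkali-lignin
standards, with out-of-range absorbances flaggable via the recorded
standard span.

## Numerical choices and problem sizes

- All thresholds compare linear ratios; the control gene's normalized
  value is set to exactly 1.0 (not recomputed by division) so the
  invariant holds bit-exactly.
- Float invariants that are exact in real arithmetic (membrane-rescale
  invariance, zero-noise fold recovery) hold to ~1e-15 relative in
  floating point and are asserted at 1e-12; discrete outputs (calls, Venn
  cells, candidate sets) are asserted exactly.
- Output tables are tab-separated, floats at six significant digits,
  lexicographic gene order; reruns are byte-identical.
- Test-suite problem sizes: scanner oracle equivalence over 200 random
  sequences (20–1000 bp) × 60 patterns; fold recovery over 100 simulated
  experiments (96% sensitivity, <1% false positives measured at the
  default conditions); t-test calibration over 10,000 null genes in 500
  independent experiments; these sizes keep the whole suite under a
  minute while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

- The t-test with n = 3 on mildly log-normal ratios is only approximately
  calibrated; a log-scale test would be slightly better behaved but the
  linear-ratio convention is retained as the field-standard procedure for
  this design.
- `not_evaluable` genes are excluded from classification rather than
  imputed; a detection-aware model (e.g. Tobit-style censoring) is out of
  scope.
- The collision-free promoter mode can fail (with a clear error) for very
  permissive patterns in long windows, where a match-free background may
  not exist at practical redraw counts.
- No position-weight-matrix scoring, no enrichment p-values for motif
  frequencies, no genome retrieval: user-supplied FASTA windows are the
  promoter interface.
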