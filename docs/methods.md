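# Methods

## The model

The package profiles the nucleotide context of eukaryotic translation
initiation sites (the Kozak context). For every annotated mRNA the 15-base
window spanning positions −9..−1 (5′UTR), +1..+3 (the ATG; +1 is its A, there
is no position 0) and +4..+6 (the first CDS codon after the start) is
extracted. Over a set of windows the per-position base composition is the
position frequency matrix (PFM); percents are kept exact and rounded to
integers only on display/export.

**Positional selection.** Each position's composition is tested against an
even 25:25:25:25 background — the composition reported genome-wide for the
broad neighbourhood of vertebrate transcription start sites — with a Pearson
chi-square at 3 degrees of freedom (statistic Σ(obs − n/4)²/(n/4), upper-tail
p, no continuity correction). Two significance thresholds coexist by design:
α = 0.03 for flagging positions under selection, α = 0.05 for consensus
letter calling. No multiple-testing correction is applied; with six unbiased
positions in the default window this implies a per-profile family-wise false
flag probability of 1 − 0.97⁶ ≈ 0.17, which users should keep in mind when
reading the significant-position set of a single profile.

**Consensus.** A non-ATG position contributes a letter when its modal base is
significantly above 25%. The default test is a one-sided *exact* binomial on
the modal count (`binomial` mode); `chi_square` mode instead reuses the
positional chi-square and requires the modal frequency to exceed 25%. The
letter is lowercased when the runner-up base is within 5 percent points of
the modal base — a "near tie" annotation; the margin is configurable and the
lowercase convention is an interpretation layered on top of the statistics,
not itself a test. The rendered consensus is the maximal contiguous run of
lettered positions containing the ATG, so an isolated significant position
far upstream is lettered but not rendered.

**Comparative score.** Over the variable positions (default −4..−1, +4, +5 —
the significant zebrafish context minus the invariant ATG) a sequence's score
is the sum of the population percent frequencies of its bases, position by
position. `exact_percent` sums exact percents; `integer_percent` rounds each
percent half-up first, reproducing arithmetic done on a printed integer
frequency table (e.g. the zebrafish modal context AAAC·ATG·GC sums to
35+62+39+36+46+42 = 260). The two scales differ by at most 0.5·k. The
maximum-score sequence is always the concatenation of per-position modal
bases.

**Breakdown and trend.** Distinct observed variable sequences are ranked by
count (ties: score, then alphabet). The breakdown reports the observed count
out of 4^k possible, the number of rare sequences (relative frequency ≤ 0.1%,
inclusive), the minimum number of top sequences covering 50% of windows, and
the coverage of the top decile — the last two being deliberately separate
operationalisations of "a small fraction of sequences covers half the
transcriptome". The score–frequency trend groups distinct sequences by raw
occurrence count, takes the median score per group (midpoint for even
groups), and fits frequency = a·exp(b·score) by least squares of
log(frequency) on median score; at least two groups are required.

## Coordinates and filtering

External formats keep their native conventions (GFF3 1-based inclusive, BED
0-based half-open, TSV 1-based, GenBank feature locations); everything is
normalised internally to a 0-based sense-strand offset of the start codon.
Minus-strand annotations are reverse-complemented on load. Windows are
rejected — with a recorded reason, in the fixed precedence short 5′UTR →
short CDS tail → non-ATG codon → ambiguous base — rather than padded or
rescued, so every matrix column shares one denominator and acceptance
accounting always balances. Records whose annotated codon is not ATG are not
rescanned for a nearby ATG.

## The synthetic generator

`generate_transcriptome` emulates curated mRNA records: a background-sampled
5′UTR whose final (up to) 9 bases are overwritten by PWM-sampled context, the
ATG, a PWM-sampled +4..+6 codon, then background CDS codons and 3′UTR.
Defaults: 5′UTR length uniform on [9, 120], CDS 30–300 codons, 3′UTR 20–200,
uniform background — lengths only gate window acceptance, so no richer length
model is warranted. The `zebrafish` PWM preset places the published zebrafish
modal percents (35, 62, 39, 36, 46, 42 on A, A, A, C, G, C at −4..−1, +4, +5)
with the remainder spread evenly; all other positions, including +6 (for
which no modal percent is published), are uniform. Each transcript draws from
a deterministic per-transcript substream of the single global seed, so
enlarging n never reshuffles earlier records and reruns are byte-identical.

What the generator does *not* emulate: real codon usage, in-frame stop
avoidance, UTR composition bias, isoform redundancy, or the dependence
structure between positions of real promoters. Passing recovery tests
therefore demonstrates the statistical machinery is correct under the
generative model, not that any particular biological dataset will reproduce
published counts.

## Numerical choices

- Chi-square p-values via `scipy.stats.chi2.sf` (regularised upper incomplete
  gamma); tests cross-check df = 3 against the closed form
  erfc(√(x/2)) + √(2x/π)·e^(−x/2).
- Consensus binomial tails are exact at every n (`scipy.stats.binom.sf`);
  no normal approximation is used.
- Integer-percent rounding is half-up (⌊x + 0.5⌋), matching how printed
  integer tables are produced, not banker's rounding.
- Modal-base ties break alphabetically (A < C < G < T); ranking ties break
  count ↓, score ↓, sequence ↑ — all outputs are deterministic.
- Matrices built from expected counts (`from_probabilities`) may carry
  fractional counts; every statistic is well defined on them.

## Problem sizes used in validation

The automated checks use: 2,000 replicates of n = 1000 for type-I
calibration; 20,000 PWM-sampled windows for matrix recovery (binomial
4σ ≈ 0.012 ≤ the 0.02 acceptance envelope); 100 replicates of n = 12,926
windows for significant-set and consensus recovery; and 1,000-transcript
round trips for pipeline closure and determinism. With no multiple-testing
correction the expected exact significant-set recovery rate at α = 0.03 is
0.97⁶ ≈ 0.83 — the observed ~0.83 is the calibrated behaviour of the method,
not an implementation defect; the consensus letters themselves are recovered
essentially always at this sample size.

## Known limitations

- The consensus lowercase rule is a configurable interpretation of mixed-case
  consensus strings seen in the literature; no standard definition exists.
- The exponential trend is fit on group medians, so it ignores within-group
  score spread; r² is reported in log space only.
- The primer designer assembles constructs from explicit parts; it does not
  re-derive which contexts deserve testing.
- GFF3 joining uses the transcript id as seqid (transcript-space
  annotations); genome-space GFF3 with spliced CDS is out of scope.
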