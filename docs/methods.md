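# Methods

## Model and assumptions

The package operationalizes "conserved" in the strictest possible sense:
an alignment column counts as conserved only when one nucleotide (never a
gap or N) occupies every row. A conserved pattern is a maximal run of such
columns at least `min_pattern_len` nucleotides long. The strictness has
two consequences worth keeping in mind:

* patterns are gap-free by construction, so per-species coordinates are
  well defined and the pattern sequence can be read from any row;
* the method is sensitive to the species panel. It is designed for a small
  set of closely related genomes (defaults assume five mammals); adding a
  distant species collapses most runs.

Alignment itself is deliberately external. The `align` subcommand shells
out to a user-configured command (default `mafft --auto {input}`, an
assumption — any aligner emitting FASTA works), or pre-aligned /
equal-length inputs are consumed directly. Realignment is not part of this
package's contribution and tests use pre-aligned fixtures.

The consensus-profile stage (majority-rule consensus at a strict 0.7
fraction threshold) is part of the pipeline's contract and is implemented
and tested faithfully, but the extraction stage reads the position score
matrix directly, so the final pattern set does not depend on the profile
threshold; a test documents this invariance.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `consensus_threshold` | 0.7 | fraction | strict (>) majority threshold for the profile character |
| `min_pattern_len` | 15 | nt | minimum conserved-run length; suppresses chance runs and is long enough to hold a binding site |
| `logodds_threshold` | 10 | bits | minimum summed PWM log-odds of a TFBS hit |
| `min_motif_width` | 10 | nt | motifs narrower than this never produce hits ("sparse" matches excluded) |
| `pseudocount` | 0.01 | fraction | mixed with the background proportionally before taking log-odds |
| `cv_threshold` | 75 | 0–100 | consensus-value call threshold for splice sites |
| `maxent_threshold` | 3 | bits (log2) | maximum-entropy call threshold |
| `strands` | both | — | TFBS are double-stranded elements; a flag restricts to one strand |
| `ss_rule` | any | — | call a splice site on either scorer (`any`) or require both (`all`) |

The thresholds are the method's published operating point; the scoring
base (log2), uniform background and pseudocount are the conventional
choices for PWM log-odds and are exposed in the configuration.

"≥ 10 consecutive nucleotides" for TFBS is interpreted as a minimum motif
width: log-odds scanning yields only full-width matches, so the motif
width is the only run of consecutive matched nucleotides a hit has.

## Control sampling

Controls mirror the conserved patterns: maximal runs of
less-than-100%-conserved columns at least `min_pattern_len` long are
enumerated, runs are sampled without replacement with probability
proportional to their length (avoiding a bias toward short runs), and each
sampled run contributes one uniformly placed sub-window of uniformly drawn
length. Controls are count-matched, not individually length-matched, to
the conserved set; both length distributions are available from the
written tables. The control sequence reads the per-column majority
nucleotide (ties alphabetical) so that a concrete, scannable sequence
exists even where species disagree; windows must be gap-free in the
reference (first) species. The sampling seed is a required configuration
key and the whole procedure is reproducible.

## Classification, summaries, rounding

A pattern with at least one TFBS hit and at least one splice hit is
TFBS-SS; with only one kind of hit, TFBS or SS; with neither, not
identified. The per-ordinal summary counts patterns (not sites): a pattern
counts toward the TFBS column when its class is TFBS or TFBS-SS, and
toward the SS column when SS or TFBS-SS, which keeps the percentage rows
consistent with the pattern-count denominators. Percentages are computed
with exact integer half-up rounding. Site-level counts appear in the
family tallies instead, where one (motif, offset, strand) triple is one
TFBS; a motif mapped to several TFs multiplies TF-level reports (e.g. the
nuclear-receptor clusters) but never site-level counts. Nuclear-receptor
membership is taken from the library's family column, not a hard-coded
gene list, so reports follow whatever library version was scanned.

## Splice-site scoring

The consensus value is min-max normalized per matrix, so it is invariant
to any global rescaling of the frequencies and always maps the
best-possible window to 100 and the worst to 0. The packaged donor
(width 9: 3 exonic + 6 intronic positions) and acceptor (width 14:
pyrimidine tract + CAG core) matrices are *synthetic* defaults built from
the classical mammalian splice-consensus base frequencies; they are
ordinary TSV files and should be replaced when site-specific matrices are
available. The maximum-entropy scorer is defined entirely by its
model-file contract (direct or factored signed score tables, summed in
log2 units); the package ships no real model tables, runs CV-only without
them, and treats any window containing an unknown k-mer as unscorable.
Whether a site must be called by both scorers or either is genuinely
ambiguous in the method description; the default is the union rule with
an `ss_rule` switch rather than a silent choice.

## Statistics

Mann-Whitney U (two-sided) compares per-gene conservation fractions
between intron groups — the per-gene fraction of alignment columns covered
by conserved patterns, including zero for genes without patterns. The unit
of observation is the gene, which avoids pseudo-replication from counting
patterns. SciPy's exact method is used where available, the tie-corrected
normal approximation otherwise; two groups whose pooled values are all
identical are reported as p = 1 rather than a 0/0 variance. The chi-square
test compares each intron's four-class counts against the pooled
all-intron class proportions (the natural null of "no intron is
different"; a configuration of the statistics API accepts any expected
proportions, e.g. uniform). When a pooled expected count falls below 1,
the SS class is collapsed into TFBS-SS with a warning. The Wilcoxon
signed-rank test (two-sided, zero differences dropped, exact for up to 25
informative pairs) compares per-region element counts between conserved
patterns and their controls. No multiple-testing correction is applied by
default, matching the analysis this package reproduces; Bonferroni is a
one-liner on the returned p-values.

## Synthetic data: what it does and does not emulate

The simulator draws a uniform ancestral sequence per region and mutates
each species independently per column (star phylogeny), leaving planted
blocks untouched — so planted blocks are exactly the fully conserved runs
the extractor must find, and everything downstream has planted truth.
Defaults are the intended study conditions: 5 species, 25 genes × 3
introns × 600 nt, substitution probability 0.3 per column per species,
indels off, 40 planted 20-nt blocks (20 with a 12-nt motif-consensus
instance, 10 with a canonical donor site, 10 plain). At substitution 0.3
the chance of a spurious 15-nt conserved run is ~0.17^15 per position,
i.e. negligible, while each block flank has a ~17% chance of extending a
recovered run by a column or two — recovery is therefore asserted as
containment of the planted interval, not exact equality of endpoints.
Random planted blocks can also contain chance splice-consensus windows,
so class agreement with planted truth is exact only for particular seeds
(it holds at the suite's fixture seed and stays near 100% elsewhere).

Deliberately not emulated: realistic substitution models (HKY, rate
variation), phylogenetic correlation between species, compositional bias,
and repeat structure. Passing tests therefore demonstrate algorithmic
correctness on the stated generative model, not performance on real
genomes, where conservation is auto-correlated and alignment error exists.

Indels default off because conserved patterns are gap-free by definition;
an indel-generating mode exists to exercise gap handling in the consensus
and tally code, and its outputs require external alignment first.

## Numerical choices and degenerate inputs

* Consensus threshold comparison is a strict float `>`; the equality case
  (e.g. 7 of 10 rows at threshold 0.7) compares identical floats and is
  excluded, as intended.
* Consensus ties and gap/N-majority columns emit `X`.
* PWM rows off unity by ≤ 1e-3 are renormalized; anything worse is
  rejected. Motif files missing or empty are skipped with a warning.
* Percentages use exact integer arithmetic (`(200·num + den) // (2·den)`),
  immune to float representation of halves.
* A hit's stored score is recomputable from the matrix and the hit
  subsequence to 1e-9 (asserted by tests).
* A fully uninformative splice matrix (all positions uniform) returns
  CV 0 instead of dividing by zero.
* Alignments with fewer than two rows, ragged rows, empty sequences, and
  non-nucleotide characters are rejected at the I/O boundary.

## Problem sizes in the test suite

The default synthetic study (75 regions × 600 nt × 5 species, 40 planted
blocks) runs end to end in a few seconds; oracle-equivalence tests use 200
random alignments of up to 2,000 columns and 200 random sequence/motif
scan pairs, and the rank-statistic checks enumerate permutations exactly
for group sizes up to 8. These sizes give exhaustive or near-exhaustive
coverage of the combinatorial space the algorithms operate on while
keeping the full suite in the tens of seconds.

## Known limitations

* 100% conservation is binary: a single sequencing error or misalignment
  in one species destroys a pattern. There is no sub-threshold scoring
  (phastCons-like) and no indel-tolerant pattern merging.
* The global 10-bit log-odds threshold is not calibrated per motif; motif
  information content varies, so per-motif false-positive rates differ.
* Splice-site calls use the packaged consensus matrices unless replaced;
  they approximate, but are not, any particular web service's matrices.
* Control windows are drawn from the same alignments and are count-matched
  only; their base composition may differ from the conserved set's.
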