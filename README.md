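# consreg

Detection of fully conserved intron/exon sequence patterns across
orthologous mammalian genes, and annotation of the cis-regulatory elements
(transcription-factor binding sites and splice signals) they contain.

## Who this is for

Regulatory genomicists asking whether the conserved non-coding stretches of
a gene family — e.g. the introns of nuclear-receptor genes — are enriched
for candidate cis-regulatory elements. The package takes per-gene-region
FASTA files of orthologous sequences from a handful of closely related
species, finds the runs that are perfectly conserved across all of them,
and asks what those runs contain.

## The method

For each gene region (one intron or exon, one sequence per species):

1. **Alignment profile and position score matrix.** From a multiple
   alignment (produced externally, e.g. MAFFT, or trivially from
   equal-length sequences) a per-column tally of A/C/G/T/gap/N occurrences
   is built. A majority-rule ("dumb") consensus emits the most common
   nucleotide of a column when its fraction strictly exceeds 0.7, and `X`
   otherwise; gaps and N are never emitted.
2. **Conserved-pattern extraction.** A column is *conserved* when a single
   nucleotide occupies every row (no gap, no N, no substitution). Maximal
   runs of conserved columns of length ≥ 15 nt are the conserved patterns;
   matched non-conserved control windows of the same minimum length are
   sampled from the complementary columns with a fixed seed.
3. **TFBS scan.** Every pattern is scanned on both strands against a
   CIS-BP-style motif library with PWM log-odds scoring,
   `score(i,b) = log2((p_ib + c·bg_b)/((1+c)·bg_b))` in bits (uniform
   background, pseudocount c = 0.01). A window is a hit at total score
   ≥ 10 bits for motifs spanning ≥ 10 nt.
4. **Splice-site scan.** Donor/acceptor windows are scored with a
   consensus value, `CV = 100·(t − t_min)/(t_max − t_min)` where `t` sums
   the per-position frequencies of the window's bases; a site is called at
   CV ≥ 75. An optional maximum-entropy scorer (score tables supplied as
   files, log2 units, called at ≥ 3 bits) can corroborate or replace it.
5. **Classification and statistics.** Each pattern falls in one of four
   classes — TFBS, TFBS-SS, SS, not identified — and is summarized per
   intron ordinal (counts and half-up-rounded integer percentages),
   tallied per DNA-binding-domain family, and reported per gene as
   nuclear-receptor binding clusters. Group comparisons use the
   Mann-Whitney U test (conservation between introns), a chi-square
   goodness of fit (class distribution per intron vs pooled), and the
   Wilcoxon signed-rank test (paired conserved-vs-control element counts).

A synthetic-data module generates complete five-species inputs with
planted conserved blocks, motif instances and splice sites, so the whole
pipeline is testable offline with known truth.

## Worked example

Simulate a small study and run the full pipeline:

```sh
consreg simulate --out demo --seed 11 --n-genes 6 --introns-per-gene 2 --length 400
consreg all --inputs demo/regions \
            --library-info demo/library/TF_Information.txt \
            --pwm-dir demo/library/pwms \
            --out demo_run --seed 11
```

which prints

```
wrote 12 regions and a 10-motif library under demo
12 conserved patterns, 12 controls, 6 TFBS hits, 3 splice hits
outputs in demo_run
```

The 12 gene regions carry 12 planted conserved blocks (6 with a motif
instance, 3 with a donor site, 3 plain); extraction recovers one conserved
pattern per block, and the scans find exactly the planted elements. `demo_run/` then holds `patterns.tsv` (one row per
pattern with its class), `controls.tsv`, both hit tables, `summary.tsv`
(per-ordinal counts and percentages with a totals row),
`normalized_counts.tsv` (patterns per gene and per kb),
`family_tally.tsv`, `nr_clusters.tsv`, `stats.tsv` and a `manifest.json`
recording the effective configuration and seed; re-running with the same
inputs and seed reproduces the tables byte for byte.

Each stage is also available separately (`extract`, `controls`,
`scan-tfbs`, `scan-ss`, `classify`, `summarize`, `stats`, `align`) and as
library functions (`consreg.extract_conserved_patterns`,
`consreg.scan_pattern`, ...).

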