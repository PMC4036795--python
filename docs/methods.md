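# Methods

## Scope and model

`renscan` reannotates the NB-LRR (NLR) complement of a plant genome from
enrichment-sequencing read alignments.  It consumes a reference FASTA, SAM
alignments of enriched gDNA (and optionally cDNA) reads, a prior GFF3
annotation and an amino-acid motif set; it emits candidate loci (BED),
classified gene models (GFF3), correction events, gap records with a
patched genome and liftover table, expression records and distribution
reports (TSV).  All internal coordinates are 0-based half-open; GFF3
(1-based inclusive) and BED dialects are converted only at file boundaries,
and every writer is deterministic.

## Candidate-locus calling

Depth is the number of alignments whose CIGAR consumes a reference base.
M/=/X and D all count: a read spanning a deletion is still capture evidence
for the deleted bases.  Mates are counted independently and duplicates are
not collapsed.  The locus rule — depth **strictly greater than**
`min_depth` (default 20; a run at exactly 20× never seeds a locus) over at
least `min_run` nt (45) — reflects a literal reading of "coverage higher
than 20× over a minimum of 45 nucleotides".  Kept runs are extended by
`flank_ext` nt (500) on both sides, clipped at sequence bounds, and
overlapping *or book-ended* extensions merge (with extension, adjacency is
equivalent to overlap).  `flank_ext = 0` disables extension; this is the
one length parameter allowed to be zero, so that locus calling is idempotent
on its own indicator coverage.  Lowering `min_depth` or `min_run` never
removes or shrinks a locus (tested property).

## Motif scanning and classification

Loci are translated in six frames with the standard code; codons containing
N translate to X and score exactly as the background, while a stop codon
inside a motif window is prohibitive (score −10⁶): a motif cannot span a
stop.  A placement's score is Σᵢ log₂(pᵢ(aa)/0.05) — log-odds against a
uniform 1/20 background — and placements at or above the motif's bit
threshold become hits, mapped back to forward-genome nucleotide coordinates
through frame and strand.  Scanning a reverse complement yields mirrored
hits with flipped strands (tested property).  The background and threshold
convention is a deliberately simple MAST-like stand-in; externally derived
matrices (e.g. MEME output) can be supplied through the motif file, whose
format is one header line `>motif_id domain_class threshold_bits` followed
by width rows of 20 probabilities in alphabetical amino-acid order.
`score_tail_probability` computes the exact background tail of a threshold
by discretized convolution (4,000 bins); the observed false-positive rate
on random sequence matches it within Poisson error (tested).

Hits on one strand are chained into series ordered by position; a gap of
more than `max_intra_series_gap` nt (default 1,500 — an intron/linker
scale; the split/merge evidence in real data is a coverage pattern with no
published number, so this is a config knob) starts a new series.  Series
may span frames: colinear frameshifted hits stay in one model, tolerating
pseudogenes.  Opposite-strand hits never share a series; both models are
reported.  Classification is a pure function of the domain-presence set:

| presence | class |
|---|---|
| TIR+NB+LRR | TIR-NB-LRR (full) |
| NB+LRR (±CC) | CC-NB-LRR (full) |
| TIR+NB / CC+NB / TIR+LRR | TIR-NB / CC-NB / TIR-LRR |
| NB / TIR / LRR alone | NB / TIR / LRR |

Non-TIR NB+LRR defaults to CC-NB-LRR without requiring a CC hit: the CNL
N-terminus is weakly defined and the taxonomy has no plain NB-LRR class.
With TIR present the CC signal is ignored (TIR dominates); CC+LRR maps to
LRR and CC alone to `none` — the taxonomy has no classes for these, and
`none` models are excluded from tallies with a warning.  *Full-length*
means NB and LRR both present, the minimal domain structure of a complete
gene.

## CDS bounds

For full-length models only: the start codon is the nearest in-frame ATG
upstream of the first motif hit with no intervening in-frame stop (an ATG
at the motif's own first codon qualifies); the stop is the first in-frame
stop downstream of the last LRR hit.  If either end cannot be established
the model is demoted to partial and flagged 5′- or 3′-truncated — it keeps
its full-length class label, so the type invariant is one-directional:
`full ⇒ class ∈ {CC-NB-LRR, TIR-NB-LRR}`, and a partial model may carry a
full-length class only when truncated.

## NB-ARC extraction and baits

The NB-ARC peptide spans the first-to-last NB-class hit of a model,
translated in model orientation.  Peptides shorter than
`nbarc_min_fraction` (0.5) of the reference domain length are excluded —
strictly less than, so exactly half is retained.  Bait design tiles unique
`bait_len`-mers (120) at stride `bait_step` (60, an arbitrary half-length
stride; the published library's tiling density is not stated) with a final
window flush to the 3′ end; windows containing N are skipped and
uniqueness is set-semantic across all input sequences.

## Reconciliation

Prior and new models pair by same-strand overlap of ≥ 1 nt (gene identity
is strand-specific).  Connected components classify as: 1↔1 identical
bounds → confirmed; 1↔1 differing → boundary; 1↔k → split; k↔1 → merge;
0↔1 → novel; 1↔0 → unsupported.  Many-to-many components become a single
boundary event flagged for manual review — such cases were resolved by hand
in the original study.  Every ID lands in exactly one event, and swapping
inputs swaps split↔merge and novel↔unsupported (tested properties).

## Gap closing

Maximal N-runs ≥ `min_gap_run` (10) intersecting a candidate locus are
closure targets.  A 250-nt anchor left of the gap seeds a contig extended
rightwards: candidate reads are located by exact match of the contig's
terminal `min_overlap`-mer (30) and verified over the full overlap at
≤ `max_mismatch_rate` (0.02); new columns take a majority vote over
extending reads, and a tied column aborts extension (high-confidence
closure over guessing — the record then reports `reduced`).  The right
flank grows symmetrically via its reverse complement.  When the contigs
overlap by ≥ `min_overlap` the gap is **closed** and the sequence between
the flanks becomes the fill; its length need not equal the N-run, since
assembly gap lengths are estimates.  `max_close_iters` (50) caps the
rounds; partial progress reports `reduced` with the remaining N-run
represented as left-extension + Ns + right-extension.

A closure additionally requires mate-pair support.  The naive criterion —
one mate inside each flank contig at a plausible insert — is undefined for
gaps much shorter than the insert (no 700 ± 210 nt pair fits inside two
250-nt contigs), so the package defines support as: a pair whose fragment, placed
in the assembled sequence embedded in its genomic context, spans into the
filled interval with an implied insert within 3 s.d. of `insert_mean`
(700 ± 3·70).  Zero supporting pairs force `reduced`, never `closed`.
Closed fills are applied to a patched genome with an old→new liftover
table; models in loci touching closed gaps are re-annotated on the patched
sequence.

## Expression filter

cDNA alignments are made against the gene-model sequence set, one reference
per model.  Reads with more than one equally-best placement (NH/X0 tag > 1)
are omitted entirely; remaining reads count for their single reference, and
any gene with ≥ 1 unique read is expressed — no count cut-off.  Mates count
as two reads.  `reduction_fraction = 1 − n_expressed/n_total` is computed
at full precision; note the original study's printed 51 % differs from the
arithmetic 1 − 167/326 = 48.8 % — this package always reports the
arithmetic value.

## Distribution reports

Clusters follow the "four or more genes within 200 kb or less" rule:
greedy-left maximal runs of position-sorted genes (strand-agnostic) whose
first-start-to-last-end span is ≤ `cluster_window`, inclusive at exactly
200,000.  Greedy-left resolves the published silence on overlapping
candidate windows; membership partitions the clustered genes.  The χ² test
compares per-chromosome counts with expectations proportional to
chromosome length (df = #chromosomes − 1, upper-tail p from the χ²
distribution); unanchored bins should be excluded by the caller, as
unplaced pseudo-chromosomes distort length shares.  Tally totals are always
sums of displayed rows, never stored independently, so an output table
cannot be internally inconsistent.

## Synthetic truth

The simulator is first-class, tested code and defines the study
conditions.  Defaults: one ~1 Mb chromosome, 30 intron-free genes covering
all eight classes (8 CNL, 6 TNL, 3 CC-NB, 3 TIR-NB, 2 TIR-LRR, 4 NB,
2 TIR, 2 LRR), one 4-gene physical cluster, three N-gaps placed in
inter-gene sequence near genes (so they fall inside candidate loci), a
prior annotation with exactly one fused pair, one split gene and one
missing gene, and 50 % of genes expressed.  Genes are built from
15-residue consensus motif blocks (consensus probability 0.9, 25-bit
thresholds, 2 % per-position substitution noise) joined by in-frame linkers
free of ATG and stop codons, making true CDS bounds unambiguous.  Gap
masking preserves length by default; a fixture helper plants gaps whose
N-run length mis-states the true span, reproducing length-correcting
closures.

gDNA read pairs (250 bp, insert 700 ± 70) are drawn to overlap capture
targets (genes plus gap neighbourhoods, merged to avoid double-sampling)
with probability `on_target_fraction` (0.5, the enrichment efficiency seen
in real captures) and otherwise uniformly from non-target genome; fragments
come from the pre-masking sequence so gap interiors carry real bases, while
SAM placement uses true origins and `n_best_hits` counts exact-match
placements against the released genome (a 2-bit-packed 32-mer prefilter
makes this fast).  Interior target depth equals `depth_on_target` in
expectation because per-target sampling weights are length + insert − 1.
cDNA reads are single-end, multinomial around truth expression levels;
verbatim-duplicated transcripts carry `n_best_hits` equal to their copy
number.  The simulator does not model base qualities, indel errors,
introns, organellar contamination or bait thermodynamics — passing tests
demonstrate algorithmic correctness on clean enrichment data, not
robustness to those real-data artefacts.

## Problem sizes and determinism

Every generator and the pipeline are deterministic per seed (reruns are
byte-identical, tested).  The test suite and acceptance script use the
default study conditions above, 1,000-track locus-caller oracle sweeps,
60–100 random gap fixtures (50–1,500 nt) and 500 random reconciliation
sets — sizes chosen so the whole suite runs in seconds on one CPU while
exercising every code path at the scales the method targets.

## Known limitations

Splice-aware prediction is out of scope (genes are treated as intron-free;
real intron-containing NB-LRRs surface as frameshift-tolerant series with
motif-span bounds).  Multi-mapping status relies on the NH/X0 tags or
exact-match counting, not on a full aligner's scoring.  Gap closing is a
local consensus assembler, not a general assembler: repeats longer than the
read length inside a gap can stall extension (reported `reduced`), and
scaffolding across contig ends is not attempted.  MAST E-values are not
reproduced; thresholds are in bits.
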