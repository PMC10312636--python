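# Methods

`haplotx` detects transcript isoforms from error-prone long-read RNA-seq,
attaches sequence variants to the isoforms that carry them
(haplotype-specific transcripts, HSTs), and quantifies A-to-I editing at
the single-molecule level. This note records the models and procedures,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic data used by the tests does and
does not show about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention). GTF
(1-based closed) and VCF (1-based) are converted at the I/O boundary and
nowhere else. Minus-strand A→G editing is represented at the genome level
as T→C; strand is always resolved from the host gene's annotation, and
positions with no unambiguous gene strand are excluded from editing
analyses. Multi-allelic VCF records are split per ALT before the
single-nucleotide filter; multi-nucleotide records are skipped with a
counted warning.

## Read-to-transcript assignment (annotation-reliant step)

Reads are first aligned, ungapped, to the annotated transcriptome; the
top alignments per read (mapping quality descending, ties by edit
distance then transcript id) are screened with two rules before a read
may support an annotated isoform:

* **stringent** — matched bases / aligned read bases ≥ 0.80 (soft-clipped
  bases excluded from the denominator: clips reflect adapters and
  poly(A), not transcript disagreement), and the alignment spans into the
  terminal exons, leaving at most min(25 bp, exon length) uncovered at
  each transcript end. The min() makes the rule tolerant of terminal
  exons shorter than 25 bp.
* **check-splice** — around every junction whose ±3 bp window the
  alignment fully covers, at least 4 of the 6 flanking bases must be
  matches, and no insertion or deletion longer than 3 bp may touch the
  window. Junctions not fully covered by a (truncated) read impose no
  constraint, so truncation alone never fails this rule.

All thresholds are inclusive (≥ 0.80, ≤ 25 bp missed, ≥ 4 of 6, indel
≤ 3 bp passes); the boundary cases are pinned by tests. Annotated
transcripts with ≥ 3 supporting reads (`min_support`, inclusive) enter
the final set; all other reads go to novel-model collapse.

## Novel isoform collapse

1. **Splice-site correction.** Donor and acceptor sites of each genome-
   aligned read are snapped independently to the nearest evidence site
   within 10 bp (ties to the smaller coordinate). Evidence sites come
   from the annotation and optional short-read junctions
   (unconditionally usable) and from long-read junctions once ≥ 3
   distinct reads support them — "more evidence" made concrete. Reads
   with an uncorrectable site, or whose corrected junctions degenerate,
   are excluded from model building. The 10 bp window and the evidence
   weighting are configurable.
2. **Grouping.** Corrected reads group by exact junction-chain equality;
   a chain that is a strict prefix of another is a separate group.
   Single-exon reads group per overlap-connected locus.
3. **End calling.** Read starts and ends are clustered independently by
   single linkage with a 100 bp gap; each occupied (start-cluster,
   end-cluster) pair becomes a first-pass model whose TSS/TES is the
   cluster's most-supported position (ties to the outermost). Single
   linkage was chosen for determinism and because cDNA long-read ends
   wander tens of bp; the window is configurable.
4. **Re-assignment.** Every read is matched against all first-pass models
   whose chain contains the read's corrected chain as a contiguous
   subchain (overlap for mono-exon reads), by projecting the genome
   alignment through the model's exon structure into transcript
   coordinates and applying the same two fidelity rules. For ungapped
   long-read alignments this projection is an exact realignment, so no
   external aligner is needed; aligner-specific artifacts (clip wobble,
   multimapping) are consequently not exercised by the tests. Read bases
   aligned inside a model's intron count as an insertion at that
   junction, which is what makes a retained-intron read fail against the
   spliced model. The best passing model by matched bases wins; reads
   may move between the group that built a model and another model, and
   movement is counted in the manifest.
5. **Filtering and merging.** Novel models need ≥ 3 supporting reads. A
   novel chain identical to a retained annotated transcript collapses
   onto the annotated entry. Terminal-truncation artifacts are absorbed
   into their parent: a model whose chain is a strict terminal subchain
   of a better-supported model (far end within the 100 bp end window,
   near end inside the parent's span), or whose chain equals a
   better-supported model's with its span contained in the parent's, is
   treated as a 5'/3'-degradation pile-up rather than a distinct
   isoform. This deliberately trades away genuine same-chain
   alternative-TSS isoforms separated by more than the end window — a
   documented limitation, switchable via `filter_subchains`. Single-exon
   models fully contained in an exon of a multi-exon model are
   suppressed as degraded fragments. Strand of novel models is inferred
   by GT–AG/CT–AC dinucleotide majority vote, falling back to the
   alignment flag, because cDNA strandness is unreliable.

## Variant phasing

Variant calls from one or more callers are unioned after a per-site
exonic-coverage filter (default ≥ 10 reads), keeping the maximum quality
and concatenating caller provenance for duplicates.

**Ploidy-agnostic tabulation.** For each isoform, every supporting read
is reduced to its ref/alt vector over the variant positions inside the
isoform's exons. Complete vectors are counted; vectors with support
below `min_haplotype_support` (3) that differ from a surviving vector at
exactly one position are absorbed into it — at 1% substitution error a
5-variant isoform would otherwise shed ~5% of its reads into spurious
one-off haplotypes. Vectors with support ≥ 3 and ≥ 10% of the isoform's
reads become haplotypes (both thresholds inclusive and configurable);
reads covering only some positions then add support to the unique
surviving haplotype consistent with them. Nothing caps the number of
haplotypes at two. Haplotype indices are assigned by descending support
with lexicographic tie-breaks, so output is read-order invariant.

**Phase-set mode.** Reads carrying HP/PS tags from a diploid phasing
caller are partitioned by (phase set, haplotype); allele vectors come
from the VCF's phased genotypes. A read whose carried base contradicts
its tag follows the tag; contradictions are counted and reported.

**HST bias.** Per gene with ≥ 2 isoforms and ≥ 2 haplotype labels, each
(isoform, haplotype) pair is tested with a two-sided Fisher's exact test
on [[this isoform × this haplotype, this isoform × other], [other
isoforms × this haplotype, other × other]], adjusted transcriptome-wide
(Benjamini–Hochberg; Bonferroni available). Per-gene adjustment is the
defensible alternative; transcriptome-wide matches discovery-list
practice. In tabulation mode, per-isoform haplotypes are first clustered
into gene-level labels greedily by compatibility (agreement at every
shared variant position, at least one shared), in descending support
order.

HST outputs substitute alt alleles into the spliced sequence in genome
orientation before the minus-strand reverse complement, so a genomic
T→C surfaces as A→G in the transcript. HST records are named
`<transcript_id>_<haplotype_index>_<gene_id>`; the emitted VCF carries
the isoform list per variant in a custom `ISO` INFO key.

## Editing analyses

Candidate positions are A→G records in plus-strand genes and T→C records
in minus-strand genes from the combined VCFs, plus an optional
user-supplied known-sites BED (in place of a remote editing database).
The pileup counts, per condition, reads carrying the strand-appropriate
reference vs edited base; other bases and deletions are excluded from
the fraction denominator but tracked.

* **Differential editing** retains sites with coverage ≥ 10 in *either*
  condition (literal reading; "both" is defensible and configurable), an
  edit-fraction change ≥ 10 points, and two-sided Fisher p < 0.05 on the
  edit/ref counts. Replicates are pooled per condition upstream.
  Direction is "down" when the knockdown fraction is lower.
* **Type I hyperediting**: edit fraction strictly > 40% at a covered
  site.
* **Type II hyperediting**: maximal clusters in which every run of 3
  consecutive edits spans < 150 bp; overlapping qualifying windows
  sharing a member edit merge, and region bounds are the outermost
  member positions. An optional per-read edited-fraction criterion
  exists in the literature; it is not applied here.
* **Edit–edit coordination**: for each site, its 20 nearest candidate
  neighbours at ≥ 50 bp are paired (each unordered pair once); reads
  covering both sites exonically fill a (both, only-A, only-B, neither)
  table; pairs are reported at raw Fisher p < 0.05 with a BH column
  alongside, since coordination discovery is reported on raw p.
* **Edit–intron coordination**: sites that are type I hyperedited among
  exonically covering reads, with ≥ 10 edited reads and ≥ 10 reads
  carrying the position inside a spliced-out intron — the signature of
  mutually exclusive editing and splicing on single molecules.

## Statistics

`fisher_exact_two_sided` uses the standard "sum of all tables with the
same margins whose probability is ≤ the observed table's" convention
(ties included up to ~1e-7 relative tolerance), delegating to
`scipy.stats.fisher_exact`; a brute-force hypergeometric enumeration
oracle verifies agreement to 1e-9 on every 2×2 table with N ≤ 40 (up to
the 8-fold table symmetry, which is property-tested separately). Tables
with an empty margin return p = 1. `bh_adjust` implements the step-up
formula directly (order-preserving, capped at 1, monotone) and is
cross-checked against statsmodels.

## Transcript-set evaluation

A predicted transcript matches a truth transcript iff their junction
chains are identical at exact coordinates and both terminal ends agree
within 50 bp (inclusive); internal sites get no wiggle because terminal
variability, not splice-site error, is the tolerated quantity.
Mono-exon transcripts additionally must overlap. Matching is greedy
1-to-1 by smallest total end distance with id tie-breaks —
deterministic, and each truth transcript is claimed at most once.
Sensitivity and precision are percentages of truth and predictions
matched, respectively.

## Synthetic data: what it does and does not emulate

The generator draws a random genome with alternating-strand gene loci;
each gene's isoforms share an exon scaffold and differ by skipping
distinct internal exons, so isoforms always differ in at least one
junction (this also means same-chain alternative-end isoforms are not
generated — consistent with the truncation-artifact filter above).
Introns carry canonical GT–AG (CT–AC) dinucleotides so strand inference
is exercised. Reads default to 1% uniform substitution error
(R2C2-consensus-like, substitution-dominated; indel error is a separate
knob, default off), 30% truncation probability with exponential 5'/3'
extents (means 50/20 bp, capped at 30% of length) reflecting incomplete
reverse transcription anchored at the 3' end, diploid haplotypes in
which haplotype 2 carries every alt allele of its gene (parental-strain
style, one phase set per gene), and per-site Bernoulli edits at the
condition's fraction.

Alignments are emitted directly from simulation truth as SAM with =/X/N
CIGARs (minus-strand reads stored reverse-complemented with flag 16).
Passing tests therefore demonstrate the pipeline's behaviour given
*correct* alignments; they do not probe aligner wobble, multimapping,
chimeras, or reference bias. Same seed gives byte-identical files.

## Problem sizes used by the test and acceptance runs

Collapse recovery uses 20 transcripts × 100 reads (1% error, 30%
truncation), scored annotation-free — the harder regime, since every
model must be rebuilt from reads. Haplotype recovery uses 50 isoforms ×
2 haplotypes × 30 reads each. Differential editing uses 200 sites (50
shifted 0.5→0.1, 150 null at 0.3) at coverage 30 per condition; at
those conditions the filter chain's exact detection power, obtained by
enumerating all count outcomes through the package's own decision
function, is 0.905, with a null rejection rate of 0.026 — the
acceptance test asserts these exact operating characteristics and
checks a full simulated run for consistency with them, because a single
50-site draw has ~0.04 sampling noise on a quantity whose target sits
in the third digit.

## Known limitations

* No aligner integration: alignments and variant calls are consumed,
  never produced.
* Same-chain isoforms differing only in ends beyond the end window are
  merged by the truncation-artifact filter when support is asymmetric.
* The gene-level haplotype clustering used for HST testing in
  ploidy-agnostic mode is greedy; pathological overlap patterns could
  split one biological haplotype into two labels.
* Fusion/chimeric reads, CRAM, and GFF3 are out of scope.
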