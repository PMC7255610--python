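# Methods

## The annotation model

`srannot` assigns each mapped sRNA-seq read to an annotation *class*
(miRNA, snoRNA, CDS, intron, upstream, …) using every alignment location
("hit") the mapper reported. The method has no statistical model and no
tunable weights: it is a deterministic two-step resolution.

**Step 1 — hit annotation.** For a hit h with reference span [s, e] (1-based,
closed), the candidate features are all features whose interval overlaps
[s, e] by at least one base. A candidate survives if

* its overlap length passes the minimum-overlap threshold (below), and
* the read strand satisfies the class's orientation rule: `+`-qualified
  classes require read strand = feature strand, `-`-qualified the opposite,
  unqualified classes accept both.

Each class sits in a priority tier (Order line number, 0 = highest). Only
the surviving candidates on the minimal tier are kept. A hit with no
surviving candidate is *intergenic* (orphan); a hit whose kept candidates
span more than one class is already ambiguous.

**Step 2 — read resolution.** Intergenic hits are dropped unless every hit
is intergenic (then the read is *unannotated*). The kept matches of all
hits are pooled and tier-minimised once more across hits. If one class
remains, the read is counted there: status *unique* when the read has a
single hit, *rescued* when it is multi-mapping (its ambiguity dissolved
through agreeing hits, orphan hits, or priority filtering). If several
classes remain, the read is *ambiguous* and counted under a *merged
annotation*: the tied class labels sorted by (tier, lexicographic) and
joined with `--`. Merged annotations are first-class rows of the count
table; they are never redistributed.

The cross-hit tier minimisation deserves a note, because the two natural
readings differ: priorities could apply only within a hit, or across the
whole read. We apply them across the read — a read with one hit on a miRNA
(tier 0) and another hit on an intron (tier 2) resolves to miRNA, status
rescued, rather than to the merged pair. This is the reading consistent
with treating the tier order as a statement about which class a read
*really* comes from; the worked example in the test-suite exercises both
this case and the equal-tier cases where merging is the only honest answer.
A single-hit read whose one location ties several classes is reported
ambiguous regardless of its hit count.

**Feature-level counts.** Alongside the class table, reads are counted per
canonical feature-id combination (sorted, deduplicated). A rescued read
spanning two copies of a duplicated locus contributes to the pair
(`mirD1;mirD2`), which is how duplications and suspicious annotation
overlaps surface for inspection.

## Counting strategies

* `default` — the method above; every read contributes weight 1 to exactly
  one row (class, merged class, or unannotated).
* `unique` — multi-mapping reads (n > 1) go to a `multi-mapping (discarded)`
  row; single-mapping reads are resolved normally.
* `random` — one of the n hits is drawn uniformly (among *all* hits, so an
  intergenic draw leaves the read unannotated) and resolved alone.
* `ratio` — each hit is resolved alone and contributes 1/n; the share of
  intergenic hits goes to the unannotated row, i.e. that weight is lost.

All four conserve a total weight of exactly 1 per read; the accumulator
asserts this per read and per file. On input where every read maps uniquely
the four strategies coincide exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| priority tiers | (user) | one Order line per tier; same line = same rank |
| overlap threshold | 1 nt | minimum hit/feature overlap; `Nnt` absolute or `P%` of the read length, compared against ⌈p·L⌉; equality passes |
| vicinity size | 3000 nt | width of derived upstream/downstream regions, a span wide enough to catch promoter- and terminator-proximal sRNAs |
| bin width | 16384 nt | interval-index granularity; a few vicinity-sized features per bin, far above sRNA read length, so queries touch 1–2 bins |
| seed | 17 | drives the `random` strategy; each input file uses seed + file ordinal, so multi-file runs are reproducible for any thread count |

## Derived features

Genes are reconstructed per `gene_id` from `exon` rows, overlapping or
abutting exons merged; `CDS` rows with the same id attach to the model.
Introns are the maximal gaps between consecutive merged exons (per gene,
not per transcript — isoform-level introns are out of scope), so exons and
introns tile the gene span exactly. UTRs exist only for genes with CDS:
5'UTR = exonic bases strictly 5' of the first CDS base (strand-aware),
3'UTR symmetric; 5'UTR ∪ CDS ∪ 3'UTR partitions the exon union, a property
the tests assert base-by-base. Vicinity regions abut the feature span, are
clipped at position 1 and, when a chromosome length is known from the
SAM/BAM header, at the chromosome end; GTF itself carries no lengths, so
without a header the right edge is left unclipped.

Derived features inherit their parent's id, so several introns of one gene
share a feature id; internally features are identified by (id, interval),
and duplicate ids across loci (common for miRNA families) are allowed.

## Input handling

Coordinates are 1-based closed throughout (GTF native; SAM POS is 1-based;
pysam's half-open ends are converted at the boundary). The hit span is the
reference-consumed length of the CIGAR (M/D/N/=/X), for XA entries computed
from the embedded CIGAR string. Secondary records (0x100) are hits;
supplementary (0x800) and unmapped (0x4) records are skipped; paired-end
input is rejected — the method is defined for single-end sRNA-seq. When an
NH tag disagrees with the records actually present, the observed hits win
and a warning is emitted: only observable hits can be annotated. Read
length comes from the first record with SEQ, else from the CIGAR
query length.

The NH companion (`set-nh`) operates on SAM text directly and only appends
or rewrites the `NH:i:` field, leaving every other byte of the record — and
the header — unchanged; it is idempotent.

## What the simulator emulates — and what it does not

`simulate_dataset` lays out non-overlapping loci of several sRNA classes on
a toy chromosome (100 nt loci, 2 kb apart), duplicates a chosen fraction of
loci *verbatim* into 2–3 copies, and draws fixed-length reads uniformly
from the loci plus an intergenic background zone. A read from a duplicated
locus gets one hit per copy at the same offset, with a correct NH tag; the
ground truth records each read's class, origin copy and hit count. Defaults
— 10,000 reads of 21 nt, four classes, 25 loci each, 30% of loci
duplicated, 10% intergenic — are a desk-scale stand-in for a real library.

Deliberately absent: sequencing errors and mismatched mapping (the method
consumes mapper output and is agnostic to how hits were found), partial or
diverged duplications, overlapping annotation classes, expression-level
skew between loci, and multi-chromosome genomes. Passing tests on this
generator therefore demonstrate the bookkeeping claims — no read lost,
perfect rescue under exact duplication, conservation, strategy concordance
— not robustness to annotation errors or to near-identical paralogs, where
hits may straddle class boundaries and merged annotations will grow
accordingly.

## Numerical and degenerate-case choices

* Merged labels use the two-character separator `--`; single-character
  dashes occur inside real class names, which would make merged labels
  unparseable.
* Percentage thresholds round up (⌈p·L⌉) and ties pass; only overlaps
  strictly below the threshold are discarded.
* A read overlapping the same feature through two hits deduplicates on
  (class, feature id) and counts once.
* Empty inputs produce empty (all-zero) tables; a single-exon gene has no
  introns; a feature starting at base 1 has no upstream region.
* Count-table rows are sorted with the bookkeeping rows (`unannotated`,
  discarded) last; ratio weights print with 6 decimals, integral weights as
  integers.
* The annotation rate is computed over the reads present in the input file;
  reads that never mapped (absent from the SAM/BAM) are upstream of this
  tool and cannot enter the denominator.

## Problem sizes used in the checks

The shipped verification runs at desk scale: the seven-read worked example,
simulations of 10,000 reads for the ground-truth and conservation checks,
and 1,000 features × 1,000 queries for the index-vs-brute-force oracle.
These sizes exercise every code path (duplication, rescue, merging,
discarding, priority reversal) while keeping the whole suite in the
seconds range.

## Known limitations

* GFF3 parent/child hierarchies are not resolved; gene models come from
  flat `exon`/`CDS` rows grouped by one attribute.
* Introns and UTRs are per-gene (merged exons), not per-transcript.
* One overlap threshold applies to all classes.
* No expression-informed placement of multi-mappers (EM/rescue-by-coverage
  approaches are a different trade-off: they use more reads confidently at
  the price of a model assumption this tool deliberately avoids).
* Reads are treated as unspliced blocks; CIGAR N gaps extend the span
  rather than splitting it, which is adequate for short sRNA reads.
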