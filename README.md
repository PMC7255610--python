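# srannot

Multi-mapping-aware annotation and quantification of small RNA-seq reads.

## The problem

Small RNAs (miRNAs, snoRNAs, tRNA fragments, piRNAs, siRNAs, …) are short,
and many of them are transcribed from duplicated or repeated loci. As a
result, a large share of the reads in an sRNA-seq library maps to several
genomic locations, and a read's locations often overlap several annotation
classes at once. The common work-arounds — keep only uniquely mapping reads,
pick one hit at random, or spread a weight of 1/n over the n hits — either
throw reads away, misplace them, or dilute them across classes, and all of
them hide how much of the quantification is actually ambiguous.

`srannot` instead uses **all hits of every read** and makes the ambiguity
explicit:

1. Each hit is matched against the annotation set. Overlapping features must
   pass a minimum-overlap threshold (nucleotides or a percentage of the read
   length) and the per-class strand rule (collinear `+`, antisense `-`, or
   either). Classes are ranked by user-defined **priority tiers**; only the
   matches on a hit's best tier are kept, so e.g. a read on a miRNA inside an
   intron counts as miRNA when miRNA outranks intron.
2. The read is then resolved from its hits. Intergenic (orphan) hits are
   ignored unless all hits are orphan. If one class remains, the read is
   counted there — status *unique* for single-mapping reads, ***rescued***
   for multi-mapping reads whose hits nonetheless agree (e.g. reads from a
   perfectly duplicated miRNA pair). If several equally ranked classes
   remain, the read is counted under a ***merged annotation***, the
   concatenation of the tied class labels (`CDS (+)--miRNA`), reported as a
   category of its own rather than silently dropped or split.

Because no read is discarded and no model redistributes weights, a read from
a duplicated locus is never lost, and on reads with known origin the true
class is always among the classes the label names.

Annotation files rarely contain everything small RNAs come from, so
`srannot` derives the missing features in memory from an Ensembl-style GTF:
introns (gaps between merged exons), 5'/3' UTRs (exonic bases up/downstream
of the CDS), and user-sized upstream/downstream vicinity regions (default
±3 kb).

Besides the default method, the classical strategies are available for
comparison: `unique` (discard multi-mappers), `random` (place each read on
one of its n hits, chosen uniformly), and `ratio` (1/n per hit, the weight
of intergenic hits being lost).

## Input contracts

* **Annotation**: GTF, 9 tab-separated columns, `key "value";` attributes.
* **Reads**: single-end SAM/BAM, records of one read consecutive.
  Multi-mapping is read either from one record per hit (NH tag) or from a
  BWA-style `XA` tag on the primary record. For mappers that emit one line
  per hit without NH (bowtie), `srannot set-nh in.sam out.sam` adds the
  correct tags first.
* **Configuration**: a plain-text file with three sections —

```
Introns:
gene

Vicinity:
gene

Order:
miRNA .:CDS + 5'UTR 3'UTR +
gene -
intron
upstream
downstream
```

`Introns`/`Vicinity` name the classes whose introns, UTRs and flanking
regions are derived. Each `Order` line is one priority tier (highest first);
tokens on the same line have equal priority; `source:feature` selects GTF
rows (`.` = any source) and a trailing `+`/`-` restricts the class to
collinear/antisense reads.

## Worked example

A miniature genome with one plus-strand coding gene and five miRNAs, and
seven 20-nt reads A–G (reads D, F, G each map twice). The fixture ships with
the package:

```python
from srannot.simulate import worked_example
sc = worked_example()
open("example.gtf", "w").write(sc.gtf_text)
open("example.conf", "w").write(sc.config_text)
open("example.sam", "w").write(sc.sam_text)
```

```sh
srannot annotate -a example.gtf -c example.conf -o counts.tsv \
    --feature-counts features.tsv --read-annotations reads.tsv example.sam
```

`reads.tsv` shows each resolution path:

```
read	status	annotation	features
A	unique	upstream	gene1
B	unique	gene (-)	gene1
C	unique	miRNA	mirC
D	rescued	miRNA	mirD1;mirD2
E	ambiguous	CDS (+)--miRNA	gene1;mirE
F	ambiguous	3'UTR (+)--miRNA	gene1;mirF
G	rescued	5'UTR	gene1
```

A maps only to the gene's upstream region. B lies in the CDS but on the
opposite strand, so the collinear `CDS +` class cannot apply and the
antisense `gene -` class takes it. C overlaps a miRNA inside an intron —
miRNA outranks intron. D maps to both copies of a duplicated miRNA and is
*rescued*. E overlaps a CDS and a miRNA of equal priority at one locus, F a
3'UTR and a miRNA through its two hits — both are irreducibly ambiguous and
counted under merged annotations. G's second hit is intergenic, so it is
rescued to 5'UTR. The class table (`counts.tsv`):

```
annotation	example.sam
3'UTR (+)--miRNA	1
5'UTR	1
CDS (+)--miRNA	1
gene (-)	1
miRNA	2
upstream	1
```

and the run summary reports 7/7 reads annotated, 2 rescued, 2 ambiguous.
The feature table (`features.tsv`) lists the id combinations behind each
count — `mirD1;mirD2` flags the duplicated pair, `gene1;mirE` the
CDS/miRNA annotation overlap worth inspecting.

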