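"""Genome annotation model: GTF records, gene models and derived features.

Standard annotation files omit several regions small-RNA reads routinely come
from: introns, UTRs and the flanking (vicinity) regions of genes.  This module
parses Ensembl-style GTF, reconstructs gene models from their exon rows, and
derives those missing features in memory so they can be quantified like any
primary annotation class.

All coordinates are 1-based and inclusive at both ends (GTF native; SAM POS is
already 1-based), and all interval arithmetic uses closed intervals.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .config import ClassSpec, Config, Selector, match_selector

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;')

# origins of derived features
PRIMARY = "primary"
INTRON = "intron"
FIVE_UTR = "five_utr"
THREE_UTR = "three_utr"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

_ORIGIN_CLASS = {
    INTRON: "intron",
    FIVE_UTR: "5'UTR",
    THREE_UTR: "3'UTR",
    UPSTREAM: "upstream",
    DOWNSTREAM: "downstream",
}


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


class GeneModelError(ValueError):
    """Raised when exon/CDS records cannot form a consistent gene model."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded closed interval on a chromosome (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class AnnotationRecord:
    """One non-comment GTF line."""

    interval: GenomicInterval
    source: str
    feature: str
    attributes: tuple[tuple[str, str], ...]  # ordered key/value pairs

    @property
    def attr(self) -> dict[str, str]:
        return dict(self.attributes)


@dataclass
class GeneModel:
    """A gene reconstructed from its exon (and CDS) rows, exons merged."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class AnnotationFeature:
    """An interval carrying a quantifiable class label.

    ``spec`` is the Order-section class this feature counts toward (None when
    the class is not quantified); ``origin`` distinguishes primary GTF rows
    from in-memory derived features, whose ``feature_id`` is the parent
    gene/feature id.
    """

    feature_id: str
    class_label: str
    interval: GenomicInterval
    origin: str = PRIMARY
    spec: ClassSpec | None = None

    @property
    def tier(self) -> int | None:
        return None if self.spec is None else self.spec.tier


def parse_gtf_line(line: str, lineno: int) -> AnnotationRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GtfParseError(
            f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
        )
    chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
    if not source or not feature:
        raise GtfParseError(f"line {lineno}: empty source or feature field")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise GtfParseError(
            f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
        ) from None
    if start > end or start < 1:
        raise GtfParseError(f"line {lineno}: invalid coordinates {start}-{end}")
    if strand not in ("+", "-"):
        raise GtfParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
    attributes = tuple(_ATTR_RE.findall(attrs))
    return AnnotationRecord(
        interval=GenomicInterval(chrom, start, end, strand),
        source=source,
        feature=feature,
        attributes=attributes,
    )


def read_gtf(path) -> list[AnnotationRecord]:
    """Read a GTF file into annotation records (comments skipped)."""
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            records.append(parse_gtf_line(line, lineno))
    return records


def format_gtf_record(record: AnnotationRecord) -> str:
    attrs = " ".join(f'{k} "{v}";' for k, v in record.attributes)
    iv = record.interval
    return "\t".join(
        [
            iv.chrom,
            record.source,
            record.feature,
            str(iv.start),
            str(iv.end),
            ".",
            iv.strand,
            ".",
            attrs,
        ]
    )


def write_gtf(records, path) -> None:
    with open(path, "w") as fh:
        for record in records:
            fh.write(format_gtf_record(record) + "\n")


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of closed intervals; touching intervals ([a,b],[b+1,c]) merge."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end + 1:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, iv.strand
                )
        else:
            merged.append(iv)
    return merged


def reconstruct_genes(
    records, id_attribute: str = "gene_id"
) -> list[GeneModel]:
    """Group exon rows by ``id_attribute`` into gene models, merging
    overlapping exons and attaching CDS rows with the same id.

    Raises :class:`GeneModelError` for an exon without the id attribute or a
    gene whose exons sit on mixed strands/chromosomes.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for record in records:
        if record.feature not in ("exon", "CDS"):
            continue
        gid = record.attr.get(id_attribute)
        if gid is None:
            raise GeneModelError(
                f"{record.feature} record at {record.interval.chrom}:"
                f"{record.interval.start}-{record.interval.end} lacks "
                f"attribute {id_attribute!r}"
            )
        bucket = exons if record.feature == "exon" else cds
        if gid not in exons and gid not in cds:
            order.append(gid)
        bucket.setdefault(gid, []).append(record.interval)

    genes: list[GeneModel] = []
    for gid in order:
        ivs = exons.get(gid)
        if ivs is None:
            # CDS without exons: treat the CDS rows themselves as exonic
            ivs = cds[gid]
        strands = {iv.strand for iv in ivs}
        chroms = {iv.chrom for iv in ivs}
        if len(strands) > 1 or len(chroms) > 1:
            raise GeneModelError(
                f"gene {gid!r} has exons on mixed strands or chromosomes"
            )
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chroms.pop(),
                strand=strands.pop(),
                exons=merge_intervals(ivs),
                cds=merge_intervals(cds.get(gid, [])),
            )
        )
    return genes


def infer_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Maximal gaps between consecutive merged exons (empty for single-exon
    genes); introns and exons are disjoint and tile the gene span."""
    introns = []
    for left, right in zip(gene.exons, gene.exons[1:]):
        if right.start > left.end + 1:
            introns.append(
                GenomicInterval(gene.chrom, left.end + 1, right.start - 1, gene.strand)
            )
    return introns


def infer_utrs(
    gene: GeneModel,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """5' and 3' UTRs: exonic bases strictly up-/downstream of the CDS,
    strand-aware.  Requires at least one CDS interval contained in the exons."""
    if not gene.cds:
        raise GeneModelError(f"gene {gene.gene_id!r} has no CDS; cannot infer UTRs")
    for c in gene.cds:
        if not any(e.start <= c.start and c.end <= e.end for e in gene.exons):
            raise GeneModelError(
                f"gene {gene.gene_id!r}: CDS {c.start}-{c.end} not contained "
                "in the exon union"
            )
    cds_start = min(c.start for c in gene.cds)
    cds_end = max(c.end for c in gene.cds)
    left: list[GenomicInterval] = []
    right: list[GenomicInterval] = []
    for e in gene.exons:
        if e.start < cds_start:
            left.append(
                GenomicInterval(
                    gene.chrom, e.start, min(e.end, cds_start - 1), gene.strand
                )
            )
        if e.end > cds_end:
            right.append(
                GenomicInterval(
                    gene.chrom, max(e.start, cds_end + 1), e.end, gene.strand
                )
            )
    if gene.strand == "+":
        return left, right
    return right, left


def make_vicinity(
    feature_interval: GenomicInterval,
    size: int,
    chrom_length: int | None = None,
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Flanking regions abutting the feature, strand-aware, clipped at
    position 1 and (when known) the chromosome end.  Either side may be None
    when fully clipped away."""
    iv = feature_interval
    left = right = None
    if iv.start > 1:
        left = GenomicInterval(iv.chrom, max(1, iv.start - size), iv.start - 1, iv.strand)
    right_end = iv.end + size
    if chrom_length is not None:
        right_end = min(right_end, chrom_length)
    if right_end > iv.end:
        right = GenomicInterval(iv.chrom, iv.end + 1, right_end, iv.strand)
    if iv.strand == "+":
        return left, right
    return right, left


def primary_feature_id(record: AnnotationRecord) -> str:
    for key in ("ID", "gene_id", "Name"):
        if key in record.attr:
            return record.attr[key]
    iv = record.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def _selector_targets(
    selector: Selector,
    records,
    genes_by_id: dict[str, GeneModel],
    id_attribute: str,
) -> tuple[list[GeneModel], list[AnnotationRecord]]:
    """Resolve an Introns/Vicinity selector to gene models and/or plain records.

    A selector on feature ``gene`` addresses every reconstructed gene model,
    whether or not explicit ``gene`` rows exist.  Any other selector addresses
    the matching records directly; when such a record's id names a
    reconstructed gene, the gene model is used (so introns can be derived).
    """
    if selector.feature_pattern == "gene":
        genes = sorted(genes_by_id.values(), key=lambda g: g.gene_id)
        if selector.source_pattern != ".":
            matched_ids = {
                r.attr.get(id_attribute)
                for r in records
                if match_selector(selector, r.source, r.feature)
            }
            genes = [g for g in genes if g.gene_id in matched_ids] or genes
        return genes, []
    genes, plain = [], []
    for record in records:
        if not match_selector(selector, record.source, record.feature):
            continue
        gid = record.attr.get(id_attribute)
        if gid in genes_by_id:
            genes.append(genes_by_id[gid])
        else:
            plain.append(record)
    return genes, plain


def build_feature_set(
    records,
    config: Config,
    vicinity_size: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
    id_attribute: str = "gene_id",
) -> list[AnnotationFeature]:
    """Assemble the in-memory annotation set the reads are matched against.

    Emits (i) every primary record matched by an Order selector, labeled with
    that class; (ii) introns of the classes listed under Introns; (iii)
    upstream/downstream regions and inferred UTRs of the classes listed under
    Vicinity.  The input records are left untouched.  Output order is
    deterministic and independent of the GTF record order.
    """
    if vicinity_size is None:
        vicinity_size = config.vicinity_size
    chrom_lengths = chrom_lengths or {}
    genes = reconstruct_genes(records, id_attribute=id_attribute)
    genes_by_id = {g.gene_id: g for g in genes}
    derived_specs = {
        s.feature_pattern: s for s in config.all_specs() if s.is_derived
    }

    features: list[AnnotationFeature] = []

    # (i) primary records
    for spec in config.all_specs():
        if spec.is_derived:
            continue
        matched = False
        for record in records:
            if match_selector(spec, record.source, record.feature):
                matched = True
                features.append(
                    AnnotationFeature(
                        feature_id=primary_feature_id(record),
                        class_label=spec.label,
                        interval=record.interval,
                        origin=PRIMARY,
                        spec=spec,
                    )
                )
        if not matched:
            warnings.warn(
                f"Order selector {spec.token()!r} matched no annotation record",
                stacklevel=2,
            )

    def emit(origin: str, parent_id: str, interval: GenomicInterval) -> None:
        class_name = _ORIGIN_CLASS[origin]
        spec = derived_specs.get(class_name)
        label = spec.label if spec is not None else class_name
        features.append(
            AnnotationFeature(
                feature_id=parent_id,
                class_label=label,
                interval=interval,
                origin=origin,
                spec=spec,
            )
        )

    # (ii) introns
    for selector in config.intron_sources:
        sel_genes, _ = _selector_targets(selector, records, genes_by_id, id_attribute)
        for gene in sel_genes:
            for intron in infer_introns(gene):
                emit(INTRON, gene.gene_id, intron)

    # (iii) vicinity regions and UTRs
    for selector in config.vicinity_sources:
        sel_genes, plain = _selector_targets(selector, records, genes_by_id, id_attribute)
        for gene in sel_genes:
            up, down = make_vicinity(
                gene.span, vicinity_size, chrom_lengths.get(gene.chrom)
            )
            if up is not None:
                emit(UPSTREAM, gene.gene_id, up)
            if down is not None:
                emit(DOWNSTREAM, gene.gene_id, down)
            if gene.cds:
                five, three = infer_utrs(gene)
                for iv in five:
                    emit(FIVE_UTR, gene.gene_id, iv)
                for iv in three:
                    emit(THREE_UTR, gene.gene_id, iv)
        for record in plain:
            up, down = make_vicinity(
                record.interval,
                vicinity_size,
                chrom_lengths.get(record.interval.chrom),
            )
            pid = primary_feature_id(record)
            if up is not None:
                emit(UPSTREAM, pid, up)
            if down is not None:
                emit(DOWNSTREAM, pid, down)

    features.sort(
        key=lambda f: (
            f.interval.chrom,
            f.interval.start,
            f.interval.end,
            f.class_label,
            f.feature_id,
        )
    )
    return features
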