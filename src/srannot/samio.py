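"""SAM/BAM input: rebuild the complete hit set of each read.

Mappers report multi-mapping reads in two dialects: one record per hit with
the NH tag giving the hit count (bowtie-style output lacks NH, hence the
companion re-tagger), or a single primary record whose XA tag lists the
alternative hits (BWA).  Both are normalised here into one
:class:`ReadAlignmentSet` per read holding all n hits.

Only single-end data is supported; records of one read must be consecutive
in the file (true for the direct output of the common sRNA mappers).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterator

import pysam

from .annotation import GenomicInterval

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")
_QUERY_CONSUMING = set("MIS=X")


class SamFormatError(ValueError):
    pass


class NonConsecutiveReadsError(SamFormatError):
    """Records of one read are interleaved with another read's records."""


@dataclass(frozen=True)
class Hit:
    """One genomic alignment location of a read."""

    interval: GenomicInterval
    read_strand: str
    from_xa: bool = False


@dataclass
class ReadAlignmentSet:
    """A read together with all n of its hits."""

    read_id: str
    read_length: int
    hits: list[Hit]

    @property
    def n(self) -> int:
        return len(self.hits)


def cigar_reference_length(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M/D/N/=/X)."""
    if cigar == "*":
        raise SamFormatError("cannot compute reference length of CIGAR '*'")
    length = 0
    parsed = 0
    for m in _CIGAR_RE.finditer(cigar):
        parsed += len(m.group(0))
        if m.group(2) in _REF_CONSUMING:
            length += int(m.group(1))
    if parsed != len(cigar):
        raise SamFormatError(f"malformed CIGAR {cigar!r}")
    return length


def cigar_query_length(cigar: str) -> int:
    """Query bases consumed by a CIGAR string (M/I/S/=/X)."""
    length = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.group(2) in _QUERY_CONSUMING:
            length += int(m.group(1))
    return length


def _parse_xa(xa: str) -> list[Hit]:
    """Expand a BWA XA tag: ``chr,(+|-)pos,CIGAR,NM;`` repeated."""
    hits = []
    for entry in xa.rstrip(";").split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        if len(parts) != 4:
            raise SamFormatError(f"malformed XA entry {entry!r}")
        chrom, signed_pos, cigar, _nm = parts
        strand, pos = signed_pos[0], int(signed_pos[1:])
        if strand not in "+-":
            raise SamFormatError(f"malformed XA position {signed_pos!r}")
        end = pos + cigar_reference_length(cigar) - 1
        hits.append(
            Hit(
                interval=GenomicInterval(chrom, pos, end, strand),
                read_strand=strand,
                from_xa=True,
            )
        )
    return hits


def _record_to_hit(rec: pysam.AlignedSegment) -> Hit:
    strand = "-" if rec.is_reverse else "+"
    start = rec.reference_start + 1  # pysam is 0-based
    end = rec.reference_end  # 0-based exclusive == 1-based inclusive
    return Hit(
        interval=GenomicInterval(rec.reference_name, start, end, strand),
        read_strand=strand,
    )


def _read_length(records: list[pysam.AlignedSegment]) -> int:
    for rec in records:
        if rec.query_sequence:
            return len(rec.query_sequence)
    for rec in records:
        if rec.cigarstring:
            return cigar_query_length(rec.cigarstring)
    raise SamFormatError(
        f"read {records[0].query_name!r}: cannot determine read length "
        "(no SEQ, no CIGAR)"
    )


def _finish_group(qname: str, records: list[pysam.AlignedSegment]) -> ReadAlignmentSet | None:
    if not records:
        return None
    hits: list[Hit] = []
    nh_declared = None
    for rec in records:
        hits.append(_record_to_hit(rec))
        if rec.has_tag("XA"):
            hits.extend(_parse_xa(rec.get_tag("XA")))
        if nh_declared is None and rec.has_tag("NH"):
            nh_declared = rec.get_tag("NH")
    if nh_declared is not None and nh_declared != len(hits):
        warnings.warn(
            f"read {qname!r}: NH tag declares {nh_declared} hits but "
            f"{len(hits)} are present; using the observed hits",
            stacklevel=3,
        )
    return ReadAlignmentSet(
        read_id=qname, read_length=_read_length(records), hits=hits
    )


def read_alignment_sets(path) -> Iterator[ReadAlignmentSet]:
    """Stream one :class:`ReadAlignmentSet` per read from a SAM/BAM file.

    Unmapped (0x4) and supplementary (0x800) records are skipped; secondary
    records (0x100) count as hits; XA tags are expanded.  Paired-end records
    and non-consecutive read groups raise errors.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        current: str | None = None
        group: list[pysam.AlignedSegment] = []
        seen: set[str] = set()
        for rec in af.fetch(until_eof=True):
            if rec.is_paired:
                raise SamFormatError(
                    f"read {rec.query_name!r} is paired-end; only single-end "
                    "sRNA-seq input is supported"
                )
            if rec.is_unmapped or rec.is_supplementary:
                continue
            qname = rec.query_name
            if qname != current:
                if qname in seen:
                    raise NonConsecutiveReadsError(
                        f"records of read {qname!r} are not consecutive; "
                        "group the file by read name (e.g. samtools sort -n) "
                        "or run the NH re-tagging companion first"
                    )
                result = _finish_group(current, group)
                if result is not None:
                    yield result
                if current is not None:
                    seen.add(current)
                current, group = qname, []
            group.append(rec)
        result = _finish_group(current, group)
        if result is not None:
            yield result


# --- NH companion tool (bowtie emits one record per hit without NH) --------

_FLAG_UNMAPPED = 0x4
_FLAG_PAIRED = 0x1


def _tag_group(lines: list[str], out) -> None:
    mapped = [ln for ln in lines if not int(ln.split("\t", 2)[1]) & _FLAG_UNMAPPED]
    count = len(mapped)
    for line in lines:
        fields = line.rstrip("\n").split("\t")
        if int(fields[1]) & _FLAG_UNMAPPED:
            out.write(line if line.endswith("\n") else line + "\n")
            continue
        replaced = False
        for i in range(11, len(fields)):
            if fields[i].startswith("NH:i:"):
                fields[i] = f"NH:i:{count}"
                replaced = True
                break
        if not replaced:
            fields.append(f"NH:i:{count}")
        out.write("\t".join(fields) + "\n")


def set_nh_tags(sam_in, sam_out) -> dict[str, int]:
    """Add/refresh ``NH:i:<hit count>`` on every mapped record of a SAM text
    stream whose records are grouped by read name; all other fields and the
    header pass through byte-identical.  Idempotent.  Returns the per-read
    mapped-record counts."""

    def _run(fin, fout) -> dict[str, int]:
        counts: dict[str, int] = {}
        current: str | None = None
        group: list[str] = []

        def flush() -> None:
            if current is None:
                return
            counts[current] = sum(
                1 for ln in group if not int(ln.split("\t", 2)[1]) & _FLAG_UNMAPPED
            )
            _tag_group(group, fout)

        for line in fin:
            if line.startswith("@"):
                fout.write(line)
                continue
            qname, flag_s = line.split("\t", 2)[:2]
            if int(flag_s) & _FLAG_PAIRED:
                raise SamFormatError(
                    f"read {qname!r} is paired-end; only single-end input "
                    "is supported"
                )
            if qname != current:
                if qname in counts:
                    raise NonConsecutiveReadsError(
                        f"records of read {qname!r} are not consecutive; "
                        "group the file by read name first"
                    )
                flush()
                current, group = qname, []
            group.append(line)
        flush()
        return counts

    close_in = close_out = None
    fin, fout = sam_in, sam_out
    if isinstance(sam_in, (str, bytes)) or hasattr(sam_in, "__fspath__"):
        fin = close_in = open(sam_in)
    if isinstance(sam_out, (str, bytes)) or hasattr(sam_out, "__fspath__"):
        fout = close_out = open(sam_out, "w")
    try:
        return _run(fin, fout)
    finally:
        if close_in:
            close_in.close()
        if close_out:
            close_out.close()
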