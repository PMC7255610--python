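"""Synthetic inputs: a worked-example scenario and ground-truth simulations.

``worked_example`` builds a miniature genome — one plus-strand coding gene
(two exons, CDS, hence UTRs, an intron and ±3 kb vicinity regions) and five
miRNA loci — together with seven reads A–G exercising every resolution path:
unique, antisense, priority filtering, rescue across duplicated loci, rescue
via an intergenic hit, and two flavours of irreducible ambiguity.

``simulate_dataset`` emulates an sRNA-seq library over a toy genome with
several annotation classes, a configurable share of loci duplicated verbatim
(so their reads multi-map to every copy), and intergenic background reads.
Reads map perfectly (no mismatches): the annotation method is
mapping-agnostic, so sequencing-error models are deliberately absent.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .annotator import UNANNOTATED, ReadAnnotation

_QUALIFIER_SUFFIXES = (" (+)", " (-)")


def _seq(length: int) -> str:
    return ("ACGT" * (length // 4 + 1))[:length]


def _sam_line(
    qname: str,
    flag: int,
    chrom: str,
    pos: int,
    cigar: str,
    seq: str,
    tags: Iterable[str] = (),
) -> str:
    fields = [
        qname,
        str(flag),
        chrom,
        str(pos),
        "255",
        cigar,
        "*",
        "0",
        "0",
        seq,
        "I" * len(seq),
        *tags,
    ]
    return "\t".join(fields)


# ---------------------------------------------------------------------------
# Worked example: one coding gene, five miRNAs, seven reads
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_CONFIG = """\
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
"""


@dataclass(frozen=True)
class WorkedExample:
    gtf_text: str
    config_text: str
    sam_text: str
    #: read_id -> (expected label, expected status)
    expected: Mapping[str, tuple[str, str]]


def worked_example() -> WorkedExample:
    """The worked example: concrete coordinates realising the narrative.

    Gene ``gene1`` (+): exons 1001-3000 and 4001-6000, CDS 1501-3000 and
    4001-5500, so 5'UTR = 1001-1500, 3'UTR = 5501-6000, intron = 3001-4000,
    upstream = 1-1000, downstream = 6001-9000 (±3 kb, clipped at 1).  Five
    miRNAs: one inside the CDS, one inside the intron, a duplicated pair far
    downstream, and one isolated copy.  Reads (20 nt, + strand unless noted):

    - A 501:  upstream only → unique
    - B 1601 (−): antisense over the CDS → gene (-) via the antisense rule
    - C 3203: miRNA inside the intron → miRNA by priority
    - D 20002 / 30002: both hits on the duplicated miRNA pair → rescued
    - E 2002: CDS and miRNA at one locus, same tier → merged, ambiguous
    - F 5601 / 40002: 3'UTR vs miRNA across hits → merged, ambiguous
    - G 1101 / 50001: 5'UTR vs intergenic → rescued
    """
    gtf_rows = [
        ("gene", 1001, 6000, "gene1"),
        ("exon", 1001, 3000, "gene1"),
        ("exon", 4001, 6000, "gene1"),
        ("CDS", 1501, 3000, "gene1"),
        ("CDS", 4001, 5500, "gene1"),
        ("miRNA", 2001, 2021, "mirE"),
        ("miRNA", 3201, 3220, "mirC"),
        ("miRNA", 20001, 20021, "mirD1"),
        ("miRNA", 30001, 30021, "mirD2"),
        ("miRNA", 40001, 40021, "mirF"),
    ]
    gtf_text = (
        "\n".join(
            "\t".join(
                ["chr1", "test", feat, str(s), str(e), ".", "+", ".",
                 f'gene_id "{gid}";']
            )
            for feat, s, e, gid in gtf_rows
        )
        + "\n"
    )
    seq = _seq(20)
    sam_rows = [
        ("A", 0, 501, 1),
        ("B", 16, 1601, 1),
        ("C", 0, 3203, 1),
        ("D", 0, 20002, 2),
        ("D", 256, 30002, 2),
        ("E", 0, 2002, 1),
        ("F", 0, 5601, 2),
        ("F", 256, 40002, 2),
        ("G", 0, 1101, 2),
        ("G", 256, 50001, 2),
    ]
    sam_text = (
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:60000\n"
        + "\n".join(
            _sam_line(q, f, "chr1", p, "20M", seq, [f"NH:i:{nh}"])
            for q, f, p, nh in sam_rows
        )
        + "\n"
    )
    expected = {
        "A": ("upstream", "unique"),
        "B": ("gene (-)", "unique"),
        "C": ("miRNA", "unique"),
        "D": ("miRNA", "rescued"),
        "E": ("CDS (+)--miRNA", "ambiguous"),
        "F": ("3'UTR (+)--miRNA", "ambiguous"),
        "G": ("5'UTR", "rescued"),
    }
    return WorkedExample(gtf_text, WORKED_EXAMPLE_CONFIG, sam_text, expected)


# ---------------------------------------------------------------------------
# Parameterised simulation with ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthEntry:
    true_class: str | None  # None = intergenic read
    true_feature: str | None
    n_hits: int


@dataclass
class SimulatedDataset:
    gtf_text: str
    sam_text: str
    config_text: str
    truth: dict[str, TruthEntry] = field(default_factory=dict)
    chrom_length: int = 0


def simulation_config_text(classes: Iterable[str]) -> str:
    """One Order tier per class, highest priority first; no derived classes."""
    return "Order:\n" + "\n".join(classes) + "\n"


def simulate_dataset(
    n_reads: int = 10_000,
    classes: tuple[str, ...] = ("miRNA", "snoRNA", "tRNA", "piRNA"),
    loci_per_class: int = 25,
    duplicated_fraction: float = 0.3,
    n_duplicated_loci: int | None = None,
    dup_copies: tuple[int, ...] = (2, 3),
    locus_length: int = 100,
    read_length: int = 21,
    intergenic_fraction: float = 0.1,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate an sRNA library over a toy genome with duplicated loci.

    Loci of each class are laid out non-overlapping on one chromosome with
    2 kb spacing; a chosen subset of loci is duplicated verbatim into 2-3
    copies, so every read drawn from such a locus has one hit per copy (with
    a correct NH tag).  A fraction of reads comes from a reserved intergenic
    zone overlapping no locus.  Defaults model a desk-scale sRNA library:
    21 nt reads, four sRNA classes, 30% of loci duplicated, 10% intergenic
    background.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if read_length > locus_length:
        raise ValueError("read_length must not exceed locus_length")
    rng = random.Random(seed)
    chrom = "chrS"
    gap = 2000

    # lay out locus groups (a group = one origin locus and its copies)
    n_groups = len(classes) * loci_per_class
    if n_duplicated_loci is None:
        n_duplicated_loci = round(duplicated_fraction * n_groups)
    dup_groups = set(rng.sample(range(n_groups), n_duplicated_loci))

    groups: list[tuple[str, list[str], list[int]]] = []
    cursor = 1 + gap
    gtf_lines: list[str] = []
    gi = 0
    for cls in classes:
        for li in range(loci_per_class):
            k = rng.choice(dup_copies) if gi in dup_groups else 1
            ids, starts = [], []
            for ci in range(k):
                fid = f"{cls}_{li}" if k == 1 else f"{cls}_{li}_copy{ci}"
                ids.append(fid)
                starts.append(cursor)
                gtf_lines.append(
                    "\t".join(
                        [
                            chrom,
                            "sim",
                            cls,
                            str(cursor),
                            str(cursor + locus_length - 1),
                            ".",
                            "+",
                            ".",
                            f'gene_id "{fid}";',
                        ]
                    )
                )
                cursor += locus_length + gap
            groups.append((cls, ids, starts))
            gi += 1

    intergenic_start = cursor + 10_000
    intergenic_len = 50_000
    chrom_length = intergenic_start + intergenic_len + gap

    seq = _seq(read_length)
    sam_lines = [
        "@HD\tVN:1.6",
        f"@SQ\tSN:{chrom}\tLN:{chrom_length}",
    ]
    truth: dict[str, TruthEntry] = {}
    max_offset = locus_length - read_length
    for ri in range(n_reads):
        read_id = f"read{ri:06d}"
        if rng.random() < intergenic_fraction:
            pos = intergenic_start + rng.randrange(intergenic_len - read_length)
            sam_lines.append(
                _sam_line(read_id, 0, chrom, pos, f"{read_length}M", seq, ["NH:i:1"])
            )
            truth[read_id] = TruthEntry(None, None, 1)
            continue
        cls, ids, starts = groups[rng.randrange(n_groups)]
        offset = rng.randrange(max_offset + 1)
        origin = rng.randrange(len(ids))
        k = len(ids)
        for ci, start in enumerate(starts):
            flag = 0 if ci == 0 else 256
            sam_lines.append(
                _sam_line(
                    read_id,
                    flag,
                    chrom,
                    start + offset,
                    f"{read_length}M",
                    seq,
                    [f"NH:i:{k}"],
                )
            )
        truth[read_id] = TruthEntry(cls, ids[origin], k)

    return SimulatedDataset(
        gtf_text="\n".join(gtf_lines) + "\n",
        sam_text="\n".join(sam_lines) + "\n",
        config_text=simulation_config_text(classes),
        truth=truth,
        chrom_length=chrom_length,
    )


def truth_to_tsv(truth: Mapping[str, TruthEntry]) -> str:
    lines = ["read\tclass\tfeature\tn_hits"]
    for read_id in sorted(truth):
        t = truth[read_id]
        lines.append(
            "\t".join(
                [read_id, t.true_class or ".", t.true_feature or ".", str(t.n_hits)]
            )
        )
    return "\n".join(lines) + "\n"


def truth_from_tsv(text: str) -> dict[str, TruthEntry]:
    truth = {}
    for line in text.splitlines()[1:]:
        read_id, cls, feat, n = line.split("\t")
        truth[read_id] = TruthEntry(
            None if cls == "." else cls, None if feat == "." else feat, int(n)
        )
    return truth


def label_classes(label: str) -> set[str]:
    """Base class names in a (possibly merged) label, qualifiers stripped."""
    out = set()
    for part in label.split("--"):
        for suffix in _QUALIFIER_SUFFIXES:
            if part.endswith(suffix):
                part = part[: -len(suffix)]
                break
        out.add(part)
    return out


def score_against_truth(
    read_annotations: Iterable[ReadAnnotation] | Mapping[str, ReadAnnotation],
    truth: Mapping[str, TruthEntry],
) -> tuple[int, int, int]:
    """Count (TP, FP, FN) against ground truth.

    A read is a true positive when its true class is among the classes named
    by its (possibly merged) label; a false positive when it is annotated but
    its true class is absent; a false negative when it is unannotated while
    the truth names a class.
    """
    if not isinstance(read_annotations, Mapping):
        read_annotations = {ra.read_id: ra for ra in read_annotations}
    if set(read_annotations) != set(truth):
        only_a = set(read_annotations) - set(truth)
        only_t = set(truth) - set(read_annotations)
        raise ValueError(
            f"read universes differ: {len(only_a)} only in annotations, "
            f"{len(only_t)} only in truth"
        )
    tp = fp = fn = 0
    for read_id, ra in read_annotations.items():
        t = truth[read_id]
        if ra.label == UNANNOTATED:
            if t.true_class is not None:
                fn += 1
            continue
        if t.true_class is not None and t.true_class in label_classes(ra.label):
            tp += 1
        else:
            fp += 1
    return tp, fp, fn
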