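"""Accumulation of per-read contributions into count tables and summaries.

Three outputs mirror the three levels of detail a user may want: the class
count table (including merged-annotation categories), the per-feature table
keyed by single feature ids or sorted id combinations (so duplicated loci and
suspicious class overlaps can be inspected), and the per-read annotation
table for manual review of the reads behind any merged category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .annotator import (
    DISCARDED,
    STATUS_AMBIGUOUS,
    STATUS_DISCARDED,
    STATUS_RESCUED,
    STATUS_UNANNOTATED,
    UNANNOTATED,
    Contribution,
    ReadAnnotation,
)

_WEIGHT_TOL = 1e-6


@dataclass
class CountTable:
    """Per-label weights for one input file."""

    counts: dict[str, float] = field(default_factory=dict)
    rescued_count: float = 0.0

    def add(self, label: str, weight: float) -> None:
        self.counts[label] = self.counts.get(label, 0.0) + weight

    def total(self) -> float:
        return sum(self.counts.values())

    def merge(self, other: "CountTable") -> "CountTable":
        out = CountTable(dict(self.counts), self.rescued_count + other.rescued_count)
        for label, w in other.counts.items():
            out.add(label, w)
        return out


@dataclass
class FeatureCountTable:
    """Weights per canonical feature-id combination (sorted tuple)."""

    counts: dict[tuple[str, ...], float] = field(default_factory=dict)

    def add(self, feature_ids: Iterable[str], weight: float) -> None:
        key = tuple(sorted(set(feature_ids)))
        if not key:
            return
        self.counts[key] = self.counts.get(key, 0.0) + weight

    def merge(self, other: "FeatureCountTable") -> "FeatureCountTable":
        out = FeatureCountTable(dict(self.counts))
        for key, w in other.counts.items():
            out.counts[key] = out.counts.get(key, 0.0) + w
        return out


@dataclass
class SummaryStats:
    reads_seen: int = 0
    reads_annotated: float = 0.0
    reads_rescued: float = 0.0
    reads_ambiguous: float = 0.0
    reads_unannotated: float = 0.0
    reads_discarded: float = 0.0

    @property
    def annotation_rate(self) -> float:
        return self.reads_annotated / self.reads_seen if self.reads_seen else 0.0

    def merge(self, other: "SummaryStats") -> "SummaryStats":
        return SummaryStats(
            self.reads_seen + other.reads_seen,
            self.reads_annotated + other.reads_annotated,
            self.reads_rescued + other.reads_rescued,
            self.reads_ambiguous + other.reads_ambiguous,
            self.reads_unannotated + other.reads_unannotated,
            self.reads_discarded + other.reads_discarded,
        )

    def as_text(self, name: str = "") -> str:
        lines = [
            f"summary{f' [{name}]' if name else ''}:",
            f"  reads seen        {self.reads_seen}",
            f"  reads annotated   {self.reads_annotated:g}",
            f"  reads rescued     {self.reads_rescued:g}",
            f"  reads ambiguous   {self.reads_ambiguous:g}",
            f"  reads unannotated {self.reads_unannotated:g}",
            f"  reads discarded   {self.reads_discarded:g}",
            f"  annotation rate   {self.annotation_rate:.4f}",
        ]
        return "\n".join(lines)


def accumulate(
    read_results: Iterable[tuple[str, list[Contribution]]],
) -> tuple[CountTable, FeatureCountTable, SummaryStats]:
    """Fold per-read contributions into the three result objects.

    Totals are deterministic and independent of read order.  Per-read weight
    conservation (sum of contribution weights == 1) is asserted for every
    read, and the per-file total is checked against the read count.
    """
    table = CountTable()
    features = FeatureCountTable()
    stats = SummaryStats()
    for read_id, contribs in read_results:
        stats.reads_seen += 1
        total = sum(c.weight for c in contribs)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise AssertionError(
                f"read {read_id!r}: contribution weights sum to {total}, not 1"
            )
        for c in contribs:
            table.add(c.label, c.weight)
            if c.status == STATUS_UNANNOTATED:
                stats.reads_unannotated += c.weight
            elif c.status == STATUS_DISCARDED:
                stats.reads_discarded += c.weight
            else:
                stats.reads_annotated += c.weight
                if c.status == STATUS_RESCUED:
                    stats.reads_rescued += c.weight
                    table.rescued_count += c.weight
                elif c.status == STATUS_AMBIGUOUS:
                    stats.reads_ambiguous += c.weight
                features.add(c.features, c.weight)
    if abs(table.total() - stats.reads_seen) > _WEIGHT_TOL * max(1, stats.reads_seen):
        raise AssertionError(
            f"count table total {table.total()} != reads seen {stats.reads_seen}"
        )
    return table, features, stats


def _format_weight(w: float) -> str:
    if abs(w - round(w)) < _WEIGHT_TOL:
        return str(int(round(w)))
    return f"{w:.6f}"


def counts_frame(tables: dict[str, CountTable]) -> pd.DataFrame:
    """Label x file DataFrame; class labels sorted, bookkeeping rows last."""
    labels = sorted(
        {lab for t in tables.values() for lab in t.counts},
        key=lambda lab: (lab in (UNANNOTATED, DISCARDED), lab),
    )
    data = {
        name: [t.counts.get(lab, 0.0) for lab in labels]
        for name, t in tables.items()
    }
    return pd.DataFrame(data, index=pd.Index(labels, name="annotation"))


def write_counts(tables: dict[str, CountTable], path) -> None:
    frame = counts_frame(tables)
    with open(path, "w") as fh:
        fh.write("annotation\t" + "\t".join(frame.columns) + "\n")
        for label, row in frame.iterrows():
            fh.write(label + "\t" + "\t".join(_format_weight(w) for w in row) + "\n")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_feature_counts(table: FeatureCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("features\tcount\n")
        for key in sorted(table.counts):
            fh.write(";".join(key) + "\t" + _format_weight(table.counts[key]) + "\n")


def read_feature_counts(path) -> FeatureCountTable:
    table = FeatureCountTable()
    frame = pd.read_csv(path, sep="\t", dtype={"features": str})
    for _, row in frame.iterrows():
        table.add(str(row["features"]).split(";"), float(row["count"]))
    return table


def write_read_annotations(annotations: Iterable[ReadAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tstatus\tannotation\tfeatures\n")
        for ra in sorted(annotations, key=lambda r: r.read_id):
            fh.write(
                "\t".join(
                    [ra.read_id, ra.status, ra.label, ";".join(sorted(ra.features))]
                )
                + "\n"
            )
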