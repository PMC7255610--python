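"""Binned genomic interval index for read-hit vs annotation overlap queries.

Features are registered in fixed-width bins per chromosome; a query touches
only the bins its interval spans, so lookup cost tracks local annotation
density rather than genome-wide feature count.  Bin k covers the 1-based
closed range [k*w + 1, (k+1)*w].
"""

from __future__ import annotations

import math
from collections import defaultdict

from .annotation import AnnotationFeature, GenomicInterval

DEFAULT_BIN_WIDTH = 16384


class BinnedIndex:
    """Per-chromosome binned lists of annotation features."""

    def __init__(self, bin_width: int = DEFAULT_BIN_WIDTH) -> None:
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.bin_width = bin_width
        self.bins: dict[str, dict[int, list[AnnotationFeature]]] = defaultdict(
            lambda: defaultdict(list)
        )

    def _bin(self, pos: int) -> int:
        return (pos - 1) // self.bin_width

    def add(self, feature: AnnotationFeature) -> None:
        iv = feature.interval
        chrom_bins = self.bins[iv.chrom]
        for b in range(self._bin(iv.start), self._bin(iv.end) + 1):
            chrom_bins[b].append(feature)

    def query(self, interval: GenomicInterval) -> list[tuple[AnnotationFeature, int]]:
        """All features overlapping ``interval`` by >= 1 nt, each once, with
        the overlap length.  Strand is not filtered here — orientation is a
        class-level rule applied by the annotator.  Unknown chromosome yields
        an empty result."""
        if interval.chrom not in self.bins:
            return []
        chrom_bins = self.bins[interval.chrom]
        seen: dict[int, tuple[AnnotationFeature, int]] = {}
        for b in range(self._bin(interval.start), self._bin(interval.end) + 1):
            for feature in chrom_bins.get(b, ()):
                key = id(feature)
                if key in seen:
                    continue
                ov = interval.overlap_length(feature.interval)
                if ov >= 1:
                    seen[key] = (feature, ov)
        return list(seen.values())


def build_index(features, bin_width: int = DEFAULT_BIN_WIDTH) -> BinnedIndex:
    index = BinnedIndex(bin_width=bin_width)
    for feature in features:
        index.add(feature)
    return index


def query_overlaps(
    index: BinnedIndex, interval: GenomicInterval
) -> list[tuple[AnnotationFeature, int]]:
    return index.query(interval)


def overlap_passes(
    overlap_length: int, read_length: int, threshold: int | float
) -> bool:
    """Minimum-overlap filter.

    An integer threshold is in nucleotides; a float in (0, 1] is a fraction
    of the read length, compared against ``ceil(p * read_length)``.  Equality
    passes (only overlaps strictly below the threshold are discarded); a zero
    overlap never passes.
    """
    if overlap_length <= 0:
        return False
    if isinstance(threshold, float):
        if not 0 < threshold <= 1:
            raise ValueError(f"fractional threshold out of range: {threshold}")
        return overlap_length >= math.ceil(threshold * read_length)
    return overlap_length >= threshold
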