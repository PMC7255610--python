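"""Core read annotation: hit-level class matching and read-level resolution.

Annotation proceeds in two steps.  First, each hit of a read is matched
against the annotation set: of all overlapping features that pass the
minimum-overlap and strand-orientation rules, only those on the highest
priority tier are kept — a hit matching several classes on one tier is
already ambiguous.  Second, the read is resolved from its hits: intergenic
(orphan) hits are ignored unless every hit is orphan; the surviving matches
are pooled, again keeping only the highest tier; a single remaining class
annotates the read (status *unique* for single-mapping reads, *rescued* for
multi-mapping reads whose ambiguity dissolved), while several remaining
classes produce a *merged annotation* — the concatenation of the tied class
labels — counted as its own category.

Four counting strategies are provided.  ``default`` is the method above;
``unique`` discards every multi-mapping read; ``random`` places each read on
one of its n hits chosen uniformly; ``ratio`` spreads 1/n over the n hits,
losing the weight of intergenic hits.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import Config, orientation_ok
from .index import BinnedIndex, overlap_passes, query_overlaps
from .samio import Hit, ReadAlignmentSet

MERGE_SEPARATOR = "--"
UNANNOTATED = "unannotated"
DISCARDED = "multi-mapping (discarded)"

STRATEGIES = ("default", "unique", "random", "ratio")

STATUS_UNIQUE = "unique"
STATUS_RESCUED = "rescued"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNANNOTATED = "unannotated"
STATUS_DISCARDED = "discarded"


@dataclass(frozen=True)
class HitAnnotation:
    """Matches of one hit at its best priority tier (None = intergenic)."""

    tier: int | None
    matches: frozenset  # of (class_label, feature_id); empty iff intergenic

    @property
    def is_intergenic(self) -> bool:
        return self.tier is None

    @property
    def labels(self) -> set[str]:
        return {label for label, _ in self.matches}


@dataclass(frozen=True)
class ReadAnnotation:
    """The resolved annotation of one read."""

    read_id: str
    label: str
    status: str
    features: frozenset  # feature_ids supporting the label


def annotate_hit(
    hit: Hit,
    read_length: int,
    index: BinnedIndex,
    config: Config,
) -> HitAnnotation:
    """Match one hit against the annotation set, keeping only the matching
    classes on the highest (minimal) priority tier."""
    best_tier: int | None = None
    matches: set[tuple[str, str]] = set()
    for feature, overlap in query_overlaps(index, hit.interval):
        spec = feature.spec
        if spec is None:
            continue
        if not overlap_passes(overlap, read_length, config.overlap_threshold):
            continue
        if not orientation_ok(spec, hit.read_strand, feature.interval.strand):
            continue
        if best_tier is None or spec.tier < best_tier:
            best_tier = spec.tier
            matches = {(spec.label, feature.feature_id)}
        elif spec.tier == best_tier:
            matches.add((spec.label, feature.feature_id))
    return HitAnnotation(tier=best_tier, matches=frozenset(matches))


def merge_label(class_labels: Iterable[str], config: Config | None = None) -> str:
    """Canonical merged-annotation label: class labels sorted by (tier,
    lexicographic) and joined with ``--``; independent of input order."""
    labels = set(class_labels)

    def key(label: str):
        tier = config.tier_of_label(label) if config is not None else None
        return (tier if tier is not None else -1, label)

    return MERGE_SEPARATOR.join(sorted(labels, key=key))


def resolve_read(
    read_set: ReadAlignmentSet,
    hit_annotations: Sequence[HitAnnotation],
    config: Config | None = None,
) -> ReadAnnotation:
    """Resolve a read from the per-hit annotations (the general method)."""
    informative = [ha for ha in hit_annotations if not ha.is_intergenic]
    if not informative:
        return ReadAnnotation(
            read_set.read_id, UNANNOTATED, STATUS_UNANNOTATED, frozenset()
        )
    best = min(ha.tier for ha in informative)
    pooled = frozenset().union(
        *(ha.matches for ha in informative if ha.tier == best)
    )
    labels = {label for label, _ in pooled}
    features = frozenset(fid for _, fid in pooled)
    if len(labels) == 1:
        status = STATUS_UNIQUE if read_set.n == 1 else STATUS_RESCUED
        return ReadAnnotation(read_set.read_id, labels.pop(), status, features)
    return ReadAnnotation(
        read_set.read_id, merge_label(labels, config), STATUS_AMBIGUOUS, features
    )


@dataclass(frozen=True)
class Contribution:
    """One weighted increment toward the count tables."""

    label: str
    weight: float
    status: str
    features: frozenset


def _resolve_single_hit(
    read_set: ReadAlignmentSet, ha: HitAnnotation, config: Config | None
) -> ReadAnnotation:
    one = ReadAlignmentSet(read_set.read_id, read_set.read_length, read_set.hits[:1])
    return resolve_read(one, [ha], config)


def apply_strategy(
    strategy: str,
    read_set: ReadAlignmentSet,
    hit_annotations: Sequence[HitAnnotation],
    config: Config | None = None,
    rng: random.Random | None = None,
) -> list[Contribution]:
    """Turn one read into weighted count contributions under a strategy.

    Every strategy conserves a total weight of exactly 1 per read across
    class, merged, unannotated and discarded categories.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    n = read_set.n
    if strategy == "default" or (strategy == "unique" and n == 1):
        ra = resolve_read(read_set, hit_annotations, config)
        return [Contribution(ra.label, 1.0, ra.status, ra.features)]
    if strategy == "unique":
        return [Contribution(DISCARDED, 1.0, STATUS_DISCARDED, frozenset())]
    if strategy == "random":
        if rng is None:
            raise ValueError("the random strategy needs a seeded rng")
        i = rng.randrange(n)
        ra = _resolve_single_hit(read_set, hit_annotations[i], config)
        return [Contribution(ra.label, 1.0, ra.status, ra.features)]
    # ratio
    share = 1.0 / n
    out = []
    for ha in hit_annotations:
        ra = _resolve_single_hit(read_set, ha, config)
        out.append(Contribution(ra.label, share, ra.status, ra.features))
    return out


def annotate_read(
    read_set: ReadAlignmentSet,
    index: BinnedIndex,
    config: Config,
    strategy: str = "default",
    rng: random.Random | None = None,
) -> tuple[ReadAnnotation, list[Contribution]]:
    """Convenience: annotate all hits, resolve, and apply the strategy."""
    has = [
        annotate_hit(hit, read_set.read_length, index, config)
        for hit in read_set.hits
    ]
    resolved = resolve_read(read_set, has, config)
    contribs = apply_strategy(strategy, read_set, has, config, rng)
    return resolved, contribs
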