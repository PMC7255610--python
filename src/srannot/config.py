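"""Configuration file parsing: class selectors, strand rules, priority tiers.

The configuration file has three sections.  ``Introns:`` lists the classes
whose introns (gaps between merged exons) are added to the annotation set.
``Vicinity:`` lists the classes whose upstream/downstream regions — and, for
coding genes, 5'/3' UTRs — are derived.  ``Order:`` ranks the classes to be
quantified: one priority tier per line, whitespace-separated tokens on one
line share a tier.  A token is either ``source:feature`` (``.`` matches any
source) or a bare feature name; a trailing ``+`` restricts the class to reads
collinear with the annotation, a trailing ``-`` to antisense reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

COLLINEAR = "collinear"
ANTISENSE = "antisense"
ANY = "any"

#: Bare words in Order that name in-memory derived features, not GTF rows.
DERIVED_CLASSES = frozenset({"intron", "upstream", "downstream", "5'UTR", "3'UTR"})

DEFAULT_VICINITY_SIZE = 3000
DEFAULT_OVERLAP_THRESHOLD = 1  # any overlap of >= 1 nt counts


class ConfigError(ValueError):
    """Raised for malformed configuration text."""


@dataclass(frozen=True)
class ClassSpec:
    """One quantifiable annotation class: a selector plus a priority rank."""

    source_pattern: str  # '.' = any source
    feature_pattern: str
    orientation: str  # COLLINEAR | ANTISENSE | ANY
    tier: int  # 0 = highest priority

    @property
    def label(self) -> str:
        """Display label: feature name plus an orientation qualifier."""
        if self.orientation == COLLINEAR:
            return f"{self.feature_pattern} (+)"
        if self.orientation == ANTISENSE:
            return f"{self.feature_pattern} (-)"
        return self.feature_pattern

    @property
    def is_derived(self) -> bool:
        return self.feature_pattern in DERIVED_CLASSES

    def token(self) -> str:
        """Round-trippable config token."""
        base = (
            self.feature_pattern
            if self.source_pattern == "."
            else f"{self.source_pattern}:{self.feature_pattern}"
        )
        if self.orientation == COLLINEAR:
            return base + " +"
        if self.orientation == ANTISENSE:
            return base + " -"
        return base


@dataclass(frozen=True)
class Selector:
    """A source:feature selector used by the Introns and Vicinity sections."""

    source_pattern: str
    feature_pattern: str

    def token(self) -> str:
        if self.source_pattern == ".":
            return self.feature_pattern
        return f"{self.source_pattern}:{self.feature_pattern}"


@dataclass
class Config:
    intron_sources: list[Selector] = field(default_factory=list)
    vicinity_sources: list[Selector] = field(default_factory=list)
    tiers: list[list[ClassSpec]] = field(default_factory=list)
    vicinity_size: int = DEFAULT_VICINITY_SIZE
    #: int = nucleotides, float in (0, 1] = fraction of the read length
    overlap_threshold: int | float = DEFAULT_OVERLAP_THRESHOLD

    def all_specs(self) -> list[ClassSpec]:
        return [s for tier in self.tiers for s in tier]

    def spec_for_label(self, label: str) -> ClassSpec | None:
        for spec in self.all_specs():
            if spec.label == label:
                return spec
        return None

    def tier_of_label(self, label: str) -> int | None:
        spec = self.spec_for_label(label)
        return None if spec is None else spec.tier

    def reversed_tiers(self, keep_derived_last: bool = True) -> "Config":
        """A copy with the Order tiers reversed (for robustness checks).

        With ``keep_derived_last`` the tiers containing only derived classes
        (intron, vicinity, UTRs) stay at the bottom and only the primary-class
        tiers are reversed.
        """
        if keep_derived_last:
            primary = [t for t in self.tiers if not all(s.is_derived for s in t)]
            derived = [t for t in self.tiers if all(s.is_derived for s in t)]
            new_order = primary[::-1] + derived
        else:
            new_order = self.tiers[::-1]
        new_tiers = [
            [replace(s, tier=i) for s in tier] for i, tier in enumerate(new_order)
        ]
        return Config(
            intron_sources=list(self.intron_sources),
            vicinity_sources=list(self.vicinity_sources),
            tiers=new_tiers,
            vicinity_size=self.vicinity_size,
            overlap_threshold=self.overlap_threshold,
        )


def _parse_selector_token(token: str, lineno: int) -> tuple[str, str]:
    if token.count(":") > 1:
        raise ConfigError(f"line {lineno}: token {token!r} has more than one colon")
    if ":" in token:
        source, feature = token.split(":")
        if not feature:
            raise ConfigError(f"line {lineno}: empty feature in token {token!r}")
        return source or ".", feature
    return ".", token


def parse_config(text: str) -> Config:
    """Parse the three-section configuration text into a :class:`Config`.

    Raises :class:`ConfigError` on a missing/empty Order section, a token
    with more than one colon, or a class token repeated across tiers.
    """
    section = None
    intron_sources: list[Selector] = []
    vicinity_sources: list[Selector] = []
    tiers: list[list[ClassSpec]] = []
    seen_tokens: set[tuple[str, str, str]] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in ("Introns:", "Vicinity:", "Order:"):
            section = line[:-1]
            continue
        if section is None:
            raise ConfigError(f"line {lineno}: content before any section header")
        if section == "Introns":
            intron_sources.append(Selector(*_parse_selector_token(line, lineno)))
        elif section == "Vicinity":
            vicinity_sources.append(Selector(*_parse_selector_token(line, lineno)))
        else:  # Order
            tier: list[ClassSpec] = []
            tokens = line.split()
            i = 0
            while i < len(tokens):
                token = tokens[i]
                orientation = ANY
                if i + 1 < len(tokens) and tokens[i + 1] in ("+", "-"):
                    orientation = COLLINEAR if tokens[i + 1] == "+" else ANTISENSE
                    i += 1
                source, feature = _parse_selector_token(token, lineno)
                key = (source, feature, orientation)
                if key in seen_tokens:
                    raise ConfigError(
                        f"line {lineno}: class token {token!r} appears in more "
                        "than one tier"
                    )
                seen_tokens.add(key)
                tier.append(
                    ClassSpec(
                        source_pattern=source,
                        feature_pattern=feature,
                        orientation=orientation,
                        tier=len(tiers),
                    )
                )
                i += 1
            tiers.append(tier)

    if not tiers:
        raise ConfigError("configuration has no Order section (or it is empty)")
    return Config(
        intron_sources=intron_sources,
        vicinity_sources=vicinity_sources,
        tiers=tiers,
    )


def serialize_config(config: Config) -> str:
    """Inverse of :func:`parse_config` (round-trip safe)."""
    lines: list[str] = []
    if config.intron_sources:
        lines.append("Introns:")
        lines.extend(sel.token() for sel in config.intron_sources)
        lines.append("")
    if config.vicinity_sources:
        lines.append("Vicinity:")
        lines.extend(sel.token() for sel in config.vicinity_sources)
        lines.append("")
    lines.append("Order:")
    for tier in config.tiers:
        lines.append(" ".join(spec.token() for spec in tier))
    return "\n".join(lines) + "\n"


def match_selector(spec: ClassSpec | Selector, source: str, feature: str) -> bool:
    """True iff the selector matches a GTF (source, feature) pair."""
    if spec.source_pattern != "." and spec.source_pattern != source:
        return False
    return spec.feature_pattern == feature


def orientation_ok(spec: ClassSpec, read_strand: str, feature_strand: str) -> bool:
    """Apply the class's strand rule to a read/feature strand pair."""
    if spec.orientation == COLLINEAR:
        return read_strand == feature_strand
    if spec.orientation == ANTISENSE:
        return read_strand != feature_strand
    return True


def parse_threshold(text: str) -> int | float:
    """Parse an overlap threshold: ``'12nt'`` / ``'12'`` → 12, ``'50%'`` → 0.5."""
    text = text.strip()
    if text.endswith("%"):
        frac = float(text[:-1]) / 100.0
        if not 0 < frac <= 1:
            raise ConfigError(f"percentage threshold out of range: {text!r}")
        return frac
    if text.endswith("nt"):
        text = text[:-2]
    try:
        value = int(text)
    except ValueError:
        raise ConfigError(f"cannot parse overlap threshold {text!r}") from None
    if value < 0:
        raise ConfigError("overlap threshold must be >= 0")
    return value


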