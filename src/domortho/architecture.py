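"""Domain-architecture construction and homolog-group partitioning.

Stage one of the pipeline: raw profile-database hits are filtered by
E-value (< 0.01 by default), overlapping hits on a protein are flattened,
and the surviving hits — ordered N-terminus to C-terminus — define the
protein's domain architecture. Proteins sharing the exact same domain
composition *and order* form one homolog group; proteins with no
surviving domain hit are pooled into a single "uncharacterized" group.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import ProteinRecord, TabularHit

DEFAULT_EVALUE_MAX = 0.01
DEFAULT_OVERLAP_FRACTION = 0.5

_VERSION_SUFFIX_RE = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class DomainHit:
    """One profile-database hit on a protein (1-based inclusive coordinates)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"domain hit {self.domain_id} on {self.protein_id}: start > end"
            )
        if self.evalue < 0:
            raise ValueError(f"domain hit {self.domain_id} on {self.protein_id}: negative evalue")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Architecture:
    """The ordered N→C sequence of domain identifiers on a protein.

    The empty tuple is the "uncharacterized" sentinel for proteins with no
    domain hit. Equality is element-wise on the ordered tuple, so tandem
    repeats are significant: (A, A, B) != (A, B).
    """

    domains: tuple[str, ...]

    @property
    def is_uncharacterized(self) -> bool:
        return not self.domains

    @property
    def string(self) -> str:
        """The "/"-joined rendering used in the architecture map."""
        return "/".join(self.domains)


UNCHARACTERIZED = Architecture(domains=())


@dataclass(frozen=True)
class HomologGroup:
    """All proteins (across species) sharing one domain architecture.

    ``index`` is a deterministic 1-based number over the characterized
    groups of a partition (sorted by architecture string); it is the
    numeric stem used in the architecture map. The uncharacterized group
    has index 0.
    """

    architecture: Architecture
    members: frozenset[tuple[str, str]]  # (species_id, protein_id)
    index: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("homolog group cannot be empty")

    @property
    def species(self) -> set[str]:
        return {s for s, _ in self.members}


def strip_accession_version(domain_id: str) -> str:
    """Drop a trailing profile-accession version, e.g. ``PF00085.14`` → ``PF00085``."""
    return _VERSION_SUFFIX_RE.sub("", domain_id)


def tabular_to_domain_hits(hits: Iterable[TabularHit]) -> list[DomainHit]:
    """Interpret tabular rows as domain hits: query=protein, subject=profile."""
    return [
        DomainHit(
            protein_id=h.query_id,
            domain_id=strip_accession_version(h.subject_id),
            start=h.q_start,
            end=h.q_end,
            evalue=h.evalue,
            bit_score=h.bit_score,
        )
        for h in hits
    ]


def filter_hits(
    hits: Iterable[DomainHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[DomainHit]:
    """Keep hits with E-value strictly below ``evalue_max``; order preserved."""
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be positive, got {evalue_max}")
    return [h for h in hits if h.evalue < evalue_max]


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def conflicts(a: DomainHit, b: DomainHit, overlap_fraction: float) -> bool:
    """Two hits conflict when their overlap exceeds ``overlap_fraction`` of the shorter span."""
    return _overlap(a, b) > overlap_fraction * min(a.span, b.span)


def resolve_overlaps(
    hits: Sequence[DomainHit], overlap_fraction: float = DEFAULT_OVERLAP_FRACTION
) -> list[DomainHit]:
    """Greedily flatten overlapping hits on one protein.

    Hits are considered in order of ascending E-value (ties: descending
    bit score, then lexicographic domain id, then start); a hit is kept
    unless it conflicts with an already-kept hit. The result is returned
    in N→C positional order and is idempotent under re-application.
    """
    hits = list(hits)
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"resolve_overlaps expects hits of one protein, got {sorted(protein_ids)}")
    ranked = sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.domain_id, h.start, h.end))
    kept: list[DomainHit] = []
    for h in ranked:
        if not any(conflicts(h, k, overlap_fraction) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.domain_id))
    return kept


def build_architecture(hits: Sequence[DomainHit]) -> Architecture:
    """Order filtered, overlap-resolved hits N→C into an architecture.

    Sorting is by ascending start (ties: ascending end, then domain id).
    No hits yields the uncharacterized sentinel; tandem repeats of one
    domain are kept as repeats.
    """
    if not hits:
        return UNCHARACTERIZED
    ordered = sorted(hits, key=lambda h: (h.start, h.end, h.domain_id))
    return Architecture(domains=tuple(h.domain_id for h in ordered))


def architectures_from_hits(
    proteins: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> dict[str, Architecture]:
    """Run filter → overlap resolution → architecture for every protein.

    Proteins with no (surviving) hit map to the uncharacterized sentinel.
    """
    filtered = filter_hits(hits, evalue_max)
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in filtered:
        by_protein[h.protein_id].append(h)
    archs: dict[str, Architecture] = {}
    for p in proteins:
        protein_hits = by_protein.get(p.protein_id, [])
        archs[p.protein_id] = build_architecture(
            resolve_overlaps(protein_hits, overlap_fraction)
        )
    return archs


def partition_by_architecture(
    proteins: Iterable[ProteinRecord], architectures: Mapping[str, Architecture]
) -> list[HomologGroup]:
    """Partition proteins into homolog groups keyed by exact architecture.

    Every uncharacterized protein lands in one shared group (index 0);
    characterized groups are numbered 1..N sorted by architecture string.
    """
    by_arch: dict[Architecture, set[tuple[str, str]]] = defaultdict(set)
    for p in proteins:
        if p.protein_id not in architectures:
            raise ValueError(f"protein {p.protein_id!r} missing from the architecture map")
        by_arch[architectures[p.protein_id]].add((p.species_id, p.protein_id))
    groups: list[HomologGroup] = []
    characterized = sorted(
        (a for a in by_arch if not a.is_uncharacterized), key=lambda a: a.string
    )
    for i, arch in enumerate(characterized, start=1):
        groups.append(HomologGroup(architecture=arch, members=frozenset(by_arch[arch]), index=i))
    if UNCHARACTERIZED in by_arch:
        groups.append(
            HomologGroup(
                architecture=UNCHARACTERIZED,
                members=frozenset(by_arch[UNCHARACTERIZED]),
                index=0,
            )
        )
    return groups
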