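"""Within-group reciprocal-best-hit ortholog assignment.

Stage two of the pipeline. Inside each homolog group, every anchor-species
protein is compared against the group members of every other species;
a pair is reported when each side is the other's best hit within the
group (best = highest bit score, ties broken by lowest E-value, then
lexicographic protein id). Candidate groups from several anchor genomes
are merged by connected components over shared membership, which rescues
clade-specific families and families lost from one anchor genome.

The search space is deliberately the homolog group, never the whole
proteome: that restriction is the efficiency mechanism of the two-stage
design, and it also means orthologs whose reported architectures differ
(domain rearrangement, insertion, deletion) can never be paired — a known
limitation of architecture-keyed detection.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .architecture import (
    Architecture,
    DomainHit,
    HomologGroup,
    architectures_from_hits,
    partition_by_architecture,
)
from .io_formats import ProteinRecord
from .similarity import SimilarityBackend, SimilarityHit

logger = logging.getLogger(__name__)

PREFIX_DOMAIN = "PfamArcNu"
PREFIX_NO_DOMAIN = "NoDomainInfo"


@dataclass(frozen=True)
class OrthologGroup:
    """An anchor-seeded ortholog set: at most one member per species.

    ``group_id`` starts with ``PfamArcNu`` when the group descends from a
    domain-characterized homolog group and ``NoDomainInfo`` when it was
    resolved purely by RBH inside the uncharacterized pool.
    """

    anchor_protein: tuple[str, str]  # (species_id, protein_id)
    members: frozenset[tuple[str, str]]
    source_architecture: Architecture
    group_id: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_protein not in self.members:
            raise ValueError("anchor protein must be a group member")
        species = [s for s, _ in self.members]
        if len(set(species)) != len(species):
            raise ValueError("ortholog group holds two proteins of one species")

    @property
    def species(self) -> set[str]:
        return {s for s, _ in self.members}


@dataclass
class PipelineConfig:
    """Tunables for the two-stage run."""

    anchors: list[str]
    evalue_max: float = 0.01
    overlap_fraction: float = 0.5
    min_species: int = 2
    uncharacterized_cap: int | None = None

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("at least one anchor species is required")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


_WORST = (float("-inf"), float("inf"), "")


def _best(
    candidates: Iterable[str], scores: Mapping[tuple[str, str], SimilarityHit], source: str
) -> str | None:
    """Best-scoring candidate for ``source``: bit desc, evalue asc, id asc."""
    best_id: str | None = None
    best_key = None
    for c in candidates:
        hit = scores.get((source, c))
        if hit is None:
            continue
        key = (-hit.bit_score, hit.evalue, c)
        if best_key is None or key < best_key:
            best_key = key
            best_id = c
    return best_id


def within_group_rbh(
    group: HomologGroup,
    anchor_species: str,
    backend: SimilarityBackend,
    proteins: Mapping[str, ProteinRecord],
    min_species: int = 2,
    score_sink: dict[tuple[str, str], SimilarityHit] | None = None,
) -> list[OrthologGroup]:
    """Reciprocal best hits between anchor proteins and every other species.

    Returns one candidate group per anchor protein that found at least one
    reciprocal partner (groups must span ``min_species`` species). Anchor
    proteins with no partner are logged and dropped. ``score_sink``, when
    given, collects every pairwise score computed — the multi-anchor merge
    uses it to resolve species conflicts.
    """
    anchor_ids = sorted(p for s, p in group.members if s == anchor_species)
    if not anchor_ids:
        return []
    by_species: dict[str, list[str]] = defaultdict(list)
    for s, p in group.members:
        if s != anchor_species:
            by_species[s].append(p)
    if not by_species:
        return []

    anchor_recs = [proteins[p] for p in anchor_ids]
    other_recs = [proteins[p] for ps in by_species.values() for p in sorted(ps)]
    scores: dict[tuple[str, str], SimilarityHit] = {}
    for hit in backend.score_pairs(anchor_recs, other_recs):
        scores[(hit.query_id, hit.subject_id)] = hit
        scores.setdefault(
            (hit.subject_id, hit.query_id),
            SimilarityHit(hit.subject_id, hit.query_id, hit.bit_score, hit.evalue),
        )
    if score_sink is not None:
        score_sink.update(scores)

    species_of = {p: s for s, p in group.members}
    groups: list[OrthologGroup] = []
    for a in anchor_ids:
        partners: set[tuple[str, str]] = set()
        for sp in sorted(by_species):
            b = _best(by_species[sp], scores, a)
            if b is None:
                continue
            if _best(anchor_ids, scores, b) == a:
                partners.add((sp, b))
        if not partners:
            logger.debug(
                "anchor protein %s (%s) found no reciprocal partner in group %d",
                a, anchor_species, group.index,
            )
            continue
        members = frozenset(partners | {(anchor_species, a)})
        if len({s for s, _ in members}) >= min_species:
            groups.append(
                OrthologGroup(
                    anchor_protein=(anchor_species, a),
                    members=members,
                    source_architecture=group.architecture,
                )
            )
    return groups


def assign_group_ids(groups: Iterable[OrthologGroup]) -> list[OrthologGroup]:
    """Assign deterministic IDs: per-prefix counters, sorted by anchor protein id."""
    ordered = sorted(groups, key=lambda g: g.anchor_protein[1])
    counters = {PREFIX_DOMAIN: 0, PREFIX_NO_DOMAIN: 0}
    out: list[OrthologGroup] = []
    for g in ordered:
        prefix = PREFIX_NO_DOMAIN if g.source_architecture.is_uncharacterized else PREFIX_DOMAIN
        counters[prefix] += 1
        out.append(replace(g, group_id=f"{prefix}{counters[prefix]}"))
    return out


class _UnionFind:
    def __init__(self) -> None:
        self._parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        self._parent.setdefault(x, x)
        while self._parent[x] != x:
            self._parent[x] = self._parent[self._parent[x]]
            x = self._parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[max(ra, rb)] = min(ra, rb)


def merge_anchor_groups(
    groups: Sequence[OrthologGroup],
    scores: Mapping[tuple[str, str], SimilarityHit],
    min_species: int = 2,
) -> list[OrthologGroup]:
    """Merge candidate groups from several anchors by shared membership.

    Connected components are taken over shared proteins. If a merged
    component would carry two proteins of one species, the one with the
    higher summed bit score against the component's anchor proteins wins
    (ties: lexicographic protein id); the conflict is logged. The merged
    group keeps the lexicographically smallest anchor protein as its seed.
    """
    if not groups:
        return []
    uf = _UnionFind()
    by_member: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, g in enumerate(groups):
        for m in g.members:
            by_member[m].append(i)
    for idxs in by_member.values():
        for j in idxs[1:]:
            uf.union(idxs[0], j)

    components: dict[int, list[OrthologGroup]] = defaultdict(list)
    for i, g in enumerate(groups):
        components[uf.find(i)].append(g)

    merged: list[OrthologGroup] = []
    for comp in components.values():
        anchors = sorted({g.anchor_protein for g in comp}, key=lambda ap: ap[1])
        all_members: set[tuple[str, str]] = set()
        for g in comp:
            all_members |= g.members
        by_species: dict[str, list[str]] = defaultdict(list)
        for s, p in all_members:
            by_species[s].append(p)
        resolved: set[tuple[str, str]] = set()
        for s, pids in by_species.items():
            if len(pids) == 1:
                resolved.add((s, pids[0]))
                continue

            def anchor_support(pid: str) -> float:
                return sum(
                    scores[(pid, ap)].bit_score
                    for _, ap in anchors
                    if (pid, ap) in scores and ap != pid
                )

            winner = sorted(pids, key=lambda p: (-anchor_support(p), p))[0]
            logger.warning(
                "multi-anchor merge: species %s contributes %d proteins to one "
                "component; keeping %s", s, len(pids), winner,
            )
            resolved.add((s, winner))
        seed = next(
            (ap for ap in anchors if ap in resolved),
            min(resolved, key=lambda m: m[1]),
        )
        if len({s for s, _ in resolved}) >= min_species:
            merged.append(
                OrthologGroup(
                    anchor_protein=seed,
                    members=frozenset(resolved),
                    source_architecture=comp[0].source_architecture,
                )
            )
    return merged


def run_pipeline(
    proteomes: Sequence[ProteinRecord],
    domain_hits: Sequence[DomainHit],
    backend: SimilarityBackend,
    config: PipelineConfig,
) -> tuple[list[OrthologGroup], list[HomologGroup]]:
    """Execute the full two-stage pipeline.

    Stage 1: E-value filter → overlap resolution → architecture →
    homolog-group partition (uncharacterized proteins pooled). Stage 2:
    within-group RBH per anchor species, multi-anchor merge, deterministic
    ID assignment. Returns the labelled ortholog groups and the underlying
    homolog partition.
    """
    species_labels = {p.species_id for p in proteomes}
    unknown = [a for a in config.anchors if a not in species_labels]
    if unknown:
        raise ValueError(f"anchor species not present in the input proteomes: {unknown}")

    archs = architectures_from_hits(
        proteomes, domain_hits, config.evalue_max, config.overlap_fraction
    )
    homolog_groups = partition_by_architecture(proteomes, archs)
    logger.info(
        "stage 1: %d proteins -> %d homolog groups (%d characterized)",
        len(proteomes), len(homolog_groups),
        sum(1 for g in homolog_groups if not g.architecture.is_uncharacterized),
    )

    proteins = {p.protein_id: p for p in proteomes}
    scores: dict[tuple[str, str], SimilarityHit] = {}
    candidates: list[OrthologGroup] = []
    for hg in homolog_groups:
        if (
            hg.architecture.is_uncharacterized
            and config.uncharacterized_cap is not None
            and len(hg.members) > config.uncharacterized_cap
        ):
            logger.warning(
                "uncharacterized group holds %d proteins (> cap %d); skipping its RBH step",
                len(hg.members), config.uncharacterized_cap,
            )
            continue
        for anchor in config.anchors:
            candidates.extend(
                within_group_rbh(
                    hg, anchor, backend, proteins,
                    min_species=config.min_species, score_sink=scores,
                )
            )

    if len(config.anchors) > 1:
        final = merge_anchor_groups(candidates, scores, min_species=config.min_species)
    else:
        final = candidates
    ortholog_groups = assign_group_ids(final)
    logger.info("stage 2: %d ortholog groups reported", len(ortholog_groups))
    return ortholog_groups, homolog_groups
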