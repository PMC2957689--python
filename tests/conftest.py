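"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive — exhaustive enumeration over all
pairs or subsets — so they stay independent of the pipeline code they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from domortho.architecture import DomainHit, HomologGroup, Architecture
from domortho.io_formats import ProteinRecord
from domortho.similarity import MatrixBackend


def make_protein(pid: str, species: str, seq: str = "MKTAYIAKQR") -> ProteinRecord:
    return ProteinRecord(protein_id=pid, species_id=species, sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# exhaustive mutual-best oracle (checks within_group_rbh)

def exhaustive_rbh_oracle(
    members: set[tuple[str, str]],
    anchor_species: str,
    scores: dict[tuple[str, str], tuple[float, float]],
    min_species: int = 2,
) -> set[frozenset[tuple[str, str]]]:
    """All candidate groups by direct mutual-best checking over every pair.

    ``scores[(a, b)] = (bit, evalue)``; missing pairs are no-hits. Best is
    bit desc, evalue asc, protein id asc — asserted by comparing every
    alternative explicitly, no sorting shortcuts shared with the
    implementation.
    """

    def better(x: str, y: str, source: str) -> bool:
        # is x a strictly better partner than y for source?
        sx, sy = scores.get((source, x)), scores.get((source, y))
        if sy is None:
            return sx is not None
        if sx is None:
            return False
        return (-sx[0], sx[1], x) < (-sy[0], sy[1], y)

    species_of = {p: s for s, p in members}
    anchors = [p for s, p in members if s == anchor_species]
    groups: set[frozenset[tuple[str, str]]] = set()
    for a in anchors:
        partners = set()
        for s, b in members:
            if s == anchor_species or (a, b) not in scores:
                continue
            best_for_a = all(
                not better(b2, b, a)
                for s2, b2 in members
                if s2 == s and b2 != b
            )
            best_for_b = all(
                not better(a2, a, b)
                for s2, a2 in members
                if s2 == anchor_species and a2 != a
            )
            if best_for_a and best_for_b:
                partners.add((s, b))
        if partners:
            g = frozenset(partners | {(anchor_species, a)})
            if len({s for s, _ in g}) >= min_species:
                groups.add(g)
    return groups


def random_group_instance(rng, max_proteins=8, max_species=4):
    """A random homolog group plus a random symmetric score matrix."""
    n_species = int(rng.integers(2, max_species + 1))
    species = [f"s{i}" for i in range(n_species)]
    members: set[tuple[str, str]] = set()
    for sp in species:
        for k in range(int(rng.integers(1, 4))):
            members.add((sp, f"{sp}p{k}"))
    members = set(list(sorted(members))[:max_proteins])
    ids = [p for _, p in sorted(members)]
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in combinations(ids, 2):
        if rng.random() < 0.85:  # some pairs have no hit at all
            bit = float(rng.integers(20, 200))  # integer bits make ties likely
            ev = float(2.0 ** (-bit)) * 1e4
            scores[(a, b)] = (bit, ev)
            scores[(b, a)] = (bit, ev)
    return members, scores


def matrix_backend(scores: dict[tuple[str, str], tuple[float, float]]) -> MatrixBackend:
    return MatrixBackend(scores)


def group_from_members(members, index=1, domains=("DX",)) -> HomologGroup:
    return HomologGroup(
        architecture=Architecture(domains=tuple(domains)),
        members=frozenset(members),
        index=index,
    )


# ---------------------------------------------------------------------------
# genome-wide RBH oracle (checks whole-pipeline equivalence)

def genome_wide_rbh_oracle(proteins, backend, anchor_species, min_species=2):
    """Brute-force anchor-vs-everything RBH with no architecture grouping."""
    anchors = sorted(
        (p for p in proteins if p.species_id == anchor_species),
        key=lambda p: p.protein_id,
    )
    others = sorted(
        (p for p in proteins if p.species_id != anchor_species),
        key=lambda p: p.protein_id,
    )
    scores = {}
    for hit in backend.score_pairs(anchors, others):
        scores[(hit.query_id, hit.subject_id)] = (hit.bit_score, hit.evalue)
        scores[(hit.subject_id, hit.query_id)] = (hit.bit_score, hit.evalue)

    def best(source, candidates):
        scored = [
            (-scores[(source, c)][0], scores[(source, c)][1], c)
            for c in candidates
            if (source, c) in scores
        ]
        return min(scored)[2] if scored else None

    by_species = {}
    for p in others:
        by_species.setdefault(p.species_id, []).append(p.protein_id)
    anchor_ids = [p.protein_id for p in anchors]

    groups = set()
    for a in anchor_ids:
        partners = set()
        for sp, cands in by_species.items():
            b = best(a, cands)
            if b is not None and best(b, anchor_ids) == a:
                partners.add((sp, b))
        if partners:
            g = frozenset(partners | {(anchor_species, a)})
            if len({s for s, _ in g}) >= min_species:
                groups.add(g)
    return groups


# ---------------------------------------------------------------------------
# pair-enumeration oracle (checks compare_partitions)

def pair_metrics_oracle(predicted, reference):
    """Precision/recall over cross-species pairs by raw enumeration."""

    def pairs(partition):
        out = set()
        for g in partition:
            for a in g:
                for b in g:
                    if a < b and a[0] != b[0]:
                        out.add((a, b))
        return out

    pp, rp = pairs(predicted), pairs(reference)
    tp = len(pp & rp)
    return (tp / len(pp) if pp else 1.0, tp / len(rp) if rp else 1.0)
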