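"""Synthetic multi-species proteomes with known ortholog truth.

Gene families evolve along a balanced binary species tree with unit
branch lengths. Each family starts from an ancestral domain architecture
(an ordered draw from a shared domain alphabet, each domain with its own
consensus sequence) and, on every branch, each gene lineage may be lost,
duplicated, or have its architecture rearranged (swap / insert / delete
one domain); every residue then mutates independently at the configured
per-branch substitution rate. The simulator emits standard inputs for the
pipeline — FASTA-ready protein records and a domain-hit table whose
coordinates match the realized domain placement and whose E-values fall
below the 0.01 filter — together with a truth table and the set of true
cross-species ortholog pairs.

Orthology bookkeeping: every duplication event is stamped with the tree
branch where it happened and appended to the duplicated copy's lineage
trace. Two same-family genes in species u and v are true orthologs iff
their traces agree on all events that predate the u/v split (events below
the split are in-paralog duplications and do not break co-orthology,
matching the usual in-/out-paralog distinction).

The generator aims at structural truth (who is orthologous to whom, and
which evolutionary event hides it), not biological realism: no indels,
no rate heterogeneity, no empirical domain-length distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .architecture import Architecture, DomainHit
from .io_formats import ProteinRecord, TabularHit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Knobs of the generator; identical seeds give byte-identical output.

    Event probabilities are per gene lineage per branch; the substitution
    rate is the expected fraction of residues replaced per branch.
    """

    n_species: int = 10
    n_families: int = 100
    domain_alphabet_size: int = 40
    domains_per_family: tuple[int, int] = (1, 4)
    p_loss: float = 0.05
    p_duplication: float = 0.05
    p_rearrangement: float = 0.05
    substitution_rate: float = 0.05
    domain_length: tuple[int, int] = (60, 120)
    linker_length: tuple[int, int] = (5, 25)
    seed: int = 0
    unique_architectures: bool = True

    def __post_init__(self) -> None:
        for name in ("p_loss", "p_duplication", "p_rearrangement", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_species", "n_families", "domain_alphabet_size"):
            if getattr(self, name) < 1 and not (name == "n_families" and self.n_families == 0):
                raise ValueError(f"{name} must be positive")
        for name in ("domains_per_family", "domain_length", "linker_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range ({lo}, {hi}) is invalid")
        if self.domains_per_family[0] < 1:
            raise ValueError("families need at least one ancestral domain")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the simulated proteomes."""

    table: pd.DataFrame  # protein_id, species_id, family_id, duplicated, rearranged
    ancestral_architectures: dict[str, Architecture]
    true_pairs: set[frozenset[str]]  # unordered protein-id pairs

    def family_partition(self) -> list[set[tuple[str, str]]]:
        """One (species_id, protein_id) member set per family, sorted by family."""
        out = []
        for fam, sub in sorted(self.table.groupby("family_id")):
            out.append({(r.species_id, r.protein_id) for r in sub.itertuples()})
        return out

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.table.protein_id, self.table.species_id))


@dataclass
class SimulationResult:
    proteins: list[ProteinRecord]
    domain_hits: list[DomainHit]
    truth: TruthSet


# ---------------------------------------------------------------------------
# species tree

@dataclass
class _Node:
    node_id: int
    children: list["_Node"] = field(default_factory=list)
    species: str | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _balanced_tree(species: Sequence[str]) -> tuple[_Node, dict[int, set[int]]]:
    """Balanced binary tree over the species; returns root and ancestor sets.

    ``ancestors[node_id]`` contains the ids of the node itself and every
    node above it (used to decide whether a duplication predates a split).
    """
    counter = [0]

    def build(labels: Sequence[str]) -> _Node:
        node = _Node(node_id=counter[0])
        counter[0] += 1
        if len(labels) == 1:
            node.species = labels[0]
            return node
        mid = (len(labels) + 1) // 2
        node.children = [build(labels[:mid]), build(labels[mid:])]
        return node

    root = build(list(species))
    ancestors: dict[int, set[int]] = {}

    def walk(node: _Node, above: set[int]) -> None:
        here = above | {node.node_id}
        ancestors[node.node_id] = here
        for ch in node.children:
            walk(ch, here)

    walk(root, set())
    return root, ancestors


def _leafsets(root: _Node) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}

    def walk(node: _Node) -> frozenset[str]:
        if node.is_leaf:
            s = frozenset([node.species])
        else:
            s = frozenset().union(*(walk(ch) for ch in node.children))
        sets[node.node_id] = s
        return s

    walk(root)
    return sets


def _lca_id(root: _Node, leafsets: dict[int, frozenset[str]], sp_a: str, sp_b: str) -> int:
    node = root
    while True:
        sub = [
            ch for ch in node.children
            if sp_a in leafsets[ch.node_id] and sp_b in leafsets[ch.node_id]
        ]
        if not sub:
            return node.node_id
        node = sub[0]


def leaf_depths(n_species: int) -> dict[str, int]:
    """Number of branches from the root to each species leaf."""
    species = [f"sp{i:02d}" for i in range(1, n_species + 1)]
    root, _ = _balanced_tree(species)
    depths: dict[str, int] = {}

    def walk(node: _Node, d: int) -> None:
        if node.is_leaf:
            depths[node.species] = d
        for ch in node.children:
            walk(ch, d + 1)

    walk(root, 0)
    return depths


# ---------------------------------------------------------------------------
# genes and events

@dataclass
class _Gene:
    family: str
    domains: list[tuple[str, str]]  # (domain_id, current sequence)
    linkers: list[str]  # len(domains) + 1
    dup_trace: tuple[tuple[int, int], ...] = ()  # (branch node_id, event id)
    duplicated: bool = False
    rearranged: bool = False

    def clone(self) -> "_Gene":
        return _Gene(
            family=self.family,
            domains=list(self.domains),
            linkers=list(self.linkers),
            dup_trace=self.dup_trace,
            duplicated=self.duplicated,
            rearranged=self.rearranged,
        )

    @property
    def architecture(self) -> Architecture:
        return Architecture(domains=tuple(d for d, _ in self.domains))


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        cur = chars[i]
        pool = AMINO_ACIDS.replace(cur, "") if cur in AMINO_ACIDS else AMINO_ACIDS
        chars[i] = pool[rng.integers(len(pool))]
    return "".join(chars)


def rearrange_architecture(gene: _Gene, rng: np.random.Generator,
                           consensus: dict[str, str], alphabet: list[str],
                           linker_length: tuple[int, int]) -> None:
    """Apply one domain-changing event in place; the architecture always changes.

    Candidate moves: swap two adjacent *different* domains, insert a random
    alphabet domain (fresh copy of its consensus), or delete a domain
    (only when at least two remain).
    """
    moves = ["insert"]
    if len(gene.domains) >= 2:
        if any(gene.domains[i][0] != gene.domains[i + 1][0] for i in range(len(gene.domains) - 1)):
            moves.append("swap")
        moves.append("delete")
    move = moves[rng.integers(len(moves))]
    if move == "swap":
        idx = [i for i in range(len(gene.domains) - 1) if gene.domains[i][0] != gene.domains[i + 1][0]]
        i = idx[rng.integers(len(idx))]
        gene.domains[i], gene.domains[i + 1] = gene.domains[i + 1], gene.domains[i]
    elif move == "insert":
        i = int(rng.integers(len(gene.domains) + 1))
        dom = alphabet[rng.integers(len(alphabet))]
        gene.domains.insert(i, (dom, consensus[dom]))
        gene.linkers.insert(i + 1, _random_seq(int(rng.integers(linker_length[0], linker_length[1] + 1)), rng))
    else:  # delete
        i = int(rng.integers(len(gene.domains)))
        gene.domains.pop(i)
        gene.linkers.pop(i + 1)
    gene.rearranged = True


def _mutate_gene(gene: _Gene, rate: float, rng: np.random.Generator) -> None:
    gene.domains = [(d, _mutate(s, rate, rng)) for d, s in gene.domains]
    gene.linkers = [_mutate(s, rate, rng) for s in gene.linkers]


def _assemble(gene: _Gene) -> tuple[str, list[tuple[str, int, int]]]:
    """Concatenate linkers and domains; return sequence + 1-based domain placements."""
    parts: list[str] = []
    placements: list[tuple[str, int, int]] = []
    pos = 0
    for i, (dom, seq) in enumerate(gene.domains):
        parts.append(gene.linkers[i])
        pos += len(gene.linkers[i])
        parts.append(seq)
        placements.append((dom, pos + 1, pos + len(seq)))
        pos += len(seq)
    parts.append(gene.linkers[-1])
    return "".join(parts), placements


# ---------------------------------------------------------------------------
# the simulator proper

def simulate(config: SimConfig, force_rearrangement_species: str | None = None) -> SimulationResult:
    """Evolve ``n_families`` gene families over ``n_species`` and emit truth.

    When ``force_rearrangement_species`` names a species, one rearrangement
    is additionally applied — after normal evolution — to every surviving
    gene of the *first* family in that species, guaranteeing its realized
    architecture differs from the family's ancestral one. This reproduces,
    on demand, the event class that architecture-keyed grouping cannot
    recover from.
    """
    rng = np.random.default_rng(config.seed)
    species = [f"sp{i:02d}" for i in range(1, config.n_species + 1)]
    if force_rearrangement_species is not None and force_rearrangement_species not in species:
        raise ValueError(f"unknown species {force_rearrangement_species!r}")
    root, ancestors = _balanced_tree(species)

    alphabet = [f"D{i:03d}" for i in range(1, config.domain_alphabet_size + 1)]
    lengths = {
        d: int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
        for d in alphabet
    }
    consensus = {d: _random_seq(lengths[d], rng) for d in alphabet}

    families = [f"fam{j:03d}" for j in range(1, config.n_families + 1)]
    ancestral: dict[str, Architecture] = {}
    seen_archs: set[tuple[str, ...]] = set()
    root_genes: list[_Gene] = []
    for fam in families:
        for _attempt in range(1000):
            k = int(rng.integers(config.domains_per_family[0], config.domains_per_family[1] + 1))
            arch = tuple(alphabet[i] for i in rng.integers(0, len(alphabet), size=k))
            if not config.unique_architectures or arch not in seen_archs:
                break
        else:
            raise ValueError(
                "could not draw a unique architecture; enlarge domain_alphabet_size"
            )
        seen_archs.add(arch)
        ancestral[fam] = Architecture(domains=arch)
        linkers = [
            _random_seq(int(rng.integers(config.linker_length[0], config.linker_length[1] + 1)), rng)
            for _ in range(k + 1)
        ]
        root_genes.append(_Gene(family=fam, domains=[(d, consensus[d]) for d in arch], linkers=linkers))

    event_counter = [0]
    leaf_genes: dict[str, list[_Gene]] = {}

    def descend(node: _Node, genes: list[_Gene]) -> None:
        if node.is_leaf:
            leaf_genes[node.species] = genes
            return
        for child in node.children:
            surviving: list[_Gene] = []
            for gene in genes:
                if rng.random() < config.p_loss:
                    continue
                copies = [gene.clone()]
                if rng.random() < config.p_duplication:
                    event_counter[0] += 1
                    dup = gene.clone()
                    dup.dup_trace = dup.dup_trace + ((child.node_id, event_counter[0]),)
                    dup.duplicated = True
                    copies.append(dup)
                for g in copies:
                    if rng.random() < config.p_rearrangement:
                        rearrange_architecture(g, rng, consensus, alphabet, config.linker_length)
                    _mutate_gene(g, config.substitution_rate, rng)
                    surviving.append(g)
            descend(child, surviving)

    descend(root, root_genes)

    if force_rearrangement_species is not None and families:
        target_family = families[0]
        for g in leaf_genes[force_rearrangement_species]:
            if g.family == target_family:
                while g.architecture == ancestral[target_family]:
                    rearrange_architecture(g, rng, consensus, alphabet, config.linker_length)

    proteins: list[ProteinRecord] = []
    domain_hits: list[DomainHit] = []
    rows: list[dict] = []
    gene_meta: dict[str, _Gene] = {}
    for sp in species:
        per_family: dict[str, int] = {}
        ordered = sorted(leaf_genes[sp], key=lambda g: (g.family, g.dup_trace))
        for g in ordered:
            per_family[g.family] = per_family.get(g.family, 0) + 1
            pid = f"{sp}_{g.family}_g{per_family[g.family]}"
            seq, placements = _assemble(g)
            if not seq:  # all-domain deletion plus empty linkers; exceedingly rare
                seq = _random_seq(30, rng)
            proteins.append(ProteinRecord(protein_id=pid, species_id=sp, sequence=seq))
            for dom, start, end in placements:
                domain_hits.append(
                    DomainHit(
                        protein_id=pid,
                        domain_id=dom,
                        start=start,
                        end=end,
                        evalue=float(10.0 ** rng.uniform(-30.0, -3.0)),
                        bit_score=float(1.8 * (end - start + 1) + rng.uniform(0.0, 10.0)),
                    )
                )
            rows.append(
                {
                    "protein_id": pid,
                    "species_id": sp,
                    "family_id": g.family,
                    "duplicated": int(g.duplicated),
                    "rearranged": int(g.rearranged),
                }
            )
            gene_meta[pid] = g

    table = pd.DataFrame(rows, columns=["protein_id", "species_id", "family_id", "duplicated", "rearranged"])

    leafsets = _leafsets(root)
    lca_cache: dict[tuple[str, str], set[int]] = {}
    for a in species:
        for b in species:
            if a < b:
                lca = _lca_id(root, leafsets, a, b)
                lca_cache[(a, b)] = ancestors[lca]

    true_pairs: set[frozenset[str]] = set()
    by_family: dict[str, list[dict]] = {}
    for r in rows:
        by_family.setdefault(r["family_id"], []).append(r)
    for fam_rows in by_family.values():
        for i in range(len(fam_rows)):
            for j in range(i + 1, len(fam_rows)):
                ra, rb = fam_rows[i], fam_rows[j]
                if ra["species_id"] == rb["species_id"]:
                    continue
                key = tuple(sorted((ra["species_id"], rb["species_id"])))
                shared = lca_cache[key]
                ta = tuple(e for e in gene_meta[ra["protein_id"]].dup_trace if e[0] in shared)
                tb = tuple(e for e in gene_meta[rb["protein_id"]].dup_trace if e[0] in shared)
                if ta == tb:
                    true_pairs.add(frozenset((ra["protein_id"], rb["protein_id"])))

    truth = TruthSet(table=table, ancestral_architectures=ancestral, true_pairs=true_pairs)
    return SimulationResult(proteins=proteins, domain_hits=domain_hits, truth=truth)


def inject_decoys(
    hits: Sequence[DomainHit],
    n: int,
    evalue_range: tuple[float, float] = (0.01, 10.0),
    seed: int = 0,
) -> list[DomainHit]:
    """Append ``n`` spurious hits with E-values at or above the 0.01 cutoff.

    Each decoy is placed overlapping a randomly chosen real hit, with a
    lower bit score than the hit it shadows, so it exercises both the
    E-value filter and — if let through deliberately — overlap resolution.
    Original hits are returned untouched.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    lo, hi = evalue_range
    if lo < 0.01:
        raise ValueError("decoy evalues must be >= 0.01 to sit above the filter")
    if n == 0:
        return list(hits)
    if not hits:
        raise ValueError("cannot place decoys without real hits to shadow")
    rng = np.random.default_rng(seed)
    out = list(hits)
    for i in range(n):
        target = hits[int(rng.integers(len(hits)))]
        span = int(rng.integers(20, 61))
        # keep the decoy inside (or covering) its target so the two always
        # overlap by more than half of the shorter span
        start_hi = max(target.start, target.end - span + 1)
        start = int(rng.integers(target.start, start_hi + 1))
        out.append(
            DomainHit(
                protein_id=target.protein_id,
                domain_id=f"DECOY{i + 1:03d}",
                start=start,
                end=start + span - 1,
                evalue=float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi))),
                bit_score=float(target.bit_score * rng.uniform(0.2, 0.8)),
            )
        )
    return out


def domain_hits_to_tabular(hits: Iterable[DomainHit]) -> list[TabularHit]:
    """Render simulated domain hits in the 12-column tabular dialect."""
    rows = []
    for h in hits:
        span = h.end - h.start + 1
        rows.append(
            TabularHit(
                query_id=h.protein_id,
                subject_id=h.domain_id,
                percent_identity=85.0,
                alignment_length=span,
                mismatches=0,
                gap_opens=0,
                q_start=h.start,
                q_end=h.end,
                s_start=1,
                s_end=span,
                evalue=h.evalue,
                bit_score=h.bit_score,
            )
        )
    return rows


def anchor_rescue_scenario(seed: int = 0, substitution_rate: float = 0.02) -> SimulationResult:
    """Hand-built four-genome scenario for multi-anchor rescue.

    Species A–D fall into two clades {A, B} and {C, D}. Family 1 is
    present in all four genomes, family 2 only in the second clade, and
    family 3 everywhere except genome A (a loss on the A lineage). With A
    as the sole anchor only family 1 can be reported; adding an anchor
    from the second clade (C) rescues the other two.
    """
    rng = np.random.default_rng(seed)
    presence = {
        "fam1": ["A", "B", "C", "D"],
        "fam2": ["C", "D"],
        "fam3": ["B", "C", "D"],
    }
    archs = {"fam1": ("DA", "DB"), "fam2": ("DC",), "fam3": ("DD", "DE")}
    domain_ids = sorted({d for a in archs.values() for d in a})
    consensus = {d: _random_seq(90, rng) for d in domain_ids}

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    rows: list[dict] = []
    for fam in sorted(presence):
        linkers = [_random_seq(int(rng.integers(5, 16)), rng) for _ in range(len(archs[fam]) + 1)]
        for sp in presence[fam]:
            gene = _Gene(
                family=fam,
                domains=[(d, _mutate(consensus[d], substitution_rate, rng)) for d in archs[fam]],
                linkers=[_mutate(l, substitution_rate, rng) for l in linkers],
            )
            pid = f"{sp}_{fam}"
            seq, placements = _assemble(gene)
            proteins.append(ProteinRecord(protein_id=pid, species_id=sp, sequence=seq))
            for dom, start, end in placements:
                hits.append(
                    DomainHit(
                        protein_id=pid, domain_id=dom, start=start, end=end,
                        evalue=float(10.0 ** rng.uniform(-30.0, -3.0)),
                        bit_score=float(1.8 * (end - start + 1)),
                    )
                )
            rows.append(
                {"protein_id": pid, "species_id": sp, "family_id": fam,
                 "duplicated": 0, "rearranged": 0}
            )

    table = pd.DataFrame(rows, columns=["protein_id", "species_id", "family_id", "duplicated", "rearranged"])
    pairs = {
        frozenset((a["protein_id"], b["protein_id"]))
        for fam, sub in table.groupby("family_id")
        for a in sub.to_dict("records")
        for b in sub.to_dict("records")
        if a["protein_id"] < b["protein_id"] and a["species_id"] != b["species_id"]
    }
    truth = TruthSet(
        table=table,
        ancestral_architectures={f: Architecture(domains=a) for f, a in archs.items()},
        true_pairs=pairs,
    )
    return SimulationResult(proteins=proteins, domain_hits=hits, truth=truth)
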