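"""Metrics for comparing ortholog partitions, plus the update-cost model.

A predicted partition (collections of ``(species_id, protein_id)`` member
sets) is scored against a reference partition with:

* exact-match fraction — predicted groups identical, as member sets, to
  some reference group;
* majority-overlap fraction — predicted groups with strictly more than
  half their members inside a single reference group;
* pairwise precision/recall over unordered cross-species member pairs.

Also here: the species-count histogram of a set of groups, a taxonomic
"closeness" score per group on a supplied rooted taxonomy, the analytic
cost model contrasting all-vs-all reciprocal-best-hit searching with
per-genome domain identification, and a thin rank-sum test wrapper for
comparing closeness or length distributions between two sets of groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from skbio import TreeNode

Member = tuple[str, str]  # (species_id, protein_id)


@dataclass(frozen=True)
class GroupComparison:
    n_predicted: int
    n_reference: int
    exact_match_fraction: float
    majority_overlap_fraction: float
    pair_precision: float
    pair_recall: float


def _cross_species_pairs(groups: Iterable[frozenset[Member]]) -> set[frozenset[Member]]:
    pairs: set[frozenset[Member]] = set()
    for g in groups:
        for a, b in combinations(sorted(g), 2):
            if a[0] != b[0]:
                pairs.add(frozenset((a, b)))
    return pairs


def compare_partitions(
    predicted: Iterable[Iterable[Member]], reference: Iterable[Iterable[Member]]
) -> GroupComparison:
    """Score a predicted ortholog partition against a reference partition."""
    pred = [frozenset(g) for g in predicted]
    ref = [frozenset(g) for g in reference]
    ref_sets = set(ref)
    member_to_ref: dict[Member, int] = {}
    for i, g in enumerate(ref):
        for m in g:
            member_to_ref[m] = i

    exact = sum(1 for g in pred if g in ref_sets)
    majority = 0
    for g in pred:
        counts = Counter(member_to_ref[m] for m in g if m in member_to_ref)
        if counts and max(counts.values()) * 2 > len(g):
            majority += 1

    pred_pairs = _cross_species_pairs(pred)
    ref_pairs = _cross_species_pairs(ref)
    tp = len(pred_pairs & ref_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 1.0
    recall = tp / len(ref_pairs) if ref_pairs else 1.0

    if pred:
        exact_frac, majority_frac = exact / len(pred), majority / len(pred)
    else:
        exact_frac = majority_frac = 1.0 if not ref else 0.0
    return GroupComparison(
        n_predicted=len(pred),
        n_reference=len(ref),
        exact_match_fraction=exact_frac,
        majority_overlap_fraction=majority_frac,
        pair_precision=precision,
        pair_recall=recall,
    )


def pair_precision_recall(
    predicted_pairs: set[frozenset[str]], true_pairs: set[frozenset[str]]
) -> tuple[float, float]:
    """Precision/recall over unordered protein-id pairs (e.g. vs simulator truth)."""
    tp = len(predicted_pairs & true_pairs)
    precision = tp / len(predicted_pairs) if predicted_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall


def group_pairs(groups: Iterable[Iterable[Member]]) -> set[frozenset[str]]:
    """Cross-species member pairs of a partition, as protein-id pairs."""
    return {
        frozenset((a[1], b[1]))
        for pair in _cross_species_pairs(frozenset(g) for g in groups)
        for a, b in [sorted(pair)]
    }


def species_count_distribution(groups: Iterable[Iterable[Member]]) -> dict[int, int]:
    """Histogram: number of species in a group → count of such groups."""
    groups = [frozenset(g) for g in groups]
    if not groups:
        raise ValueError("no groups to histogram")
    return dict(Counter(len({s for s, _ in g}) for g in groups))


def cost_model(n_genomes: int) -> int:
    """Unordered genome pairs needing mutual comparison in all-vs-all RBH."""
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    return n_genomes * (n_genomes - 1) // 2


def update_cost(n_existing: int, m_new: int) -> tuple[int, int]:
    """Cost of adding ``m_new`` genomes to a database of ``n_existing``.

    All-vs-all RBH needs ``n·m`` fresh genome-pair comparisons; the
    domain-architecture scheme needs only ``m`` domain-identification
    scans, independent of database size.
    """
    if n_existing < 0 or m_new < 0:
        raise ValueError("genome counts must be non-negative")
    return n_existing * m_new, m_new


def _depth(node: TreeNode) -> int:
    return len(node.ancestors())


def closeness(group: Iterable[Member], taxonomy: TreeNode) -> float:
    """Mean taxonomic relatedness of a group's species on a rooted taxonomy.

    For each unordered species pair: depth of the shared ancestor divided
    by the deeper leaf's depth (depths in edges from the root). A pair of
    identical species scores 1, so a single-species group scores 1.
    """
    species = sorted({s for s, _ in group})
    if not species:
        raise ValueError("empty group")
    tips: dict[str, TreeNode] = {}
    for s in species:
        try:
            tips[s] = taxonomy.find(s)
        except Exception as exc:
            raise ValueError(f"species {s!r} not found in the taxonomy") from exc
    if len(species) == 1:
        return 1.0
    values = []
    for a, b in combinations(species, 2):
        lca = taxonomy.lowest_common_ancestor([tips[a], tips[b]])
        deeper = max(_depth(tips[a]), _depth(tips[b]))
        values.append(_depth(lca) / deeper if deeper else 1.0)
    return sum(values) / len(values)


def read_taxonomy(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U): returns (statistic, p)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def read_partition_tsv(path: str | Path) -> list[set[Member]]:
    """Read a reference partition: TSV with group_id, species_id, protein_id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["group_id", "species_id", "protein_id"],
        dtype=str, comment="#",
    )
    return [
        {(r.species_id, r.protein_id) for r in sub.itertuples()}
        for _, sub in df.groupby("group_id", sort=True)
    ]


def write_partition_tsv(groups, path: str | Path) -> None:
    """Write ortholog groups as the 3-column partition TSV."""
    with open(path, "w") as fh:
        for g in groups:
            gid = getattr(g, "group_id", None)
            members = g.members if hasattr(g, "members") else g
            if gid is None:
                raise ValueError("groups need assigned IDs to be written")
            for species, protein in sorted(members):
                fh.write(f"{gid}\t{species}\t{protein}\n")
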