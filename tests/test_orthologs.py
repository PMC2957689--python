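"""Within-group RBH, ID assignment, multi-anchor merging, full pipeline."""

import numpy as np
import pytest

from domortho.architecture import UNCHARACTERIZED
from domortho.orthologs import (
    OrthologGroup,
    PipelineConfig,
    assign_group_ids,
    run_pipeline,
    within_group_rbh,
)
from domortho.similarity import BuiltinAligner, MatrixBackend
from domortho.simulate import SimConfig, anchor_rescue_scenario, simulate

from .conftest import (
    exhaustive_rbh_oracle,
    genome_wide_rbh_oracle,
    group_from_members,
    make_protein,
    random_group_instance,
)


def run_rbh(members, scores, anchor="s0", min_species=2):
    proteins = {p: make_protein(p, s) for s, p in members}
    backend = MatrixBackend(scores)
    return within_group_rbh(
        group_from_members(members), anchor, backend, proteins, min_species=min_species
    )


class TestWithinGroupRBH:
    def test_single_pair_is_forced(self):
        members = {("s0", "a1"), ("s1", "b1")}
        groups = run_rbh(members, {("a1", "b1"): (50.0, 1e-10)})
        assert len(groups) == 1
        assert groups[0].members == frozenset(members)

    def test_sole_domain_pair_reported(self):
        # Two proteins that are each the only carrier of a domain in their
        # genome: grouped by architecture first, the pair is reported even
        # though neither would need to win a genome-wide race.
        members = {("human", "h_nop16"), ("mouse", "m_nop16")}
        proteins = {p: make_protein(p, s) for s, p in members}
        groups = within_group_rbh(
            group_from_members(members, domains=("Nop16",)),
            "human",
            MatrixBackend({("h_nop16", "m_nop16"): (40.0, 1e-8)}),
            proteins,
        )
        assert [sorted(g.members) for g in groups] == [sorted(members)]

    def test_anchor_absent_returns_empty(self):
        members = {("s1", "b1"), ("s2", "c1")}
        assert run_rbh(members, {("b1", "c1"): (50.0, 1e-10)}) == []

    def test_in_paralog_only_best_duplicate_joins(self):
        members = {("s0", "a1"), ("s1", "b1"), ("s1", "b2")}
        scores = {("a1", "b1"): (90.0, 1e-20), ("a1", "b2"): (70.0, 1e-15)}
        (group,) = run_rbh(members, scores)
        assert group.members == frozenset({("s0", "a1"), ("s1", "b1")})

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        members, scores = random_group_instance(rng)
        got = {g.members for g in run_rbh(members, scores)}
        assert got == exhaustive_rbh_oracle(members, "s0", scores)

    @pytest.mark.parametrize("seed", range(10))
    def test_one_membership_and_rbh_symmetry(self, seed):
        rng = np.random.default_rng(1000 + seed)
        members, scores = random_group_instance(rng)
        groups = run_rbh(members, scores)
        seen = [m for g in groups for m in g.members if m[0] != "s0"]
        assert len(seen) == len(set(seen))
        for g in groups:
            a = g.anchor_protein[1]
            for s, b in g.members:
                if s == "s0":
                    continue
                rivals = [p for sp, p in members if sp == s and p != b]
                for r in rivals:  # b must beat every same-species rival from a's side
                    if (a, r) in scores:
                        assert (
                            (-scores[(a, b)][0], scores[(a, b)][1], b)
                            < (-scores[(a, r)][0], scores[(a, r)][1], r)
                        )


class TestAssignGroupIds:
    def make(self, pid, arch):
        return OrthologGroup(
            anchor_protein=("s0", pid),
            members=frozenset({("s0", pid), ("s1", pid + "_m")}),
            source_architecture=arch,
        )

    def test_prefixes_and_determinism(self):
        from domortho.architecture import Architecture

        arch = Architecture(("A",))
        groups = [self.make("z", arch), self.make("a", UNCHARACTERIZED), self.make("m", arch)]
        ids1 = [g.group_id for g in assign_group_ids(groups)]
        ids2 = [g.group_id for g in assign_group_ids(list(reversed(groups)))]
        assert ids1 == ids2 == ["NoDomainInfo1", "PfamArcNu1", "PfamArcNu2"]


class TestRunPipeline:
    def test_unknown_anchor_raises(self):
        sim = simulate(SimConfig(n_species=2, n_families=2, seed=0))
        with pytest.raises(ValueError, match="marsupial"):
            run_pipeline(sim.proteins, sim.domain_hits, BuiltinAligner(),
                         PipelineConfig(anchors=["marsupial"]))

    def test_single_species_yields_no_groups(self):
        sim = simulate(SimConfig(n_species=1, n_families=3, p_loss=0, p_duplication=0,
                                 p_rearrangement=0, seed=0))
        groups, _ = run_pipeline(sim.proteins, sim.domain_hits, BuiltinAligner(),
                                 PipelineConfig(anchors=["sp01"]))
        assert groups == []

    def test_deterministic_rerun(self):
        sim = simulate(SimConfig(n_species=4, n_families=8, seed=7))
        cfg = PipelineConfig(anchors=["sp01", "sp03"])
        out1, _ = run_pipeline(sim.proteins, sim.domain_hits, BuiltinAligner(), cfg)
        out2, _ = run_pipeline(sim.proteins, sim.domain_hits, BuiltinAligner(), cfg)
        assert [(g.group_id, g.members) for g in out1] == [(g.group_id, g.members) for g in out2]

    def test_matches_genome_wide_rbh_when_architectures_unique(self):
        # no loss: every family keeps its anchor gene, so genome-wide best
        # hits never cross family boundaries and the equivalence is exact
        sim = simulate(
            SimConfig(n_species=3, n_families=10, p_loss=0.0, p_duplication=0.15,
                      p_rearrangement=0.0, substitution_rate=0.03, seed=11)
        )
        backend = BuiltinAligner()
        got, _ = run_pipeline(sim.proteins, sim.domain_hits, backend,
                              PipelineConfig(anchors=["sp01"]))
        oracle = genome_wide_rbh_oracle(sim.proteins, backend, "sp01")
        assert {g.members for g in got} == oracle

    def test_gene_loss_makes_genome_wide_rbh_cross_families(self):
        """Under gene loss, whole-proteome RBH can pair proteins from
        different families (the true partner's lineage is gone and a weak
        cross-family alignment wins the race); architecture grouping keeps
        families pure. This seed produces such a spurious pair."""
        sim = simulate(SimConfig(n_species=3, n_families=10, p_loss=0.1,
                                 p_duplication=0.1, p_rearrangement=0.0,
                                 substitution_rate=0.03, seed=1792079620))
        backend = BuiltinAligner()
        got, _ = run_pipeline(sim.proteins, sim.domain_hits, backend,
                              PipelineConfig(anchors=["sp01"]))
        oracle = genome_wide_rbh_oracle(sim.proteins, backend, "sp01")
        fam = dict(zip(sim.truth.table.protein_id, sim.truth.table.family_id))

        def is_pure(group):
            return len({fam[p] for _, p in group}) == 1

        assert all(is_pure(g.members) for g in got)
        assert any(not is_pure(g) for g in oracle)

    def test_uncharacterized_proteins_resolved_by_pure_rbh(self):
        sim = simulate(SimConfig(n_species=3, n_families=4, p_loss=0, p_duplication=0,
                                 p_rearrangement=0, substitution_rate=0.02, seed=3))
        # withhold all domain hits: everything lands in the uncharacterized pool
        groups, homologs = run_pipeline(sim.proteins, [], BuiltinAligner(),
                                        PipelineConfig(anchors=["sp01"]))
        assert len(homologs) == 1 and homologs[0].architecture.is_uncharacterized
        assert groups and all(g.group_id.startswith("NoDomainInfo") for g in groups)

    def test_uncharacterized_cap_skips_pool(self):
        sim = simulate(SimConfig(n_species=3, n_families=4, p_loss=0, p_duplication=0,
                                 p_rearrangement=0, seed=3))
        groups, _ = run_pipeline(sim.proteins, [], BuiltinAligner(),
                                 PipelineConfig(anchors=["sp01"], uncharacterized_cap=5))
        assert groups == []


class TestMultiAnchor:
    def test_second_anchor_rescues_missing_families(self):
        sim = anchor_rescue_scenario(seed=0)
        backend = BuiltinAligner()
        single, _ = run_pipeline(sim.proteins, sim.domain_hits, backend,
                                 PipelineConfig(anchors=["A"]))
        double, _ = run_pipeline(sim.proteins, sim.domain_hits, backend,
                                 PipelineConfig(anchors=["A", "C"]))
        assert len(single) == 1
        assert len(double) == 3
        families = {frozenset(p for _, p in g.members) for g in double}
        expected = {
            frozenset({"A_fam1", "B_fam1", "C_fam1", "D_fam1"}),
            frozenset({"C_fam2", "D_fam2"}),
            frozenset({"B_fam3", "C_fam3", "D_fam3"}),
        }
        assert families == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_anchor_coverage_is_monotone(self, seed):
        sim = simulate(SimConfig(n_species=4, n_families=8, p_loss=0.2, p_duplication=0,
                                 p_rearrangement=0, substitution_rate=0.03, seed=seed))
        backend = BuiltinAligner()
        single, _ = run_pipeline(sim.proteins, sim.domain_hits, backend,
                                 PipelineConfig(anchors=["sp01"]))
        double, _ = run_pipeline(sim.proteins, sim.domain_hits, backend,
                                 PipelineConfig(anchors=["sp01", "sp03"]))
        cov_single = set().union(*(g.members for g in single)) if single else set()
        cov_double = set().union(*(g.members for g in double)) if double else set()
        assert cov_single <= cov_double
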