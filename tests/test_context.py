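from itertools import combinations

import pytest

from ppinet.context import (
    InteractionNetwork,
    NeighborhoodConfig,
    ProfileConfig,
    assemble_network,
    build_presence_profiles,
    neighborhood_interactions,
    profile_edge_estimate,
    profile_interactions,
)
from ppinet.io import ProteinRecord, canonical_pair
from ppinet.ris import RISConfig


def _genome(gid, seqs, ids=None):
    ids = ids or [f"p{i}" for i in range(len(seqs))]
    return [
        ProteinRecord(id=pid, sequence=seq, genome_id=gid, position=i)
        for i, (pid, seq) in enumerate(zip(ids, seqs))
    ]


def _seq_predicate(a, b):
    """Toy similarity: identical sequences are similar."""
    return a.sequence == b.sequence


class TestBuildPresenceProfiles:
    def test_identical_proteomes_all_true(self):
        seqs = ["AAAA", "CCCC", "DDDD"]
        genomes = [_genome(f"g{i}", seqs) for i in range(3)]
        presence = build_presence_profiles(genomes, _seq_predicate)
        for gid in ("g0", "g1", "g2"):
            for prof in presence.genome(gid).values():
                assert prof.bits == (True, True, True)
                assert prof.group_size == 3

    def test_orphan_protein_true_only_at_home(self):
        genomes = [_genome("g0", ["AAAA", "WWWW"]), _genome("g1", ["AAAA", "CCCC"])]
        presence = build_presence_profiles(genomes, _seq_predicate)
        assert presence.genome("g0")["p1"].bits == (True, False)
        assert presence.genome("g0")["p0"].bits == (True, True)

    def test_family_in_two_of_three_genomes(self):
        genomes = [
            _genome("g0", ["AAAA", "EEEE"]),
            _genome("g1", ["AAAA", "FFFF"]),
            _genome("g2", ["HHHH", "KKKK"]),
        ]
        presence = build_presence_profiles(genomes, _seq_predicate)
        assert presence.genome("g0")["p0"].bits == (True, True, False)
        assert presence.genome("g1")["p0"].bits == (True, True, False)

    def test_single_genome_raises(self):
        with pytest.raises(ValueError, match="2 genomes"):
            build_presence_profiles([_genome("g0", ["AAAA"])], _seq_predicate)


def _profiles(bit_map):
    """Helper: protein id -> bits, wrapped as PhylogeneticProfile mapping."""
    from ppinet.context import PhylogeneticProfile

    return {
        pid: PhylogeneticProfile(protein_id=pid, genome_id="g0", bits=bits)
        for pid, bits in bit_map.items()
    }


class TestProfileInteractions:
    def test_identical_group_of_three_forms_triangle(self):
        profs = _profiles({p: (True, True, False) for p in "abc"})
        edges = profile_interactions(profs, ProfileConfig())
        assert edges == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_hamming_tolerance_semantics(self):
        profs = _profiles({"a": (True, True, False), "b": (True, True, True)})
        assert profile_interactions(profs, ProfileConfig(diff_tolerated=0)) == set()
        assert profile_interactions(profs, ProfileConfig(diff_tolerated=1)) == {("a", "b")}

    def test_own_genome_only_profiles_are_silent(self):
        profs = _profiles({"a": (True, False, False), "b": (True, False, False)})
        assert profile_interactions(profs, ProfileConfig(diff_tolerated=3)) == set()

    def test_large_group_is_ris_sampled_to_strict_subset(self):
        members = [f"m{i:03d}" for i in range(150)]
        profs = _profiles({m: (True, True) for m in members})
        edges = profile_interactions(
            profs, ProfileConfig(ris_trigger=100), RISConfig(trigger=100, seed=0), seed=0
        )
        complete = {canonical_pair(a, b) for a, b in combinations(members, 2)}
        assert edges < complete
        assert len(edges) < len(complete)
        covered = {n for e in edges for n in e}
        assert covered == set(members)

    def test_tolerance_monotonicity_with_ris_disabled(self):
        import numpy as np

        rng = np.random.default_rng(7)
        bit_map = {
            f"p{i}": tuple(bool(b) for b in np.r_[1, rng.integers(0, 2, size=3)])
            for i in range(25)
        }
        profs = _profiles(bit_map)
        previous = set()
        for tol in range(4):
            edges = profile_interactions(profs, ProfileConfig(diff_tolerated=tol, ris_trigger=None))
            assert previous <= edges
            previous = edges

    def test_group_contributes_full_clique_and_estimate_is_lower_bound(self):
        for x in (2, 5, 20):
            profs = _profiles({f"q{i}": (True, True) for i in range(x)})
            edges = profile_interactions(profs, ProfileConfig(ris_trigger=None))
            assert len(edges) == x * (x - 1) // 2
            assert profile_edge_estimate(x) <= len(edges)


class TestProfileEdgeEstimate:
    @pytest.mark.parametrize("x,expected", [(500, 124251), (700, 243951), (3, 1), (2, 0)])
    def test_formula_values(self, x, expected):
        assert profile_edge_estimate(x) == expected

    def test_too_small_profile_raises(self):
        with pytest.raises(ValueError):
            profile_edge_estimate(1)


class TestNeighborhoodInteractions:
    def test_conserved_order_yields_window_edges(self):
        seqs = [f"{aa}{aa}{aa}{aa}" for aa in "ACDEFGHIKL"]  # 10 distinct genes
        target = _genome("g0", seqs)
        other = _genome("g1", seqs)
        edges = neighborhood_interactions(target, [other], _seq_predicate)
        # brute-force oracle: every pair within a shared w1-window is conserved
        cfg = NeighborhoodConfig()
        expected = set()
        n = len(seqs)
        for i in range(n):
            left = cfg.w1 // 2
            lo, hi = max(0, i - left), min(n, i + (cfg.w1 - 1 - left) + 1)
            window = [w for w in range(lo, hi) if w != i]
            if len(window) >= cfg.cw1:
                for w in window:
                    expected.add(canonical_pair(f"p{i}", f"p{w}"))
        assert edges == expected
        assert len(edges) > 0

    def test_no_shared_proteins_no_edges(self):
        target = _genome("g0", ["AAAA", "CCCC", "DDDD", "EEEE", "FFFF"])
        other = _genome("g1", ["GGGG", "HHHH", "IIII", "KKKK", "LLLL"])
        assert neighborhood_interactions(target, [other], _seq_predicate) == set()

    def test_quota_not_met_no_edges(self):
        # only 3 conserved genes in any window, cw1 = 4
        target = _genome("g0", ["AAAA", "CCCC", "DDDD", "EEEE"])
        other = _genome("g1", ["AAAA", "CCCC", "DDDD", "EEEE"])
        cfg = NeighborhoodConfig(w1=10, cw1=4)
        assert neighborhood_interactions(target, [other], _seq_predicate, cfg) == set()

    def test_dynamic_expansion_finds_conserved_block(self):
        seqs = [f"{aa}{aa}{aa}{aa}" for aa in "ACDEFGHIKL"]
        target = _genome("g0", seqs)
        other = _genome("g1", seqs)
        fixed = neighborhood_interactions(
            target, [other], _seq_predicate, NeighborhoodConfig(expansion="fixed")
        )
        dynamic = neighborhood_interactions(
            target, [other], _seq_predicate, NeighborhoodConfig(expansion="dynamic")
        )
        assert dynamic  # the growing window reaches the quota
        assert dynamic <= fixed

    def test_w1_smaller_than_cw1_raises(self):
        with pytest.raises(ValueError):
            NeighborhoodConfig(w1=3, cw1=4)


class TestAssembleNetwork:
    def test_evidence_union_on_duplicate_edge(self):
        net = assemble_network(
            {"profile": [("A", "B")], "neighborhood": [("B", "A")]},
            genome_id="g0",
        )
        assert net.edges == {("A", "B")}
        assert net.evidence[("A", "B")] == frozenset({"profile", "neighborhood"})

    def test_empty_inputs_empty_network(self):
        net = assemble_network({}, genome_id="g0")
        assert net.nodes == set() and net.n_edges == 0

    def test_hand_enumerated_counts(self):
        net = assemble_network(
            {
                "profile": [("a", "b"), ("b", "c")],
                "neighborhood": [("c", "b"), ("d", "e")],
                "extra": [("a", "b")],
            },
            genome_id="g0",
        )
        assert len(net.nodes) == 5
        assert net.n_edges == 3

    def test_foreign_endpoint_raises(self):
        with pytest.raises(ValueError, match="zz"):
            assemble_network({"profile": [("a", "zz")]}, genome_id="g0", valid_ids={"a", "b"})

    def test_isolated_nodes_excluded_by_default(self):
        net = assemble_network({"profile": [("a", "b")]}, genome_id="g0")
        assert net.nodes == {"a", "b"}


class TestInteractionNetworkInvariants:
    def test_self_loop_rejected(self):
        net = InteractionNetwork("g0")
        with pytest.raises(ValueError):
            net.add_edge("a", "a")

    def test_deduplication(self):
        net = InteractionNetwork("g0")
        net.add_edge("a", "b", {"profile"})
        net.add_edge("b", "a", {"neighborhood"})
        assert net.n_edges == 1
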