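"""Simulator, event classification, and the simple/inferable history
correspondence."""

from fractions import Fraction

import pytest

from isorec.histories import (
    EventClass,
    SimParams,
    admits_positive_simple,
    classify_species_node,
    derive_input,
    expand_to_simple,
    extended_inverse,
    inferable_version,
    is_inferable,
    simulate_simple_history,
)
from isorec.rooted_recon import History, histories_equal, verify_isometric
from isorec.tree_model import (
    LeafMap,
    PhyloTree,
    TreePoint,
    parse_leaf_map,
    parse_newick,
    validate_input,
    write_newick,
)
from isorec.unrooted_gene_recon import reconcile_unrooted_gene
from isorec.tree_model import InputPartialHistory

from conftest import sim_inferable


def duplication_above_fixture():
    """A history with a duplication strictly between the two speciations:
    both surviving copies descend into species c, crossing speciation x.
    The extended inverse of x is exactly the two crossing points at
    distance 2 above the gene leaves."""
    S = PhyloTree()
    r = S.add_node("r")
    d = S.add_node("D")
    x = S.add_node("x")
    a = S.add_node("a")
    b = S.add_node("b")
    c = S.add_node("c")
    S.add_edge(r, d, Fraction(1, 2))
    S.add_edge(d, x, Fraction(1, 2))
    S.add_edge(x, b, 2)
    S.add_edge(x, c, 2)
    S.add_edge(r, a, 3)
    S.set_root(r)
    G = PhyloTree()
    q = G.add_node("q")
    y = G.add_node("y")
    c1 = G.add_node("c1")
    c2 = G.add_node("c2")
    a1 = G.add_node("a1")
    G.add_edge(q, y, Fraction(1, 2))
    G.add_edge(y, c1, Fraction(5, 2))
    G.add_edge(y, c2, Fraction(5, 2))
    G.add_edge(q, a1, 3)
    G.set_root(q)
    phi = {q: r, y: d, c1: c, c2: c, a1: a}
    return History(G, S, phi)


class TestSimulator:
    def test_no_events_gives_isomorphic_trees(self):
        h = simulate_simple_history(
            SimParams(n_species=3, dup_rate=0, loss_rate=0, seed=1,
                      min_extant_genes=1)
        )
        assert len(h.gene) == len(h.species)
        # mapping is the isomorphism: depths agree node-for-node
        for g, s in h.phi.items():
            assert h.gene.depth(g) == h.species.depth(s)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_every_node_is_a_single_event(self, seed):
        h = simulate_simple_history(
            SimParams(n_species=3 + seed % 6, dup_rate=0.6, loss_rate=0.5,
                      seed=seed)
        )
        for v in h.species.nodes():
            cls = classify_species_node(h, v)
            assert cls == h.events[v]
            assert cls != EventClass.OTHER

    def test_guard_keeps_at_least_one_survivor(self):
        h = simulate_simple_history(
            SimParams(n_species=3, dup_rate=0.1, loss_rate=3.0, seed=2,
                      min_extant_genes=1)
        )
        extant = [
            u for u in h.gene.leaves() if not h.species.children(h.phi[u])
        ]
        assert len(extant) >= 1

    def test_determinism(self):
        p = SimParams(n_species=5, dup_rate=0.5, loss_rate=0.4, seed=77)
        assert histories_equal(
            simulate_simple_history(p), simulate_simple_history(p)
        )

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_simulated_mapping_is_isometric(self, seed):
        h = simulate_simple_history(
            SimParams(n_species=5, dup_rate=0.5, loss_rate=0.4, seed=seed)
        )
        assert verify_isometric(h) is None


class TestClassification:
    def test_duplication_pattern(self):
        h = duplication_above_fixture()
        d = h.species.node_by_label("D")
        assert classify_species_node(h, d) == EventClass.DUPLICATION

    def test_sample_and_speciation(self):
        h = duplication_above_fixture()
        assert classify_species_node(
            h, h.species.node_by_label("b")
        ) == EventClass.SAMPLE
        # r has preimage q splitting into the two sides: a true speciation
        assert classify_species_node(
            h, h.species.node_by_label("r")
        ) == EventClass.SPECIATION

    def test_bypassed_speciation_is_generalized_only(self):
        """x has empty preimage but two gene edges cross it, so it is a
        generalized speciation but not a speciation."""
        h = duplication_above_fixture()
        x = h.species.node_by_label("x")
        assert classify_species_node(h, x) == EventClass.GENERALIZED_SPECIATION

    def test_extended_inverse_crossing_points(self):
        h = duplication_above_fixture()
        x = h.species.node_by_label("x")
        c1 = h.gene.node_by_label("c1")
        c2 = h.gene.node_by_label("c2")
        assert extended_inverse(h, x) == {
            TreePoint(c1, 2),
            TreePoint(c2, 2),
        }

    def test_extended_inverse_trivial_cases(self):
        h = duplication_above_fixture()
        r = h.species.node_by_label("r")
        q = h.gene.node_by_label("q")
        # no crossing edges at the root: equals the plain inverse
        assert extended_inverse(h, r) == {TreePoint(q)}
        # nothing above the root's images
        S2, phi = h.species, h.phi
        b = S2.node_by_label("b")
        assert extended_inverse(h, b) == set()


class TestInferable:
    def test_no_loss_binary_history_is_fixed_point(self):
        h = simulate_simple_history(
            SimParams(n_species=4, dup_rate=0, loss_rate=0, seed=3,
                      min_extant_genes=1)
        )
        hi = inferable_version(h)
        assert histories_equal(h, hi)

    def test_pre_speciation_duplication_keeps_one_child_node(self):
        h = duplication_above_fixture()
        hi = inferable_version(h)
        # D has a preimage, so it survives as a one-child node
        d = hi.species.node_by_label("D")
        assert d is not None and len(hi.species.children(d)) == 1
        assert is_inferable(hi)

    def test_loss_leaf_not_inferable(self):
        h = duplication_above_fixture()
        # graft a loss: a gene leaf mapping to an internal species node
        x = h.species.node_by_label("x")
        y = h.gene.node_by_label("y")
        lost = h.gene.add_node("lost")
        h.gene.add_edge(y, lost, Fraction(1, 2))
        h.phi[lost] = x
        assert not is_inferable(h)

    def test_zero_length_edge_not_inferable(self):
        h = duplication_above_fixture()
        y = h.gene.node_by_label("y")
        c1 = h.gene.node_by_label("c1")
        h.gene._adj[y][c1] = Fraction(0)
        h.gene._adj[c1][y] = Fraction(0)
        assert not is_inferable(h)

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_simulated_histories_reduce_to_inferable(self, seed):
        hi = sim_inferable(seed)
        assert is_inferable(hi)
        assert admits_positive_simple(hi)


class TestClaimCorrespondence:
    @pytest.mark.parametrize("seed", range(1, 101))
    def test_expand_round_trip(self, seed):
        """Expanding an inferable history to a simple one and reducing it
        back is the identity."""
        hi = sim_inferable(seed)
        hs = expand_to_simple(hi)
        assert all(e != EventClass.OTHER for e in hs.events.values())
        assert histories_equal(inferable_version(hs), hi)

    def test_expansion_of_bypass_fixture(self):
        hi = inferable_version(duplication_above_fixture())
        hs = expand_to_simple(hi)
        assert all(e != EventClass.OTHER for e in hs.events.values())
        assert histories_equal(inferable_version(hs), hi)
        # the bypassed speciation acquired loss leaves
        losses = [
            v for v, e in hs.events.items() if e == EventClass.LOSS
        ]
        assert losses

    def test_coincident_duplication_speciation_is_not_positive_simple(
        self, fixture_species
    ):
        """A duplication mapped exactly onto a speciation node cannot come
        from a positive-branch-length simple history."""
        g = parse_newick("(b2:4)b1;", rooted=False)
        lm = LeafMap.from_dict({"b1": "B", "b2": "B"})
        h = reconcile_unrooted_gene(
            InputPartialHistory(g, fixture_species, lm)
        )
        assert is_inferable(h)
        assert not admits_positive_simple(h)
        x = h.species.node_by_label("x")
        assert classify_species_node(h, x) == EventClass.OTHER

    def test_no_event_history_is_positive_simple(self):
        h = simulate_simple_history(
            SimParams(n_species=3, dup_rate=0, loss_rate=0, seed=9,
                      min_extant_genes=1)
        )
        assert admits_positive_simple(inferable_version(h))


class TestDeriveInput:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_outputs_satisfy_input_contract(self, seed):
        hi = sim_inferable(seed)
        for kw in [
            {},
            {"unroot_gene": True},
            {"unroot_gene": True, "unroot_species": True},
        ]:
            assert validate_input(derive_input(hi, **kw)) == []

    def test_no_duplication_history_keeps_species_tree(self):
        h = simulate_simple_history(
            SimParams(n_species=4, dup_rate=0, loss_rate=0, seed=5,
                      min_extant_genes=1)
        )
        hi = inferable_version(h)
        iph = derive_input(hi)
        assert write_newick(iph.species) == write_newick(hi.species)

    def test_multifurcating_root_survives_unrooting(self):
        """A gene root with three children stays an ordinary node."""
        S = parse_newick("((B:2,C:2)x:1,A:3)r;")
        G = PhyloTree()
        q = G.add_node(None)
        for lbl, ln in [("b1", 3), ("c1", 3), ("a1", 3)]:
            G.add_edge(q, G.add_node(lbl), ln)
        G.set_root(q)
        phi = {
            q: S.node_by_label("r"),
            G.node_by_label("b1"): S.node_by_label("B"),
            G.node_by_label("c1"): S.node_by_label("C"),
            G.node_by_label("a1"): S.node_by_label("A"),
        }
        h = History(G, S, phi)
        iph = derive_input(h, unroot_gene=True)
        assert len(iph.gene) == len(G)
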