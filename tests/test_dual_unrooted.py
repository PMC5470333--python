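"""Doubly-unrooted reconciliation: parametric point arithmetic, interval
splitting, and the solution set over all species-root positions."""

from fractions import Fraction

import pytest

from isorec.dual_unrooted_recon import (
    CandidateInterval,
    EdgeCtx,
    Instrument,
    ParametricHistory,
    Rejection,
    evaluate_at,
    param_anc,
    reconcile_both_unrooted,
    simulate_interval,
    solve_breakpoint,
    ALLOWED_EPS_SLOPES,
    _root_at_edge_point,
)
from isorec.histories import derive_input
from isorec.rooted_recon import histories_equal, history_signature
from isorec.tree_model import (
    InputPartialHistory,
    LeafMap,
    PhyloTree,
    TreePoint,
    parse_newick,
)

from conftest import sim_inferable, true_root_position


def caterpillar_ctx():
    """Species: l -1- xa -5- xb -2- m; gene: a single edge l_1 -9- m_1."""
    S = PhyloTree()
    xa, xb = S.add_node("xa"), S.add_node("xb")
    l, m = S.add_node("l"), S.add_node("m")
    S.add_edge(xa, xb, 5)
    S.add_edge(xa, l, 1)
    S.add_edge(xb, m, 2)
    G = PhyloTree()
    g1, g2 = G.add_node("l_1"), G.add_node("m_1")
    G.add_edge(g1, g2, 9)
    lm = LeafMap.from_dict({"l_1": "l", "m_1": "m"})
    iph = InputPartialHistory(G, S, lm)
    return EdgeCtx(iph, xa, xb), iph, (xa, xb)


class TestParamAnc:
    def test_three_cases(self):
        ctx, _, edge = caterpillar_ctx()
        lpt = TreePoint(ctx.S.node_by_label("l"))
        full = CandidateInterval(edge, Fraction(0), Fraction(5))
        assert param_anc(ctx, lpt, 4, full) == ("split", Fraction(3))
        low = CandidateInterval(edge, Fraction(0), Fraction(3))
        kind, form = param_anc(ctx, lpt, 4, low)
        assert kind == "param" and (form.d, form.c) == (3, -1)
        high = CandidateInterval(edge, Fraction(3), Fraction(5))
        kind, pt = param_anc(ctx, lpt, 4, high)
        assert kind == "fixed"
        # the fixed point sits 3 from x_a on the root edge = 2 above x_b
        assert pt == TreePoint(ctx.xb, Fraction(2))

    def test_other_side_mirrored(self):
        ctx, _, edge = caterpillar_ctx()
        mpt = TreePoint(ctx.S.node_by_label("m"))
        # d=4 from m: 2 to reach x_b, then 2 along the edge toward x_a
        kind, rho = param_anc(ctx, mpt, 4, CandidateInterval(edge, 0, 5))
        assert (kind, rho) == ("split", Fraction(3))
        kind, form = param_anc(ctx, mpt, 4, CandidateInterval(edge, 0, 3))
        assert kind == "fixed"
        kind, form = param_anc(ctx, mpt, 4, CandidateInterval(edge, 3, 5))
        assert kind == "param" and (form.d, form.c) == (-3, 1)


class TestSolveBreakpoint:
    def test_inside(self):
        I = CandidateInterval((0, 1), Fraction(0), Fraction(5))
        assert solve_breakpoint(3, -1, 1, 1, I) == 1

    def test_outside(self):
        I = CandidateInterval((0, 1), Fraction(2), Fraction(5))
        assert solve_breakpoint(3, -1, 1, 1, I) is None

    def test_boundary_hit_is_none(self):
        I = CandidateInterval((0, 1), Fraction(0), Fraction(5))
        assert solve_breakpoint(2, -1, 2, 1, I) is None


class TestSimulateInterval:
    def test_two_leaf_continuum(self):
        """With a single species edge and a longer two-gene edge, every
        interior root position is accepted with one parametric solution
        (the gene root slides along its edge as a duplication above the
        species root)."""
        S = PhyloTree()
        a, b = S.add_node("A"), S.add_node("B")
        S.add_edge(a, b, 5)
        G = PhyloTree()
        g1, g2 = G.add_node("a1"), G.add_node("b1")
        G.add_edge(g1, g2, 9)
        lm = LeafMap.from_dict({"a1": "A", "b1": "B"})
        iph = InputPartialHistory(G, S, lm)
        edge = (a, b)
        pieces = simulate_interval(
            iph, CandidateInterval(edge, Fraction(0), Fraction(5))
        )
        accepted = [
            ci for ci, res in pieces if isinstance(res, ParametricHistory)
        ]
        assert accepted
        for ci, res in pieces:
            if isinstance(res, ParametricHistory):
                mid = (ci.lo + ci.hi) / 2
                h = evaluate_at(res, mid)
                fixed = _root_at_edge_point(iph, edge, mid)
                assert fixed is not None
                assert histories_equal(h, fixed)

    @pytest.mark.parametrize("seed", range(1, 26))
    def test_sampled_instantiation_matches_fixed_runs(self, seed):
        hi = sim_inferable(seed, max_genes=12)
        iph = derive_input(hi, unroot_gene=True, unroot_species=True)
        for edge in sorted(iph.species.edges()):
            L = iph.species.edge_length(*edge)
            pieces = simulate_interval(iph, CandidateInterval(edge, Fraction(0), L))
            # partition property: pieces tile (0, L)
            assert pieces[0][0].lo == 0 and pieces[-1][0].hi == L
            for (a, _), (b, _) in zip(pieces, pieces[1:]):
                assert a.hi == b.lo
            for ci, res in pieces:
                assert ci.lo < ci.hi
                samples = [
                    ci.lo + (ci.hi - ci.lo) * f
                    for f in (Fraction(1, 4), Fraction(1, 2), Fraction(4, 5))
                ]
                for rho in samples:
                    fixed = _root_at_edge_point(iph, edge, rho)
                    if isinstance(res, ParametricHistory):
                        assert fixed is not None
                        assert histories_equal(evaluate_at(res, rho), fixed)
                    else:
                        assert fixed is None

    def test_eps_slopes_within_printed_set(self):
        inst = Instrument()
        for seed in range(1, 16):
            hi = sim_inferable(seed, max_genes=12)
            iph = derive_input(hi, unroot_gene=True, unroot_species=True)
            for edge in sorted(iph.species.edges()):
                L = iph.species.edge_length(*edge)
                simulate_interval(
                    iph, CandidateInterval(edge, Fraction(0), L), inst
                )
        assert inst.eps_slopes <= ALLOWED_EPS_SLOPES


class TestEvaluateAt:
    def _any_parametric(self, seed=2):
        hi = sim_inferable(seed, max_genes=12)
        iph = derive_input(hi, unroot_gene=True, unroot_species=True)
        for edge in sorted(iph.species.edges()):
            L = iph.species.edge_length(*edge)
            for ci, res in simulate_interval(
                iph, CandidateInterval(edge, Fraction(0), L)
            ):
                if isinstance(res, ParametricHistory):
                    return res, ci
        pytest.skip("no accepted interval in this instance")

    def test_boundary_is_a_contract_error(self):
        res, ci = self._any_parametric()
        with pytest.raises(ValueError):
            evaluate_at(res, ci.lo)

    def test_two_offsets_differ_only_in_lengths(self):
        res, ci = self._any_parametric()
        r1 = ci.lo + (ci.hi - ci.lo) / 3
        r2 = ci.lo + (ci.hi - ci.lo) * Fraction(2, 3)
        h1, h2 = evaluate_at(res, r1), evaluate_at(res, r2)

        def shape(sig):
            if isinstance(sig, tuple):
                return tuple(shape(x) for x in sig)
            return None if isinstance(sig, Fraction) else sig

        assert shape(history_signature(h1)) == shape(history_signature(h2))
        assert history_signature(h1) != history_signature(h2)


class TestSolutionSet:
    def test_unique_node_root(self):
        """Paired gene copies in every species pin the root to the single
        internal node; every edge position is rejected (the root cannot
        slide into an edge because the gene root is a fixed multifurcating
        node)."""
        S = PhyloTree()
        y = S.add_node("y")
        for lbl, ln in [("A", 1), ("B", 2), ("C", 3)]:
            S.add_edge(y, S.add_node(lbl), ln)
        G = PhyloTree()
        x = G.add_node(None)
        for lbl, ln in [("a1", 1), ("a2", 1), ("b1", 2), ("b2", 2),
                        ("c1", 3), ("c2", 3)]:
            G.add_edge(x, G.add_node(lbl), ln)
        lm = LeafMap.from_dict(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        )
        sol = reconcile_both_unrooted(InputPartialHistory(G, S, lm))
        assert sol.accepts_node(y)
        for edge, entries in sol.edge_results.items():
            for kind, key, res in entries:
                if kind == "interval":
                    assert isinstance(res, Rejection)
                else:
                    assert res is None

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_true_root_recovered(self, seed):
        hi = sim_inferable(seed, max_genes=12)
        iph = derive_input(hi, unroot_gene=True, unroot_species=True)
        sol = reconcile_both_unrooted(iph)
        pos = true_root_position(hi)
        if pos[0] == "node":
            assert sol.accepts_node(pos[1])
            assert histories_equal(sol.node_results[pos[1]], hi)
            return
        (c1, c2), rho = pos[1], pos[2]
        eo = (c1, c2) if (c1, c2) in sol.edge_results else (c2, c1)
        r = rho if eo == (c1, c2) else iph.species.edge_length(c1, c2) - rho
        assert sol.accepts_edge_point(eo, r)
        L = iph.species.edge_length(*eo)
        if r == 0:
            h = sol.node_results[eo[0]]
        elif r == L:
            h = sol.node_results[eo[1]]
        else:
            h = _root_at_edge_point(iph, eo, r)
            if h is None:
                for kind, key, res in sol.edge_results[eo]:
                    if kind == "interval" and key.lo < r < key.hi:
                        h = evaluate_at(res, r)
        assert h is not None and histories_equal(h, hi)

    def test_single_species_gene_family(self, fixture_species):
        """All genes in one species: duplication-only rootings remain
        possible on the pendant edge."""
        S = PhyloTree()
        a, b = S.add_node("A"), S.add_node("B")
        S.add_edge(a, b, 6)
        G = parse_newick("(b2:4)b1;", rooted=False)
        lm = LeafMap.from_dict({"b1": "B", "b2": "B"})
        sol = reconcile_both_unrooted(InputPartialHistory(G, S, lm))
        edge = next(iter(sol.edge_results))
        probes = [Fraction(1), Fraction(3), Fraction(5)]
        for rho in probes:
            fixed = _root_at_edge_point(
                InputPartialHistory(G, S, lm), edge, rho
            )
            assert sol.accepts_edge_point(edge, rho) == (fixed is not None)

    @pytest.mark.parametrize("seed", [2, 7, 13])
    def test_explicit_species_chain_order(self, seed):
        """With the explicit-species option, every accepted interval carries
        the above-root nodes in a fixed order: heights are non-decreasing at
        any interior offset, and instantiation is unchanged."""
        hi = sim_inferable(seed, max_genes=12)
        iph = derive_input(hi, unroot_gene=True, unroot_species=True)
        sol = reconcile_both_unrooted(iph, explicit_species=True)
        seen = 0
        for edge, entries in sol.edge_results.items():
            for kind, key, res in entries:
                if kind != "interval" or not isinstance(res, ParametricHistory):
                    continue
                assert res.param_chain is not None
                seen += 1
                for f in (Fraction(1, 3), Fraction(2, 3)):
                    rho = key.lo + (key.hi - key.lo) * f
                    heights = [form.at(rho) for form, _ in res.param_chain]
                    assert heights == sorted(heights)
                    assert all(h >= 0 for h in heights)
                    fixed = _root_at_edge_point(iph, edge, rho)
                    assert fixed is not None
                    assert histories_equal(evaluate_at(res, rho), fixed)
        assert seen > 0

    def test_merged_runs_cover_accepted_probes(self):
        """Merged maximal runs agree with pointwise acceptance."""
        hi = sim_inferable(4, max_genes=12)
        iph = derive_input(hi, unroot_gene=True, unroot_species=True)
        sol = reconcile_both_unrooted(iph)
        for edge, runs in sol.merged.items():
            L = iph.species.edge_length(*edge)
            for run in runs:
                assert 0 <= run.lo <= run.hi <= L
                if run.lo < run.hi:
                    mid = (run.lo + run.hi) / 2
                    assert sol.accepts_edge_point(edge, mid)
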