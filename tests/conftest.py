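from fractions import Fraction

import pytest

from isorec.histories import SimParams, derive_input, inferable_version, simulate_simple_history
from isorec.tree_model import InputPartialHistory, parse_leaf_map, parse_newick


@pytest.fixture
def fixture_species():
    """Small rooted species tree: ((B:2,C:2)x:1,A:3)r."""
    return parse_newick("((B:2,C:2)x:1,A:3)r;")


@pytest.fixture
def fixture_gene_rooted():
    return parse_newick("((b1:2,c1:2)y:1,a1:3)q;")


@pytest.fixture
def fixture_iph(fixture_species, fixture_gene_rooted):
    lm = parse_leaf_map(
        "b1\tB\nc1\tC\na1\tA", fixture_gene_rooted, fixture_species
    )
    return InputPartialHistory(fixture_gene_rooted, fixture_species, lm)


def sim_inferable(seed, n_species=None, dup=0.5, loss=0.4, max_genes=None, **kw):
    """An inferable history from the simulator, seeded; the default sizes
    match the desk-scale study conditions."""
    p = SimParams(
        n_species=n_species if n_species is not None else 3 + seed % 6,
        dup_rate=dup,
        loss_rate=loss,
        seed=seed,
        max_extant_genes=max_genes,
        **kw,
    )
    return inferable_version(simulate_simple_history(p))


def true_root_position(hi):
    """Locate the original species root relative to the unrooted derived
    species tree: ('node', id) or ('edge', (c1, c2), offset_from_c1).
    Node ids are preserved by derive_input's copies."""
    rooted = derive_input(hi).species
    kids = rooted.children(rooted.root)
    if len(kids) != 2:
        return ("node", rooted.root)
    c1, c2 = kids
    return ("edge", (c1, c2), rooted.edge_length(rooted.root, c1))
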