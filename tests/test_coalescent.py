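import math

import numpy as np
import pandas as pd
import pytest

from avigc.coalescent import (branch_id, coalescent_branch_lengths,
                              count_branch_lineages, filter_branches,
                              ne_table, reconstruct_ne)
from avigc.io import read_tree
from avigc.trees import LabeledTree, TreeNode


def spnwk(nwk):
    return read_tree(nwk, "my")


def test_concordant_tree_coalesces_in_branch(tree3):
    gene = read_tree("((A:1,B:1):1,C:2);")
    counts = count_branch_lineages(tree3, gene)
    ab = [k for k in counts if k.startswith("clade") or k == "90"]
    # AB branch: 1 lineage rootward, 2 tipward -> n12 type
    key = [k for k in counts if k not in ("A", "B", "C")][0]
    assert counts[key] == (1, 2)


def test_discordant_tree_forces_deep_coalescence(tree3):
    gene = read_tree("((A:1,C:1):1,B:2);")
    key = [k for k in count_branch_lineages(tree3, gene)
           if k not in ("A", "B", "C")][0]
    assert count_branch_lineages(tree3, gene)[key] == (2, 2)


def test_unknown_tip_is_error(tree3):
    gene = read_tree("((A:1,X:1):1,C:2);")
    with pytest.raises(ValueError, match="unknown"):
        count_branch_lineages(tree3, gene)


# -- independent set-algebra oracle ------------------------------------

def _tipsets(tree):
    out = {}
    for node in tree.postorder():
        out[id(node)] = (frozenset([node.label]) if node.is_leaf else
                         frozenset().union(*[out[id(c)]
                                             for c in node.children]))
    return out


def oracle_counts(species_tree, gene_tree):
    """Lineage counts from explicit tip-set algebra (the oracle).

    An edge (c -> p) of the gene tree exits the top of the species branch
    above v iff tips(c) lies inside clade(v) while tips(p) does not; it
    enters the bottom iff tips(c) lies inside a single child clade of v
    while tips(p) is in no single child clade. Sampled tips enter their
    own terminal branch.
    """
    sp_sets = _tipsets(species_tree)
    g_sets = _tipsets(gene_tree)
    out = {}
    for v in species_tree.postorder():
        if v.parent is None:
            continue
        Sv = sp_sets[id(v)]
        children = [sp_sets[id(c)] for c in v.children]
        top = bottom = 0
        for c in gene_tree.postorder():
            if c.parent is None:
                continue
            tc, tp = g_sets[id(c)], g_sets[id(c.parent)]
            if tc <= Sv and not tp <= Sv:
                top += 1
            below = any(tc <= S for S in children)
            p_below = any(tp <= S for S in children)
            if below and not p_below:
                bottom += 1
        if v.is_leaf:
            bottom += sum(1 for t in gene_tree.tips() if t.label == v.label)
        out[branch_id(v)] = (top, bottom)
    return out


def _random_topology(labels, rng):
    nodes = [TreeNode(label=x) for x in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = TreeNode()
        p.add_child(nodes[i])
        p.add_child(nodes.pop(j))
        nodes[i] = p
    return LabeledTree(nodes[0])


def test_counts_match_set_algebra_oracle(rng):
    labels = list("ABCDEF")
    species = _random_topology(labels, rng)
    for _ in range(60):
        keep = [x for x in labels if rng.random() > 0.2]
        if len(keep) < 2:
            continue
        gene = _random_topology(keep, rng)
        got = count_branch_lineages(species, gene)
        want = oracle_counts(species, gene)
        assert got == want


# -- estimator arithmetic ----------------------------------------------

def _three_taxon_with_counts(n12, nkk, rng):
    sp = spnwk("((A:1,B:1)ab:1,C:2);")
    conc = read_tree("((A:1,B:1):1,C:2);")
    disc = read_tree("((A:1,C:1):1,B:2);")
    return sp, [conc] * n12 + [disc] * nkk


def test_raw_formula_arithmetic(rng):
    sp, gts = _three_taxon_with_counts(500, 500, rng)
    stats = {s.branch_id: s
             for s in coalescent_branch_lengths(sp, gts,
                                                correction="none")}
    s = stats["ab"]
    assert (s.n12, s.nkk) == (500, 500)
    assert s.coalescent_length == pytest.approx(math.log(2))


def test_no_coalescence_signal_gives_zero_length():
    sp, gts = _three_taxon_with_counts(0, 500, None)
    for corr in ("none", "discordance"):
        s = {x.branch_id: x for x in coalescent_branch_lengths(
            sp, gts, correction=corr)}["ab"]
        assert s.coalescent_length == 0.0


def test_no_discordance_gives_infinity():
    sp, gts = _three_taxon_with_counts(400, 0, None)
    s = {x.branch_id: x
         for x in coalescent_branch_lengths(sp, gts)}["ab"]
    assert math.isinf(s.coalescent_length)
    assert "no_discordance" in s.flags


def test_terminal_branches_undefined():
    sp, gts = _three_taxon_with_counts(5, 5, None)
    for s in coalescent_branch_lengths(sp, gts):
        if s.is_terminal:
            assert math.isnan(s.coalescent_length)


def test_adding_discordant_trees_never_increases_length():
    prev = math.inf
    for nkk in (1, 5, 20, 100, 400):
        sp, gts = _three_taxon_with_counts(300, nkk, None)
        s = {x.branch_id: x
             for x in coalescent_branch_lengths(sp, gts)}["ab"]
        assert s.coalescent_length <= prev + 1e-12
        prev = s.coalescent_length


# -- Ne reconstruction --------------------------------------------------

def _stats(length, support=90.0, cherry=True):
    from avigc.coalescent import BranchDiscordanceStats
    return BranchDiscordanceStats(
        branch_id="b", n12=10, nkk=10, coalescent_length=length,
        n_gene_trees=20, support=support, is_cherry=cherry)


def test_generation_time_formula():
    from avigc.coalescent import generation_time
    assert generation_time(2.0) == 2.0                  # maturity proxy
    assert generation_time(2.0, 0.5) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        generation_time(2.0, 1.0)


def test_ne_arithmetic():
    ne = reconstruct_ne(_stats(0.5), 1e7, 2.0, 2.0)
    assert ne.n_hat == pytest.approx(5_000_000)


def test_ne_undefined_for_degenerate_lengths():
    for bad in (0.0, math.inf, math.nan):
        ne = reconstruct_ne(_stats(bad), 1e7, 2.0, 2.0)
        assert np.isnan(ne.n_hat) and "undefined_length" in ne.flags
    with pytest.raises(ValueError):
        reconstruct_ne(_stats(0.5), -1, 2.0, 2.0)


def test_filters():
    short = _stats(0.05)
    weak = _stats(0.5, support=49.0)
    deep = _stats(0.5, cherry=True)
    noncherry = _stats(0.5, cherry=False)
    for excluded in (short, weak, noncherry):
        with pytest.warns(UserWarning, match="no branches"):
            assert filter_branches([excluded]) == []
    assert filter_branches([deep]) == [deep]
    # disabling a filter readmits the branch
    assert filter_branches([noncherry], cherry_only=False) == [noncherry]


def test_ne_rank_order_invariant_to_generation_rescale():
    stats = [_stats(L) for L in (0.2, 0.5, 1.0)]
    for i, s in enumerate(stats):
        s.branch_id = f"b{i}"
    base = pd.DataFrame({
        "branch_id": [f"b{i}" for i in range(3)],
        "time_span_my": [10.0, 8.0, 5.0],
        "gen_time_rootward_yr": [2.0, 3.0, 4.0],
        "gen_time_tipward_yr": [2.0, 3.0, 4.0]})
    t1 = ne_table(stats, base)
    scaled = base.copy()
    scaled[["gen_time_rootward_yr", "gen_time_tipward_yr"]] *= 7.5
    t2 = ne_table(stats, scaled)
    assert list(t1["n_hat_rank"]) == list(t2["n_hat_rank"])
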