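import math

import numpy as np
import pytest

from avigc import io as aio
from avigc.composition import gc_by_class, pooled_gc
from avigc.simulate import (SimulationConfig, simulate_dataset,
                            simulate_gene_trees, simulate_recomb_system,
                            simulate_species_system, simulate_alignments,
                            simulate_t92_alignment, write_dataset)
from avigc.traitstats import rank_correlation
from avigc.recomb import cross_map_correlation, assign_windows

SMALL = dict(n_species=12, n_genes=60, n_codons=60, n_introns=20,
             intron_length=120)


def test_fixed_seed_bitwise_determinism(tmp_path):
    cfg = SimulationConfig(seed=5, **SMALL)
    d1 = simulate_dataset(cfg, n_gene_trees=20)
    d2 = simulate_dataset(cfg, n_gene_trees=20)
    assert d1.species.traits.equals(d2.species.traits)
    assert d1.alignments[0].sequences == d2.alignments[0].sequences
    assert d1.gene_trees[3].newick() == d2.gene_trees[3].newick()
    w1, w2 = tmp_path / "a", tmp_path / "b"
    write_dataset(d1, w1)
    write_dataset(d2, w2)
    f = "coding/g00001.fa"
    assert (w1 / f).read_bytes() == (w2 / f).read_bytes()


def test_generated_data_pass_readers(tmp_path):
    cfg = SimulationConfig(seed=6, **SMALL)
    data = simulate_dataset(cfg, n_gene_trees=10)
    write_dataset(data, tmp_path)
    aln = aio.read_alignment(tmp_path / "coding" / "g00001.fa", "coding")
    assert aln.length == cfg.n_codons * 3
    tree = aio.read_tree(tmp_path / "species.nwk", "my")
    assert tree.n_tips == cfg.n_species
    aio.read_trait_table(tmp_path / "traits.tsv")
    aio.read_recomb_map(tmp_path / "recomb_ref1.tsv")
    aio.read_locations(tmp_path / "locations.tsv")


def test_mass_theta_association_strength(rng):
    neg = 0
    for seed in range(12):
        cfg = SimulationConfig(seed=seed)
        sys = simulate_species_system(cfg)
        mass = sys.traits.set_index("species")["body_mass_g"]
        rho = rank_correlation(mass, sys.tip_theta.reindex(mass.index))
        neg += rho.estimate < -0.5
    assert neg >= 11    # default effect: strongly negative almost always


def test_zero_effect_gives_null_association():
    rhos = []
    for seed in range(12):
        cfg = SimulationConfig(seed=seed, mass_effect=0.0)
        sys = simulate_species_system(cfg)
        mass = sys.traits.set_index("species")["body_mass_g"]
        rhos.append(rank_correlation(
            mass, sys.tip_theta.reindex(mass.index)).estimate)
    assert np.mean(np.abs(rhos)) < 0.3


def test_msc_discordance_matches_closed_form(rng):
    sp = aio.read_tree("((A:1,B:1)ab:1,C:2);", "my")
    for T, tol_extra in ((1.0, 0.0), (10.0, 0.0)):
        for n in sp.postorder():
            if n.parent is not None:
                n.annotations["coal_T"] = T
        gts = simulate_gene_trees(sp, 8000, rng)
        disc = 0
        for gt in gts:
            pair = sorted(
                sorted(t.label for t in c.children)
                for c in gt.root.children if not c.is_leaf)[0]
            disc += pair != ["A", "B"]
        expect = (2 / 3) * math.exp(-T)
        se = math.sqrt(max(expect * (1 - expect), 1e-9) / 8000)
        assert abs(disc / 8000 - expect) <= 3 * se + 1e-3


def test_stationary_when_multiplier_zero(rng):
    cfg = SimulationConfig(seed=9, n_species=10, n_genes=40, n_codons=120)
    sys = simulate_species_system(cfg)
    alns, _ = simulate_alignments(sys, cfg, np.zeros(cfg.n_genes),
                                  rng, classes=("c3",))
    pooled = pooled_gc(alns, "c3")
    assert np.allclose(pooled.values, cfg.theta_ancestral, atol=0.02)


def test_event_log_totals_match_observed_divergence(rng):
    tree = aio.read_tree("(A:0.2,B:0.2);", "substitutions")
    codes, taxa, events = simulate_t92_alignment(tree, 0.5, 2.0, 20000,
                                                 rng, log_events=True)
    # every endpoint difference requires at least one logged event
    diffs = (codes[0] != codes[1]).sum()
    assert events[["n_ws", "n_sw"]].values.sum() <= 0.6 * 20000
    assert events[["n_ws", "n_sw"]].values.sum() > 0.2 * diffs


def test_cross_map_rho_near_target():
    got = []
    for seed in (1, 2, 3):
        cfg = SimulationConfig(seed=seed)
        rs = simulate_recomb_system(cfg, np.random.default_rng(seed))
        ja = assign_windows(rs.locations[rs.locations.reference == "ref1"],
                            rs.maps["ref1"])
        jb = assign_windows(rs.locations[rs.locations.reference == "ref2"],
                            rs.maps["ref2"])
        got.append(cross_map_correlation(ja, jb).estimate)
    assert abs(np.mean(got) - 0.4) < 0.1


def test_zero_coupling_nulls_rate_link():
    cfg = SimulationConfig(seed=4, multiplier_sd=0.0)
    rs = simulate_recomb_system(cfg, np.random.default_rng(4))
    # shuffle multipliers to break the link: sd(GC3)-rate rho centred on 0
    rng2 = np.random.default_rng(5)
    decoupled = rng2.permutation(rs.multipliers)
    sys = simulate_species_system(SimulationConfig(seed=4))
    cfg2 = SimulationConfig(seed=4)
    alns, _ = simulate_alignments(sys, cfg2, decoupled,
                                  np.random.default_rng(6),
                                  classes=("c3",))
    import pandas as pd
    sd = pd.Series({a.ortholog_id:
                    gc_by_class(a, "c3")["gc_fraction"].std()
                    for a in alns[:400]})
    rate = pd.Series(rs.gene_rate[:400],
                     index=[a.ortholog_id for a in alns[:400]])
    res = rank_correlation(rate, sd)
    assert abs(res.estimate) < 0.15
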