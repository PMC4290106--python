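"""Simulation studies validating each estimator in the package.

Every function here generates its own data under known truth, runs the
relevant estimator through the public API, and returns the measured
quantities as a plain dict. They are used by the test suite and by
scripts that summarise how well each method recovers what it claims to
recover; problem sizes are chosen so the whole battery runs on one CPU
in a few minutes (the trait-correlation power study is the exception and
dominates the runtime).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .bgc import (GBGCDynamics, dynamics_from_population,
                  fixation_probability, iterate_gc, wright_fisher_fixation)
from .coalescent import coalescent_branch_lengths, ne_table
from .composition import pooled_gc
from .io import read_tree
from .simulate import (SimulationConfig, simulate_dataset,
                       simulate_gene_trees, simulate_t92_alignment,
                       _random_ultrametric_tree)
from .substitution import T92Model, gc3_star
from .traitstats import gc3_conservation_index, rank_correlation

WEAK_STRONG = ((0, 3), (1, 2))


def _seed(base, k):
    return (int(base) * 1000003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Coalescent branch-length recovery
# ---------------------------------------------------------------------------

def coalescent_length_recovery(seed, n_genes: int = 10_000,
                               t_grid=(0.2, 0.5, 1.0, 2.0)) -> dict:
    """Estimate a known internal branch length from gene-tree discordance.

    Four taxa; the (A,B) branch length varies over ``t_grid`` while the
    surrounding branches are long (the pair that fails to coalesce mixes
    with a single extra lineage, the regime in which the discordance
    correction is exact). Reports estimate, error and the 3-binomial-SE
    band per level.
    """
    rows = []
    for k, T in enumerate(t_grid):
        sp = read_tree("(((A:1,B:1)ab:1,C:2)abc:1,D:3);", "my")
        for n in sp.postorder():
            if n.parent is not None:
                n.annotations["coal_T"] = T if n.label == "ab" else 10.0
        gts = simulate_gene_trees(sp, n_genes,
                                  np.random.default_rng(_seed(seed, k)))
        stats = {s.branch_id: s for s in coalescent_branch_lengths(sp, gts)}
        s = stats["ab"]
        p = s.nkk / (s.n12 + s.nkk)
        se_est = math.sqrt(p * (1 - p) / n_genes) / p
        rows.append({"T": T, "estimate": s.coalescent_length,
                     "error": s.coalescent_length - T,
                     "band_3se": 3 * se_est})
    df = pd.DataFrame(rows)
    return {"table": df,
            "max_abs_error": float(df["error"].abs().max()),
            "all_within_3se": bool(
                (df["error"].abs() <= df["band_3se"]).all())}


def _cherry_system(seed, n_cherries: int = 8):
    """Caterpillar of cherries with known per-branch Ne, g and spans.

    A single-taxon outgroup sits below the deepest cherry so that every
    cherry's sibling subtree reduces to one lineage: a pair failing to
    coalesce then mixes with exactly one other lineage, the regime in
    which the discordance correction is exact.
    """
    rng = np.random.default_rng(seed)
    parts = [f"(a{i}:1,b{i}:1)n{i}:10" for i in range(1, n_cherries + 1)]
    nwk = f"({parts[0]},x0:11):12"
    for p in parts[1:]:
        nwk = f"({nwk},{p}):12"
    sp = read_tree(nwk + ";", "my")
    true = {}
    ne_values = np.exp(np.linspace(math.log(1.3e6), math.log(8e6),
                                   n_cherries))
    ne_values = rng.permutation(ne_values)
    i = 0
    ts_rows = []
    for node in sp.postorder():
        if node.parent is None:
            continue
        if node.label and node.label.startswith("n"):   # cherry branch
            ne = float(ne_values[i]); i += 1
            span_my, g = 10.0, 2.0
            T = span_my * 1e6 / (2 * ne * g)
            node.annotations["coal_T"] = T
            true[node.label] = {"ne": ne, "T": T, "span_my": span_my,
                                "g": g}
            ts_rows.append({"branch_id": node.label,
                            "time_span_my": span_my,
                            "gen_time_rootward_yr": g,
                            "gen_time_tipward_yr": g})
        else:
            node.annotations["coal_T"] = 0.0 if node.is_leaf else 6.0
    return sp, true, pd.DataFrame(ts_rows)


def ne_recovery(seed, n_genes: int = 10_000) -> dict:
    """End-to-end: simulate gene trees -> count discordance -> reconstruct
    ancestral population sizes for 8 cherry branches with known truth."""
    sp, true, timespans = _cherry_system(_seed(seed, 17))
    gts = simulate_gene_trees(sp, n_genes,
                              np.random.default_rng(_seed(seed, 18)))
    stats = coalescent_branch_lengths(sp, gts)
    table = ne_table([s for s in stats if s.is_cherry], timespans)
    table = table[table["branch_id"].isin(true)].set_index("branch_id")
    truth = pd.Series({b: v["ne"] for b, v in true.items()})
    est = table["n_hat"].reindex(truth.index)
    rel_err = ((est - truth) / truth).abs()
    rank_match = (est.rank() == truth.rank()).all()
    return {"max_rel_error": float(rel_err.max()),
            "mean_rel_error": float(rel_err.mean()),
            "rank_order_recovered": bool(rank_match),
            "n_branches": int(len(truth))}


# ---------------------------------------------------------------------------
# GC3* stationarity / nonstationarity
# ---------------------------------------------------------------------------

def _scaled_tree(n_tips, seed, depth_subst=0.3):
    # splits kept in the older two thirds of the depth so every terminal
    # branch carries a measurable share of the substitution process
    tree = _random_ultrametric_tree(n_tips, 1.0,
                                    np.random.default_rng(seed),
                                    min_depth=0.35)
    for n in tree.postorder():
        if n.length is not None:
            n.length *= depth_subst
    return tree


def gc3star_stationary(seed, n_tips: int = 20, n_sites: int = 50_000,
                       theta: float = 0.45) -> dict:
    """Under stationarity GC3* must agree with theta and with current GC3."""
    tree = _scaled_tree(n_tips, _seed(seed, 21))
    rng = np.random.default_rng(_seed(seed, 22))
    codes, taxa, _ = simulate_t92_alignment(tree, theta, 4.0, n_sites, rng)
    fit = T92Model(codes, taxa, tree).fit()
    star = gc3_star(fit.map_substitutions(), "per_tip_root_path")
    gc3 = pd.Series({t: float(((codes[i] == 1) | (codes[i] == 2)).mean())
                     for i, t in enumerate(taxa)})
    return {"theta_hat": fit.theta,
            "max_dev_from_theta": float((star - theta).abs().max()),
            "max_dev_from_gc3": float((star - gc3).abs().max())}


def gc3star_shifted(seed, n_tips: int = 20, n_sites: int = 50_000,
                    theta_anc: float = 0.40,
                    theta_tip: float = 0.55) -> dict:
    """Recent shift upward: GC3* should exceed GC3 for nearly all tips and
    regress on GC3 with slope > 1 (equilibria run ahead of composition)."""
    tree = _scaled_tree(n_tips, _seed(seed, 23))
    rng = np.random.default_rng(_seed(seed, 24))
    codes, taxa, _ = simulate_t92_alignment(
        tree, theta_anc, 4.0, n_sites, rng,
        tip_theta={t: theta_tip for t in tree.tip_labels})
    fit = T92Model(codes, taxa, tree).fit()
    star = gc3_star(fit.map_substitutions(), "per_tip_root_path")
    gc3 = pd.Series({t: float(((codes[i] == 1) | (codes[i] == 2)).mean())
                     for i, t in enumerate(taxa)})
    slope = float(np.polyfit(gc3.reindex(star.index), star, 1)[0])
    return {"frac_star_above_gc3": float((star > gc3).mean()),
            "slope_star_on_gc3": slope}


def substitution_count_accuracy(seed, n_tips: int = 10,
                                n_sites: int = 30_000) -> dict:
    """Mapped expected W->S / S->W counts vs logged true event counts."""
    tree = _scaled_tree(n_tips, _seed(seed, 31))
    rng = np.random.default_rng(_seed(seed, 32))
    codes, taxa, events = simulate_t92_alignment(tree, 0.5, 4.0, n_sites,
                                                 rng, log_events=True)
    fit = T92Model(codes, taxa, tree).fit()
    tb = fit.map_substitutions("labeled").table.set_index("branch_id")
    ev = events.set_index("branch_id")
    # expectation vs a single realisation: compare only where the
    # realisation's own sampling noise (~1/sqrt(N)) is well below 10%
    rel = []
    for b in ev.index:
        for cls, col in (("n_ws", "E_WS"), ("n_sw", "E_SW")):
            if ev.loc[b, cls] >= 1000:
                rel.append(abs(tb.loc[b, col] - ev.loc[b, cls])
                           / ev.loc[b, cls])
    return {"max_rel_error": float(max(rel)),
            "n_branch_counts": len(rel)}


# ---------------------------------------------------------------------------
# Gamma index
# ---------------------------------------------------------------------------

def gamma_criteria(seed) -> dict:
    rng = np.random.default_rng(_seed(seed, 41))
    # closed-form arithmetic
    gamma_arith = -10.0 / math.log(math.exp(-1.0))
    # monotone invariance (exact)
    idx = [f"g{i}" for i in range(60)]
    a = pd.Series(rng.uniform(0.3, 0.7, 60), index=idx)
    b = pd.Series(a.values + rng.normal(0, 0.05, 60), index=idx)
    base = gc3_conservation_index(a, b, t=7.0)
    warped = gc3_conservation_index(np.exp(2 * a), b ** 3, t=7.0)
    invariant = math.isclose(base.gamma, warped.gamma, rel_tol=1e-12)
    # strict decrease over increasing divergence noise
    base_vals = pd.Series(rng.uniform(0.3, 0.7, 200),
                          index=[f"g{i}" for i in range(200)])
    means = []
    for scale in (0.01, 0.03, 0.06, 0.1, 0.2):
        reps = [gc3_conservation_index(
            base_vals, base_vals + rng.normal(0, scale, 200), t=10.0).gamma
            for _ in range(5)]
        means.append(float(np.mean(reps)))
    decreasing = all(x > y for x, y in zip(means, means[1:]))
    return {"gamma_at_tau_e_minus_1_t10": gamma_arith,
            "monotone_invariant": bool(invariant),
            "strictly_decreasing_in_noise": bool(decreasing),
            "gamma_by_noise_level": means}


# ---------------------------------------------------------------------------
# Trait-correlation power and calibration
# ---------------------------------------------------------------------------

def _one_mass_gc3_rho(cfg: SimulationConfig):
    data = simulate_dataset(cfg, classes=("c3",), with_introns=False,
                            with_gene_trees=False)
    pooled = pooled_gc(data.alignments, "c3")
    mass = data.species.traits.set_index("species")["body_mass_g"]
    return rank_correlation(mass, pooled.reindex(mass.index))


def trait_correlation_power(seed, n_reps: int = 100,
                            alpha: float = 0.05) -> dict:
    """Power of the body-mass/GC3 test at generator defaults, and type-I
    error with the mass effect switched off."""
    detected = 0
    for r in range(n_reps):
        res = _one_mass_gc3_rho(SimulationConfig(seed=_seed(seed, 100 + r)))
        detected += (res.estimate < 0) and (res.p_value < alpha)
    rejected_null = 0
    for r in range(n_reps):
        res = _one_mass_gc3_rho(SimulationConfig(
            seed=_seed(seed, 500 + r), mass_effect=0.0))
        rejected_null += res.p_value < alpha
    return {"power": detected / n_reps,
            "null_rejection_rate": rejected_null / n_reps,
            "n_reps": n_reps, "alpha": alpha,
            "null_band_3se": 3 * math.sqrt(alpha * (1 - alpha) / n_reps)}


# ---------------------------------------------------------------------------
# gBGC dynamics
# ---------------------------------------------------------------------------

def dynamics_criteria(seed) -> dict:
    dyn = GBGCDynamics(g0=0.40, u=3e-9, v=5e-9)
    n = 10**6
    iterated = iterate_gc(dyn, n)
    closed = float(dyn.trajectory(n))
    rel = abs(iterated - closed) / closed

    ne, b, reps = 100, 0.005, 200_000
    wf = wright_fisher_fixation(ne, b, reps, _seed(seed, 61))
    kimura = fixation_probability(ne, b)
    se = math.sqrt(kimura * (1 - kimura) / reps)

    halving = {}
    for ne_pop in (1e5, 3e5, 1e6):
        d = dynamics_from_population(0.47, ne_pop, mu_ws=1e-9,
                                     mu_sw=2e-9, b=1e-6)
        halving[f"ne_{ne_pop:.0e}"] = d.t_half
    return {"iterative_vs_closed_rel": rel,
            "wf_fixation": wf, "kimura_fixation": kimura,
            "wf_z": abs(wf - kimura) / se,
            "halving_generations": halving,
            "min_halving": min(halving.values())}
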