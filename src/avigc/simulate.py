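"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes: a dated species tree with
per-branch effective population sizes and generation times, life-history
traits, multispecies-coalescent gene trees, codon alignments whose
third-position equilibrium GC is linked to body mass and to local
recombination rate, intron alignments, and paired recombination maps.

The emulated structure: small-bodied species have larger populations,
shorter generations and higher third-position GC (negative mass <-> GC3
association); terminal-branch equilibria are shifted upward relative to
the ancestral composition (recent GC gains, GC3* > GC3); per-gene
deviations scale with the recombination rate of the window the gene sits
in (high-recombination regions show higher between-species GC3 variance);
and gene-tree discordance follows the coalescent lengths implied by the
per-branch population sizes.

Determinism: one master seed spawns named substreams per generator, so
identical (config, seed) gives bit-identical outputs and adding genes
does not perturb trait draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import A, C, G, T, OrthologAlignment, ALPHABET
from .trees import LabeledTree, TreeNode
from .substitution import TreeArrays, t92_stationary, t92_transition_matrix
from .coalescent import branch_id

_ALPH_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
_TRANSITION_PARTNER = np.array([G, T, A, C])  # A<->G, C<->T


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic system.

    Sizes follow the scale at which the qualitative findings are
    detectable on one CPU: 40 species, 1,500 coding orthologs of 300
    codons, 400 introns. Composition parameters are equilibrium-GC values
    of the T92 model; rates are per-site per-My at third positions.
    """

    seed: int = 0
    n_species: int = 40
    n_genes: int = 1500
    n_codons: int = 300
    n_introns: int = 400
    intron_length: int = 600
    root_age_my: float = 100.0

    # composition model
    theta_ancestral: float = 0.42
    tip_theta_uplift: float = 0.05      # mean recent upward shift
    mass_effect: float = 0.08           # theta span linked to mass rank
    theta_noise_sd: float = 0.01
    kappa: float = 4.0
    subst_rate_per_my: float = 3.0e-3   # third positions
    rate12_factor: float = 0.3          # c1/c2 evolve slower (constraint)
    theta1_base: float = 0.55
    theta2_base: float = 0.40
    theta12_compression: float = 0.15   # narrow c1/c2 range
    theta_intron_base: float = 0.45
    intron_compression: float = 0.5

    # life history
    log10_mass_mean: float = 2.5        # ~300 g
    log10_mass_sd: float = 1.0
    gen_time_coef: float = 0.55         # g = coef * mass^exp (yr)
    gen_time_exp: float = 0.2
    trait_noise_sd: float = 0.15        # lognormal sd on derived traits
    dropout_longevity: float = 0.3
    dropout_maturity: float = 0.4

    # populations
    ne_ref: float = 5e5                 # Ne at the reference mass
    ne_mass_exp: float = 0.35           # Ne ~ mass^-exp
    ne_ref_mass_g: float = 300.0
    ne_noise_sd: float = 0.2

    # recombination system
    n_large_chroms: int = 9
    windows_per_large: int = 30
    n_small_chroms: int = 19
    windows_per_small: int = 6
    window_size_bp: int = 1_000_000
    rate_large_median: float = 2.0      # cM/Mb
    rate_small_median: float = 6.0
    rate_log_sd: float = 0.7
    cross_map_rho: float = 0.4          # target Spearman between maps
    multiplier_sd: float = 0.0          # extra per-gene lognormal noise


@dataclass
class SpeciesSystem:
    tree: LabeledTree                   # units = My; per-node annotations
    traits: pd.DataFrame
    tip_theta: pd.Series                # terminal-branch equilibrium GC3
    timespans: pd.DataFrame             # branch_id, time_span_my, gen times


@dataclass
class RecombSystem:
    maps: dict                          # reference -> windows DataFrame
    locations: pd.DataFrame
    gene_rate: np.ndarray               # primary-map rate per gene
    multipliers: np.ndarray


@dataclass
class SimulatedData:
    config: SimulationConfig
    species: SpeciesSystem
    recomb: RecombSystem
    alignments: list
    intron_alignments: list
    gene_trees: list
    events: pd.DataFrame | None = None


def _streams(seed):
    names = ["species", "traits", "recomb", "alignments", "genetrees",
             "introns"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Species system
# ---------------------------------------------------------------------------

def _random_ultrametric_tree(n: int, root_age: float, rng,
                             min_depth: float = 0.05) -> LabeledTree:
    """Random join order with node depths spread over (min_depth, 1] x
    root_age; raising ``min_depth`` guarantees non-negligible terminal
    branches."""
    depths = np.sort(rng.uniform(min_depth, 1.0, n - 1))
    depths = depths / depths[-1] * root_age
    lineages = [(TreeNode(label=f"sp{i+1:02d}"), 0.0) for i in range(n)]
    for t in depths:
        i, j = sorted(rng.choice(len(lineages), 2, replace=False))
        (n2, d2) = lineages.pop(j)
        (n1, d1) = lineages.pop(i)
        parent = TreeNode()
        n1.length = t - d1
        n2.length = t - d2
        parent.add_child(n1)
        parent.add_child(n2)
        parent.annotations["depth_my"] = float(t)
        lineages.append((parent, t))
    root = lineages[0][0]
    return LabeledTree(root, units="my")


def simulate_species_system(config: SimulationConfig,
                            rng=None) -> SpeciesSystem:
    """Species tree + traits + per-branch theta, Ne, generation times.

    Body mass is log-normal; generation time and Ne scale allometrically
    (Ne decreasing in mass). Terminal-branch equilibrium GC3 is
    theta_ancestral + uplift + mass_effect * (rank of 1/mass), making the
    mass <-> theta association negative with configurable strength.
    Per-branch coalescent lengths follow T = span_yr / (2 Ne g).
    """
    if rng is None:
        rng = _streams(config.seed)["species"]
    n = config.n_species
    tree = _random_ultrametric_tree(n, config.root_age_my, rng)
    tips = sorted(tree.tip_labels)
    mass = 10 ** rng.normal(config.log10_mass_mean, config.log10_mass_sd, n)
    mass = pd.Series(mass, index=tips)

    def gen_time(m):
        return config.gen_time_coef * m ** config.gen_time_exp

    # theta: smaller mass -> larger rank of 1/mass -> higher theta
    rank = mass.rank(ascending=False) - 1          # heaviest first
    centered = rank / max(1, n - 1) - 0.5
    tip_theta = (config.theta_ancestral + config.tip_theta_uplift
                 + config.mass_effect * centered
                 + rng.normal(0, config.theta_noise_sd, n))
    tip_theta = pd.Series(np.clip(tip_theta, 0.05, 0.95), index=tips,
                          name="theta")

    # annotate nodes: depth, generation time, branch Ne and coalescent T
    for node in tree.postorder():
        if node.is_leaf:
            node.annotations["depth_my"] = 0.0
            node.annotations["mass_g"] = float(mass[node.label])
        else:
            masses = [t.annotations["mass_g"] for t in node.children
                      for t in ([t] if t.is_leaf else list(_tips_of(t)))]
            node.annotations["mass_g"] = float(
                math.exp(np.mean(np.log(masses))))
        node.annotations["gen_time_yr"] = float(
            gen_time(node.annotations["mass_g"]))
    for node in tree.postorder():
        if node.parent is None:
            continue
        span = (node.parent.annotations["depth_my"]
                - node.annotations["depth_my"])
        node.annotations["time_span_my"] = float(span)
        ne = (config.ne_ref
              * (node.annotations["mass_g"] / config.ne_ref_mass_g)
              ** (-config.ne_mass_exp)
              * math.exp(rng.normal(0, config.ne_noise_sd)))
        node.annotations["ne"] = float(ne)
        g = 0.5 * (node.annotations["gen_time_yr"]
                   + node.parent.annotations["gen_time_yr"])
        node.annotations["coal_T"] = float(span * 1e6 / (2.0 * ne * g))
        node.annotations["theta"] = (float(tip_theta[node.label])
                                     if node.is_leaf
                                     else config.theta_ancestral)
        if not node.is_leaf:
            node.support = float(np.round(rng.uniform(60, 100)))

    noise = lambda: math.exp(rng.normal(0, config.trait_noise_sd))
    traits = pd.DataFrame({
        "species": tips,
        "body_mass_g": [float(mass[t]) for t in tips],
        "max_longevity_yr": [6.0 * gen_time(mass[t]) * noise()
                             for t in tips],
        "age_first_maturity_yr": [gen_time(mass[t]) * noise()
                                  for t in tips],
    })

    ts_rows = []
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        ts_rows.append({
            "branch_id": branch_id(node),
            "time_span_my": node.annotations["time_span_my"],
            "gen_time_rootward_yr": node.parent.annotations["gen_time_yr"],
            "gen_time_tipward_yr": node.annotations["gen_time_yr"],
            "true_ne": node.annotations["ne"],
            "coal_T": node.annotations["coal_T"],
        })
    timespans = (pd.DataFrame(ts_rows).sort_values("branch_id")
                 .reset_index(drop=True))
    return SpeciesSystem(tree=tree, traits=traits, tip_theta=tip_theta,
                         timespans=timespans)


def _tips_of(node):
    stack = [node]
    while stack:
        x = stack.pop()
        if x.is_leaf:
            yield x
        else:
            stack.extend(x.children)


def apply_trait_dropout(traits: pd.DataFrame, config: SimulationConfig,
                        rng) -> pd.DataFrame:
    out = traits.copy()
    for col, frac in (("max_longevity_yr", config.dropout_longevity),
                      ("age_first_maturity_yr", config.dropout_maturity)):
        mask = rng.random(len(out)) < frac
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# Gene trees (multispecies coalescent)
# ---------------------------------------------------------------------------

def simulate_gene_trees(species_tree: LabeledTree, n_genes: int, rng,
                        coal_attr: str = "coal_T") -> list[LabeledTree]:
    """Topology-only MSC gene trees, one sampled lineage per species.

    Within each species-tree branch of coalescent length T (annotation
    ``coal_attr`` on the tipward node), k lineages coalesce at rate
    k(k-1)/2 per unit; survivors merge rootward; the root branch is
    unbounded.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    order = list(species_tree.postorder())
    out = []
    for _ in range(n_genes):
        surviving: dict[int, list[TreeNode]] = {}
        for node in order:
            if node.is_leaf:
                pool = [TreeNode(label=node.label)]
            else:
                pool = []
                for ch in node.children:
                    pool.extend(surviving.pop(id(ch)))
            if node.parent is None:
                T_len = math.inf
            else:
                T_len = float(node.annotations.get(coal_attr, 0.0))
                if not np.isfinite(T_len):
                    T_len = math.inf
            t = 0.0
            while len(pool) > 1:
                k = len(pool)
                t += rng.exponential(2.0 / (k * (k - 1)))
                if t > T_len:
                    break
                i, j = rng.choice(k, 2, replace=False)
                i, j = (int(i), int(j)) if i < j else (int(j), int(i))
                parent = TreeNode()
                parent.add_child(pool[i])
                parent.add_child(pool[j])
                pool[i] = parent
                pool.pop(j)
            surviving[id(node)] = pool
        root_pool = surviving[id(order[-1])]
        out.append(LabeledTree(root_pool[0], units="none"))
    return out


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def _sample_root(pi_rows: np.ndarray, rng) -> np.ndarray:
    """pi_rows: (n_sites, 4) stationary rows -> sampled states."""
    u = rng.random(pi_rows.shape[0])
    return (pi_rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)


def _sample_branch(states: np.ndarray, P: np.ndarray, rng,
                   site_matrix_idx: np.ndarray | None = None) -> np.ndarray:
    """Endpoint sampling of child states.

    ``P`` is (4,4) shared across sites, or (n_models,4,4) with
    ``site_matrix_idx`` giving each site's model row.
    """
    u = rng.random(states.size)
    Pc = P.cumsum(axis=-1)
    if P.ndim == 2:
        out = np.empty(states.size, dtype=np.uint8)
        for s in range(4):
            mask = states == s
            out[mask] = np.searchsorted(Pc[s], u[mask], side="right")
        np.minimum(out, 3, out=out)
        return out
    flat = Pc.reshape(-1, 4)
    rows = flat.take(site_matrix_idx * 4 + states, axis=0)
    return np.minimum((rows < u[:, None]).sum(axis=1), 3).astype(np.uint8)


def _sample_branch_events(states: np.ndarray, theta, kappa: float,
                          t: float, rng):
    """Jump-chain simulation of one branch, logging true W->S / S->W
    event counts (multiple hits included). theta is scalar or per-site."""
    states = states.copy()
    n = states.size
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (n,)).copy()
    beta = 1.0 / (kappa * theta * (1 - theta) + 0.5)
    remaining = np.full(n, float(t))
    active = np.ones(n, dtype=bool)
    n_ws = n_sw = 0
    while active.any():
        idx = np.nonzero(active)[0]
        s = states[idx]
        th = theta[idx]
        strong = (s == C) | (s == G)
        rate = np.where(strong,
                        beta[idx] * (kappa * (1 - th) / 2 + 0.5),
                        beta[idx] * (kappa * th / 2 + 0.5))
        dt = rng.exponential(1.0, idx.size) / rate
        done = dt >= remaining[idx]
        active[idx[done]] = False
        jump = idx[~done]
        if jump.size == 0:
            continue
        remaining[jump] -= dt[~done]
        s2 = states[jump]
        th2 = theta[jump]
        w = np.empty((jump.size, 4))
        w[:, A] = w[:, T] = (1 - th2) / 2
        w[:, C] = w[:, G] = th2 / 2
        rowi = np.arange(jump.size)
        w[rowi, _TRANSITION_PARTNER[s2]] *= kappa
        w[rowi, s2] = 0.0
        w /= w.sum(axis=1, keepdims=True)
        new = (w.cumsum(axis=1) < rng.random(jump.size)[:, None]).sum(axis=1)
        new = new.astype(np.uint8)
        old_strong = (s2 == C) | (s2 == G)
        new_strong = (new == C) | (new == G)
        n_ws += int((~old_strong & new_strong).sum())
        n_sw += int((old_strong & ~new_strong).sum())
        states[jump] = new
    return states, n_ws, n_sw


def simulate_t92_alignment(tree: LabeledTree, theta: float, kappa: float,
                           n_sites: int, rng, tip_theta: dict | None = None,
                           log_events: bool = False):
    """Simulate sites on a tree with branch lengths in substitutions/site.

    All branches use equilibrium GC ``theta`` except terminal branches of
    species named in ``tip_theta`` (nonstationary recent shifts). Root
    states are stationary at ``theta``. Returns (codes, taxa, events)
    where events is a per-branch DataFrame of true event counts (or None).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = TreeArrays(tree)
    states = np.empty((arr.n_nodes, n_sites), dtype=np.uint8)
    pi = t92_stationary(theta)
    states[arr.root] = _sample_root(np.broadcast_to(pi, (n_sites, 4)), rng)
    rows = []
    for i in range(arr.n_nodes - 2, -1, -1):   # preorder, skipping root
        node = arr.nodes[i]
        th = theta
        if tip_theta and node.is_leaf and node.label in tip_theta:
            th = tip_theta[node.label]
        parent_states = states[arr.parent[i]]
        if log_events:
            states[i], ws, sw = _sample_branch_events(
                parent_states, th, kappa, arr.length[i], rng)
            rows.append({"branch_id": branch_id(node), "node": i,
                         "n_ws": ws, "n_sw": sw})
        else:
            P = t92_transition_matrix(th, kappa, arr.length[i])
            states[i] = _sample_branch(parent_states, P, rng)
    taxa = sorted(arr.tip_index)
    codes = np.vstack([states[arr.tip_index[t_]] for t_ in taxa])
    events = pd.DataFrame(rows) if log_events else None
    return codes, taxa, events


def _codes_to_alignment(ortholog_id: str, kind: str, taxa: list[str],
                        codes: np.ndarray) -> OrthologAlignment:
    """Fast trusted-path construction (codes already canonical)."""
    aln = object.__new__(OrthologAlignment)
    aln.ortholog_id = ortholog_id
    aln.kind = kind
    aln.sequences = {
        sp: _ALPH_BYTES[codes[r]].tobytes().decode("ascii")
        for r, sp in enumerate(taxa)}
    aln._codes = codes
    return aln


def simulate_alignments(system: SpeciesSystem, config: SimulationConfig,
                        multipliers: np.ndarray, rng,
                        classes=("c1", "c2", "c3"),
                        log_events: bool = False):
    """Codon alignments for all genes at once.

    Third positions evolve under branch-specific T92: the ancestral
    equilibrium on internal branches, and per-(gene, species) equilibria
    theta_anc + m_g * (theta_tip - theta_anc) on terminal branches, where
    the per-gene multiplier m_g is the recombination proxy. First/second
    positions use a compressed deviation and a slower clock. Positions of
    classes not simulated are filled with N so they read as missing.

    Returns (alignments, events) with true third-position W->S / S->W
    event counts per branch when ``log_events``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = config
    n_genes, n_codons = cfg.n_genes, cfg.n_codons
    multipliers = np.asarray(multipliers, dtype=float)
    if multipliers.shape != (n_genes,):
        raise ValueError("need one multiplier per gene")
    tree = system.tree
    arr = TreeArrays(tree)
    n_sites = n_genes * n_codons
    gene_idx = np.repeat(np.arange(n_genes), n_codons)
    theta_anc = cfg.theta_ancestral
    dev_tip = {sp: float(th) - theta_anc
               for sp, th in system.tip_theta.items()}

    class_spec = {}
    if "c3" in classes:
        class_spec["c3"] = (theta_anc, 1.0, 1.0)
    if "c1" in classes:
        class_spec["c1"] = (cfg.theta1_base, cfg.theta12_compression,
                            cfg.rate12_factor)
    if "c2" in classes:
        class_spec["c2"] = (cfg.theta2_base, cfg.theta12_compression,
                            cfg.rate12_factor)

    tip_codes = {}
    events_rows = []
    for cls, (base, compress, rate_factor) in class_spec.items():
        states = np.empty((arr.n_nodes, n_sites), dtype=np.uint8)
        pi = t92_stationary(base)
        states[arr.root] = _sample_root(np.broadcast_to(pi, (n_sites, 4)),
                                        rng)
        for i in range(arr.n_nodes - 2, -1, -1):
            node = arr.nodes[i]
            t_branch = arr.length[i] * cfg.subst_rate_per_my * rate_factor
            parent_states = states[arr.parent[i]]
            if node.is_leaf:
                th_g = np.clip(
                    base + compress * multipliers * dev_tip[node.label],
                    0.02, 0.98)
                if log_events and cls == "c3":
                    states[i], ws, sw = _sample_branch_events(
                        parent_states, th_g[gene_idx], cfg.kappa,
                        t_branch, rng)
                    events_rows.append({"branch_id": branch_id(node),
                                        "n_ws": ws, "n_sw": sw})
                else:
                    P = t92_transition_matrix(th_g, cfg.kappa, t_branch)
                    states[i] = _sample_branch(parent_states, P, rng,
                                               site_matrix_idx=gene_idx)
            else:
                if log_events and cls == "c3":
                    states[i], ws, sw = _sample_branch_events(
                        parent_states, base, cfg.kappa, t_branch, rng)
                    events_rows.append({"branch_id": branch_id(node),
                                        "n_ws": ws, "n_sw": sw})
                else:
                    P = t92_transition_matrix(base, cfg.kappa, t_branch)
                    states[i] = _sample_branch(parent_states, P, rng)
        taxa = sorted(arr.tip_index)
        tip_codes[cls] = np.vstack([states[arr.tip_index[t_]]
                                    for t_ in taxa])
    taxa = sorted(arr.tip_index)
    alignments = []
    offsets = {"c1": 0, "c2": 1, "c3": 2}
    big = np.full((len(taxa), n_genes * n_codons * 3), 4, dtype=np.uint8)
    for cls in class_spec:
        big[:, offsets[cls]::3] = tip_codes[cls]
    row_strings = [_ALPH_BYTES[big[r]].tobytes().decode("ascii")
                   for r in range(len(taxa))]
    gene_len = n_codons * 3
    for g in range(n_genes):
        lo, hi = g * gene_len, (g + 1) * gene_len
        aln = object.__new__(OrthologAlignment)
        aln.ortholog_id = f"g{g+1:05d}"
        aln.kind = "coding"
        aln.sequences = {sp: row_strings[r][lo:hi]
                         for r, sp in enumerate(taxa)}
        aln._codes = big[:, lo:hi]
        alignments.append(aln)
    events = pd.DataFrame(events_rows) if log_events else None
    return alignments, events


def simulate_intron_alignments(system: SpeciesSystem,
                               config: SimulationConfig,
                               multipliers: np.ndarray, rng):
    """Intron alignments for the first ``n_introns`` orthologs; intronic
    equilibria track the third-position deviation with partial strength."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = config
    arr = TreeArrays(system.tree)
    n_i = min(cfg.n_introns, cfg.n_genes)
    L = cfg.intron_length
    n_sites = n_i * L
    gene_idx = np.repeat(np.arange(n_i), L)
    dev_tip = {sp: float(th) - cfg.theta_ancestral
               for sp, th in system.tip_theta.items()}
    m = np.asarray(multipliers[:n_i], dtype=float)
    states = np.empty((arr.n_nodes, n_sites), dtype=np.uint8)
    pi = t92_stationary(cfg.theta_intron_base)
    states[arr.root] = _sample_root(np.broadcast_to(pi, (n_sites, 4)), rng)
    for i in range(arr.n_nodes - 2, -1, -1):
        node = arr.nodes[i]
        t_branch = arr.length[i] * cfg.subst_rate_per_my
        if node.is_leaf:
            th_g = np.clip(cfg.theta_intron_base
                           + cfg.intron_compression * m
                           * dev_tip[node.label], 0.02, 0.98)
            P = t92_transition_matrix(th_g, cfg.kappa, t_branch)
            states[i] = _sample_branch(states[arr.parent[i]], P, rng,
                                       site_matrix_idx=gene_idx)
        else:
            P = t92_transition_matrix(cfg.theta_intron_base, cfg.kappa,
                                      t_branch)
            states[i] = _sample_branch(states[arr.parent[i]], P, rng)
    taxa = sorted(arr.tip_index)
    tips = np.vstack([states[arr.tip_index[t_]] for t_ in taxa])
    out = []
    for g in range(n_i):
        codes = tips[:, g * L:(g + 1) * L]
        out.append(_codes_to_alignment(f"g{g+1:05d}", "intron", taxa,
                                       codes))
    return out


# ---------------------------------------------------------------------------
# Recombination system
# ---------------------------------------------------------------------------

def simulate_recomb_system(config: SimulationConfig, rng) -> RecombSystem:
    """Two syntenic recombination maps plus ortholog locations.

    Window rates are log-normal, correlated between the two references at
    the configured Spearman level, with higher rates on small chromosomes
    (at least one crossover per chromosome). Genes are scattered over the
    windows; the per-gene multiplier is the primary-map window rate scaled
    to unit mean (plus optional lognormal noise).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = config
    chrom_rows = []
    for c in range(1, cfg.n_large_chroms + 1):
        chrom_rows += [(str(c), w, math.log(cfg.rate_large_median))
                       for w in range(cfg.windows_per_large)]
    for c in range(cfg.n_large_chroms + 1,
                   cfg.n_large_chroms + cfg.n_small_chroms + 1):
        chrom_rows += [(str(c), w, math.log(cfg.rate_small_median))
                       for w in range(cfg.windows_per_small)]
    n_win = len(chrom_rows)
    # Calibrate the shared-noise weight so the *overall* Spearman between
    # the two maps hits the target: the chromosome-class means are common
    # to both references and already contribute their variance share.
    mus = np.array([mu for _, _, mu in chrom_rows])
    v_class = float(np.var(mus))
    v_noise = cfg.rate_log_sd ** 2
    rho_p = 2.0 * math.sin(math.pi * cfg.cross_map_rho / 6.0)
    r = (rho_p * (v_class + v_noise) - v_class) / v_noise
    r = float(np.clip(r, 0.0, 1.0))
    z_shared = rng.normal(0, 1, n_win)
    maps = {}
    rates = {}
    for ref in ("ref1", "ref2"):
        z = (math.sqrt(r) * z_shared
             + math.sqrt(1 - r) * rng.normal(0, 1, n_win))
        rate = np.array([math.exp(mu + cfg.rate_log_sd * zz)
                         for (_, _, mu), zz in zip(chrom_rows, z)])
        df = pd.DataFrame({
            "chrom": [c for c, _, _ in chrom_rows],
            "start": [w * cfg.window_size_bp for _, w, _ in chrom_rows],
            "end": [(w + 1) * cfg.window_size_bp for _, w, _ in chrom_rows],
            "rate_cm_mb": rate,
        })
        df.attrs["reference"] = ref
        maps[ref] = df
        rates[ref] = rate
    win_of_gene = rng.integers(0, n_win, cfg.n_genes)
    offset = rng.integers(1000, cfg.window_size_bp - 5000, cfg.n_genes)
    loc_rows = []
    for ref in maps:
        for g in range(cfg.n_genes):
            c, w, _ = chrom_rows[win_of_gene[g]]
            start = w * cfg.window_size_bp + int(offset[g])
            loc_rows.append({"ortholog_id": f"g{g+1:05d}", "reference": ref,
                             "chrom": c, "start": start,
                             "end": start + 2000})
    locations = pd.DataFrame(loc_rows)
    gene_rate = rates["ref1"][win_of_gene]
    multipliers = gene_rate / gene_rate.mean()
    if cfg.multiplier_sd > 0:
        multipliers = multipliers * np.exp(
            rng.normal(0, cfg.multiplier_sd, cfg.n_genes))
        multipliers = multipliers / multipliers.mean()
    return RecombSystem(maps=maps, locations=locations,
                        gene_rate=gene_rate, multipliers=multipliers)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig,
                     classes=("c1", "c2", "c3"),
                     with_introns: bool = True,
                     with_gene_trees: bool = True,
                     n_gene_trees: int | None = None,
                     log_events: bool = False) -> SimulatedData:
    """Generate the complete synthetic study: tree, traits, maps,
    alignments, gene trees. Deterministic under (config, config.seed)."""
    streams = _streams(config.seed)
    species = simulate_species_system(config, streams["species"])
    species.traits = apply_trait_dropout(species.traits, config,
                                         streams["traits"])
    recomb = simulate_recomb_system(config, streams["recomb"])
    alignments, events = simulate_alignments(
        species, config, recomb.multipliers, streams["alignments"],
        classes=classes, log_events=log_events)
    introns = simulate_intron_alignments(
        species, config, recomb.multipliers, streams["introns"]) \
        if with_introns else []
    gene_trees = simulate_gene_trees(
        species.tree, n_gene_trees or min(config.n_genes, 1000),
        streams["genetrees"]) if with_gene_trees else []
    return SimulatedData(config=config, species=species, recomb=recomb,
                         alignments=alignments, intron_alignments=introns,
                         gene_trees=gene_trees, events=events)


def write_dataset(data: SimulatedData, outdir) -> None:
    """Write the dataset in exactly the formats the readers consume."""
    from . import io as aio
    out = Path(outdir)
    (out / "coding").mkdir(parents=True, exist_ok=True)
    (out / "introns").mkdir(exist_ok=True)
    (out / "gene_trees").mkdir(exist_ok=True)
    for aln in data.alignments:
        aio.write_alignment(aln, out / "coding" / f"{aln.ortholog_id}.fa")
    for aln in data.intron_alignments:
        aio.write_alignment(aln, out / "introns" / f"{aln.ortholog_id}.fa")
    for i, gt in enumerate(data.gene_trees):
        aio.write_tree(gt, out / "gene_trees" / f"gt{i+1:05d}.nwk")
    aio.write_tree(data.species.tree, out / "species.nwk")
    aio.write_table(data.species.traits, out / "traits.tsv", ["species"])
    aio.write_table(data.species.timespans, out / "timespans.tsv",
                    ["branch_id"])
    for ref, df in data.recomb.maps.items():
        aio.write_table(df, out / f"recomb_{ref}.tsv", ["chrom", "start"])
    aio.write_table(data.recomb.locations, out / "locations.tsv",
                    ["reference", "ortholog_id"])
    with open(out / "config.txt", "w") as fh:
        for k, v in asdict(data.config).items():
            fh.write(f"{k}\t{v}\n")
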