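"""Correlation and hypothesis-testing machinery.

Rank correlations between species traits and composition (exact p by
enumeration for small n), phylogenetically independent contrasts, a
gene-subset randomization test, Wilcoxon rank-sum comparisons, and the
time-corrected GC3 conservation index gamma = -t / ln(tau).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .trees import LabeledTree

EXACT_N_MAX = 9        # exact rank-correlation p by full enumeration
EXACT_WILCOXON_MAX = 8  # per-sample limit for exact rank-sum p


@dataclass
class CorrelationResult:
    method: str
    estimate: float
    p_value: float
    n: int
    flags: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.estimate, self.p_value))


def _drop_missing(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


@lru_cache(maxsize=8)
def _all_perms(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _exact_p_spearman(x, y, observed):
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = _all_perms(n)
    ryp = ry[perms]                      # (n!, n)
    rxc = rx - rx.mean()
    ryc = ryp - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    rho = ryc @ rxc / denom
    return float(np.mean(np.abs(rho) >= abs(observed) - 1e-12))

def _exact_p_kendall(x, y, observed):
    n = len(x)
    i_idx, j_idx = np.triu_indices(n, k=1)
    sx = np.sign(np.subtract.outer(x, x))[i_idx, j_idx]
    sy_full = np.sign(np.subtract.outer(y, y))
    perms = _all_perms(n)
    sy = sy_full[perms[:, i_idx], perms[:, j_idx]]     # (n!, n_pairs)
    num = sy @ sx
    tx = (sx == 0).sum()
    ty = (sy_full[i_idx, j_idx] == 0).sum()
    n0 = len(i_idx)
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    tau = num / denom
    return float(np.mean(np.abs(tau) >= abs(observed) - 1e-12))


def rank_correlation(x, y, method: str = "spearman") -> CorrelationResult:
    """Correlation between two per-species vectors.

    Missing values are dropped pairwise. For ``spearman`` and ``kendall``
    (tau-b) with n <= 9 the two-sided p-value is exact, computed by
    enumerating all permutations; otherwise the asymptotic approximation
    is used. ``pearson`` is always asymptotic.
    """
    x, y = _drop_missing(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    flags = []
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method, np.nan, np.nan, n, ["constant"])
    if method == "spearman":
        est, p = stats.spearmanr(x, y)
        if n <= EXACT_N_MAX:
            p = _exact_p_spearman(x, y, est)
            flags.append("exact")
    elif method == "kendall":
        est, p = stats.kendalltau(x, y)  # tau-b
        if n <= EXACT_N_MAX:
            p = _exact_p_kendall(x, y, est)
            flags.append("exact")
    elif method == "pearson":
        est, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(est), float(p), n, flags)


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts
# ---------------------------------------------------------------------------

def independent_contrasts(tree: LabeledTree, traits: dict) -> np.ndarray:
    """Felsenstein's standardized independent contrasts.

    ``traits`` maps tip label -> value; every tip must be present. Returns
    the n-1 contrasts in postorder of the internal nodes. Correlations of
    two traits' contrasts must be computed through the origin.
    """
    if not tree.is_binary():
        raise ValueError("contrasts require a fully bifurcating tree")
    values, lengths, contrasts = {}, {}, []
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in traits:
                raise ValueError(f"no trait value for tip {node.label!r}")
            values[id(node)] = float(traits[node.label])
            lengths[id(node)] = float(node.length or 0.0)
        else:
            c1, c2 = node.children
            v1, v2 = lengths[id(c1)], lengths[id(c2)]
            if v1 + v2 <= 0:
                raise ValueError("cannot standardize a contrast over two "
                                 "zero-length branches")
            x1, x2 = values[id(c1)], values[id(c2)]
            contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
            values[id(node)] = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2) \
                if v1 > 0 and v2 > 0 else (x1 if v2 > 0 else x2)
            extra = v1 * v2 / (v1 + v2)
            lengths[id(node)] = float(node.length or 0.0) + extra
    return np.array(contrasts)


def contrasts_correlation(tree: LabeledTree, traits_x: dict,
                          traits_y: dict) -> CorrelationResult:
    """Correlation of two traits' contrasts, forced through the origin."""
    cx = independent_contrasts(tree, traits_x)
    cy = independent_contrasts(tree, traits_y)
    n = len(cx)
    denom = math.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    if denom == 0:
        return CorrelationResult("pic_pearson_origin", np.nan, np.nan, n,
                                 ["constant"])
    r = float((cx * cy).sum() / denom)
    # t-test with n-1 df (origin regression loses no mean but one slope df)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * math.sqrt(df / max(1e-300, (1 - r * r)))
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult("pic_pearson_origin", r, p, n)


# ---------------------------------------------------------------------------
# Randomization test
# ---------------------------------------------------------------------------

def subset_randomization(gene_ids, subset_size: int, observed_stat: float,
                         n_reps: int, seed, statistic,
                         direction: str = "le"):
    """Empirical p for a statistic on random gene subsets.

    Draws ``subset_size`` genes without replacement ``n_reps`` times,
    recomputes ``statistic(subset_ids)`` and returns the add-one-corrected
    one-sided p, (r + 1) / (n + 1), where r counts replicates with statistic
    <= observed (``direction='le'``) or >= observed (``'ge'``).
    """
    gene_ids = list(gene_ids)
    if subset_size > len(gene_ids):
        raise ValueError("subset_size exceeds the gene universe")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    rng = np.random.default_rng(seed)
    reps, failed = [], 0
    for _ in range(n_reps):
        subset = rng.choice(len(gene_ids), size=subset_size, replace=False)
        try:
            reps.append(float(statistic([gene_ids[i] for i in subset])))
        except Exception:   # replicate dropped but counted
            failed += 1
            reps.append(np.nan)
    reps = np.asarray(reps)
    if failed:
        import warnings
        warnings.warn(f"{failed} randomization replicates failed",
                      stacklevel=2)
    ok = np.isfinite(reps)
    if direction == "le":
        r = int((reps[ok] <= observed_stat + 1e-12).sum())
    else:
        r = int((reps[ok] >= observed_stat - 1e-12).sum())
    p = (r + 1) / (n_reps + 1)
    return p, reps


# ---------------------------------------------------------------------------
# Wilcoxon rank sum (Mann-Whitney)
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(a, b):
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    sums = np.array([sum(c) for c in itertools.combinations(ranks, n1)])
    p_le = np.mean(sums <= obs + 1e-12)
    p_ge = np.mean(sums >= obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def wilcoxon_rank_sum(a, b):
    """Two-sided Mann-Whitney rank-sum test.

    Exact by enumeration of rank assignments when both samples have
    <= 8 values (valid with ties); otherwise the tie-corrected normal
    approximation. Returns (U statistic, p, flags).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    flags = []
    if np.ptp(np.concatenate([a, b])) == 0:
        u = len(a) * len(b) / 2
        return u, 1.0, ["all_tied"]
    if len(a) <= EXACT_WILCOXON_MAX and len(b) <= EXACT_WILCOXON_MAX:
        u, _ = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        p = _exact_rank_sum_p(a, b)
        flags.append("exact")
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
    return float(u), float(p), flags


# ---------------------------------------------------------------------------
# Time-corrected GC3 conservation
# ---------------------------------------------------------------------------

@dataclass
class PairConservation:
    """gamma = -t / ln(tau) for one species pair.

    tau is the Kendall tau-b of per-gene GC3 between the two species; t is
    the divergence time in whatever units are supplied (gamma is comparable
    only within a run). gamma is defined for 0 < tau < 1.
    """

    species_a: str
    species_b: str
    t: float
    tau: float
    gamma: float
    n_genes: int
    flags: list[str] = field(default_factory=list)


def gc3_conservation_index(gc3_a: pd.Series, gc3_b: pd.Series, t: float,
                           species_a: str = "sp1", species_b: str = "sp2",
                           min_genes: int = 10) -> PairConservation:
    """Time-corrected GC3 conservation for one species pair.

    Inputs are per-gene GC3 Series indexed by ortholog id; only shared,
    finite genes are used. Natural log. tau <= 0 -> gamma undefined
    ('no_conservation_signal'); tau = 1 -> gamma = +inf ('perfect').
    """
    if t <= 0:
        raise ValueError("divergence time must be > 0")
    joined = pd.concat([gc3_a, gc3_b], axis=1, join="inner",
                       keys=["a", "b"]).dropna()
    n = len(joined)
    if n < min_genes:
        raise ValueError(f"only {n} shared genes, need >= {min_genes}")
    tau, _ = stats.kendalltau(joined["a"], joined["b"])
    tau = float(tau)
    flags = []
    if tau <= 0:
        gamma = np.nan
        flags.append("no_conservation_signal")
    elif tau >= 1.0:
        gamma = np.inf
        flags.append("perfect")
    else:
        gamma = -t / math.log(tau)
    return PairConservation(species_a, species_b, float(t), tau, gamma, n,
                            flags)


def select_independent_pairs(candidates: pd.DataFrame,
                             exclude: set | None = None,
                             min_t: float = 0.0,
                             max_pairs: int | None = None,
                             order: str = "shallow_first") -> pd.DataFrame:
    """Greedy selection of disjoint species pairs from a candidate table.

    ``candidates`` has columns species_a, species_b, t. Pairs are taken in
    order of increasing divergence time (``shallow_first``, maximising the
    number of closely related pairs) or decreasing (``deep_first``,
    preferring deeper splits over intra-genus pairs); ``min_t`` drops
    near-zero splits either way. Pairs reusing a species or touching
    ``exclude`` are skipped. This is policy, not computation: adjust to
    taste.
    """
    exclude = set(exclude or ())
    used: set = set()
    chosen = []
    ordered = candidates.sort_values("t", ascending=order == "shallow_first",
                                     kind="mergesort")
    for row in ordered.itertuples(index=False):
        if row.t < min_t:
            continue
        if {row.species_a, row.species_b} & (used | exclude):
            continue
        chosen.append(row)
        used |= {row.species_a, row.species_b}
        if max_pairs is not None and len(chosen) >= max_pairs:
            break
    return pd.DataFrame(chosen, columns=candidates.columns)
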