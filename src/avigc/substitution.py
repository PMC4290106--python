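"""Tamura (1992) substitution model: closed-form transition probabilities,
maximum-likelihood fitting on a fixed tree, per-branch expected weak->strong
(W->S) and strong->weak (S->W) substitution counts, and equilibrium GC3*.

The T92 model is an HKY-family model constrained to pi_G = pi_C = theta/2
and pi_A = pi_T = (1-theta)/2, with transition/transversion ratio kappa.
The rate matrix is normalised to one expected substitution per site per
unit branch length at stationarity.

GC3* - the composition expected on an infinitely long branch - is estimated
from mapped substitution counts. The default estimator normalises counts by
the W/S site opportunity, GC3* = u/(u+v) with u = W->S count per weak site
and v = S->W count per strong site; the raw summed-count ratio
(W->S)/(W->S + S->W) is available with ``normalized=False`` but tends to
1/2 at stationarity (the two total fluxes balance) and is kept for
comparison with count-ratio summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import A, C, G, T
from .trees import LabeledTree, TreeNode

WEAK = (A, T)
STRONG = (C, G)

__all__ = [
    "t92_stationary", "t92_rate_matrix", "t92_transition_matrix",
    "T92Model", "T92Results", "map_ws_substitutions",
    "BranchSubstitutionCounts", "gc3_star",
]


# ---------------------------------------------------------------------------
# Model primitives
# ---------------------------------------------------------------------------

def t92_stationary(theta: float) -> np.ndarray:
    """Stationary distribution (A, C, G, T) = ((1-t)/2, t/2, t/2, (1-t)/2)."""
    theta = float(theta)
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0,1), got {theta}")
    return np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])


def _beta(theta, kappa):
    # normaliser: mean rate kappa*theta*(1-theta)*beta + beta/2 = 1
    return 1.0 / (kappa * theta * (1 - theta) + 0.5)


def t92_rate_matrix(theta: float, kappa: float) -> np.ndarray:
    """Normalised T92 rate matrix (states A, C, G, T)."""
    pi = t92_stationary(theta)
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    b = _beta(theta, kappa)
    Q = np.empty((4, 4))
    transitions = {(A, G), (G, A), (C, T), (T, C)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = b * pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def t92_transition_matrix(theta, kappa, t):
    """Closed-form T92 transition-probability matrix P(t).

    ``theta`` and ``t`` may be broadcastable arrays; the result has shape
    ``broadcast + (4, 4)``. Rows sum to 1 to within 1e-12.
    """
    theta = np.asarray(theta, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("branch length must be >= 0")
    if np.any((theta <= 0) | (theta >= 1)):
        raise ValueError("theta must be in (0,1)")
    theta, t = np.broadcast_arrays(theta, t)
    b = _beta(theta, kappa)
    e2 = np.exp(-b * t)                        # transversion mixing
    e3 = np.exp(-b * (kappa + 1) / 2 * t)      # within-class transitions
    piS = theta / 2        # pi_C = pi_G
    piW = (1 - theta) / 2  # pi_A = pi_T
    P = np.empty(theta.shape + (4, 4))
    # purines A,G (indices 0,2); pyrimidines C,T (1,3); pi_R = pi_Y = 1/2
    P[..., A, A] = piW * (1 + e2) + theta * e3
    P[..., A, G] = piS * (1 + e2) - theta * e3
    P[..., G, A] = piW * (1 + e2) - (1 - theta) * e3
    P[..., G, G] = piS * (1 + e2) + (1 - theta) * e3
    P[..., C, C] = piS * (1 + e2) + (1 - theta) * e3
    P[..., C, T] = piW * (1 + e2) - (1 - theta) * e3
    P[..., T, C] = piS * (1 + e2) - theta * e3
    P[..., T, T] = piW * (1 + e2) + theta * e3
    for i, js in ((A, (C, T)), (G, (C, T)), (C, (A, G)), (T, (A, G))):
        for j in js:
            pij = piS if j in STRONG else piW
            P[..., i, j] = pij * (1 - e2)
    return P


# ---------------------------------------------------------------------------
# Tree flattening
# ---------------------------------------------------------------------------

class TreeArrays:
    """Postorder-indexed arrays for a rooted tree (root last)."""

    def __init__(self, tree: LabeledTree):
        self.tree = tree
        self.nodes: list[TreeNode] = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.index = index
        n = len(self.nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.length = np.zeros(n)
        for i, node in enumerate(self.nodes):
            for ch in node.children:
                self.parent[index[id(ch)]] = i
            self.length[i] = node.length if node.length is not None else 0.0
        self.root = n - 1
        self.tip_index = {node.label: i for i, node in enumerate(self.nodes)
                          if node.is_leaf}

    @property
    def n_nodes(self):
        return len(self.nodes)

    def root_path(self, tip_label: str) -> list[int]:
        """Node indices on the path root -> tip (excluding the root node;
        each index addresses the branch above that node)."""
        path = []
        i = self.tip_index[tip_label]
        while i != self.root:
            path.append(i)
            i = self.parent[i]
        return path[::-1]


def _tip_partials(codes: np.ndarray) -> np.ndarray:
    """(n_taxa, n_sites, 4) tip partial likelihoods; N/gap -> all ones."""
    n_taxa, n_sites = codes.shape
    L = np.zeros((n_taxa, n_sites, 4))
    for s in range(4):
        L[:, :, s] = codes == s
    L[codes >= 4] = 1.0
    return L


def _compress_patterns(codes: np.ndarray):
    pats, inverse, counts = np.unique(codes, axis=1, return_inverse=True,
                                      return_counts=True)
    return pats, counts.astype(float), inverse


# ---------------------------------------------------------------------------
# Maximum-likelihood fit (statsmodels-flavoured Model / Results pair)
# ---------------------------------------------------------------------------

class T92Model:
    """ML estimation of (theta, kappa[, branch scale]) on a fixed tree.

    Parameters
    ----------
    codes : (n_taxa, n_sites) uint8
        Encoded third-position columns (A=0,C=1,G=2,T=3; N=4 and gap=5 are
        treated as missing).
    taxa : list of str
        Row labels of ``codes``; must all appear in the tree.
    tree : LabeledTree
        Rooted tree with branch lengths in substitutions/site.
    """

    def __init__(self, codes: np.ndarray, taxa: list[str], tree: LabeledTree):
        self.arr = TreeArrays(tree)
        missing = set(taxa) - set(self.arr.tip_index)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
        if codes.shape[0] != len(taxa):
            raise ValueError("codes/taxa shape mismatch")
        if len(taxa) < 2:
            raise ValueError("need at least two taxa")
        self.taxa = list(taxa)
        self.codes = codes
        self.patterns, self.weights, self.pattern_index = \
            _compress_patterns(codes)
        self.n_sites = codes.shape[1]
        self._tipL = _tip_partials(self.patterns)
        counted = self.patterns < 4
        gc = ((self.patterns == G) | (self.patterns == C))
        self.observed_gc = float(gc.sum() / max(1, counted.sum()))
        var_cols = np.array([
            len({x for x in col if x < 4}) > 1 for col in self.patterns.T])
        self.n_variable = int(self.weights[var_cols].sum())

    @classmethod
    def from_alignment(cls, alignment, tree: LabeledTree,
                       positions: str = "c3") -> "T92Model":
        """Build from a coding :class:`~avigc.io.OrthologAlignment`
        (third positions by default) or an intron alignment (all sites)."""
        from .composition import _class_columns
        cls_name = positions if alignment.kind == "coding" else "intron"
        cols = _class_columns(cls_name, alignment.length)
        codes = alignment.codes()[:, cols]
        return cls(codes, alignment.species, tree)

    # -- likelihood ----------------------------------------------------
    def _branch_matrices(self, theta, kappa, scale=1.0):
        return t92_transition_matrix(theta, kappa,
                                     self.arr.length * scale)

    def loglike(self, theta: float, kappa: float, scale: float = 1.0):
        """Felsenstein pruning log-likelihood over compressed patterns."""
        P = self._branch_matrices(theta, kappa, scale)
        arr = self.arr
        npat = self.patterns.shape[1]
        partial = np.ones((arr.n_nodes, npat, 4))
        taxon_row = {t: r for r, t in enumerate(self.taxa)}
        for label, i in arr.tip_index.items():
            if label in taxon_row:
                partial[i] = self._tipL[taxon_row[label]]
        logscale = np.zeros(npat)
        for i, node in enumerate(arr.nodes):
            if node.is_leaf:
                continue
            acc = np.ones((npat, 4))
            for ch in node.children:
                ci = arr.index[id(ch)]
                acc *= partial[ci] @ P[ci].T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            partial[i] = acc / mx[:, None]
        pi = t92_stationary(theta)
        siteL = partial[arr.root] @ pi
        return float(np.dot(self.weights, np.log(siteL) + logscale))

    def fit(self, estimate_scale: bool = False, tol: float = 1e-8
            ) -> "T92Results":
        """Bounded quasi-Newton ML fit with deterministic starting points
        (theta = observed GC, kappa = 2, scale = 1)."""
        if self.n_variable == 0:
            warnings.warn("alignment has no variable sites; returning "
                          "observed-frequency theta", stacklevel=2)
            return T92Results(self, np.clip(self.observed_gc, 1e-6, 1 - 1e-6),
                              2.0, 1.0, np.nan, converged=True,
                              flags=["no_variable_sites"])

        def unpack(x):
            theta = 1 / (1 + np.exp(-x[0]))
            kappa = np.exp(x[1])
            scale = np.exp(x[2]) if estimate_scale else 1.0
            return theta, kappa, scale

        def nll(x):
            theta, kappa, scale = unpack(x)
            return -self.loglike(theta, kappa, scale)

        th0 = np.clip(self.observed_gc, 0.01, 0.99)
        x0 = [np.log(th0 / (1 - th0)), np.log(2.0)]
        if estimate_scale:
            x0.append(0.0)
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-7})
        if not res.success and abs(res.fun) < np.inf:
            # one polite retry from a neutral start before giving up
            res2 = optimize.minimize(
                nll, [0.0, np.log(2.0)] + ([0.0] if estimate_scale else []),
                method="L-BFGS-B", options={"ftol": tol, "gtol": 1e-7})
            if res2.fun < res.fun:
                res = res2
        if not res.success:
            raise RuntimeError(f"T92 optimisation did not converge: "
                               f"{res.message}")
        theta, kappa, scale = unpack(res.x)
        bse = self._standard_errors(res.x, estimate_scale)
        return T92Results(self, theta, kappa, scale, -res.fun,
                          converged=True, bse=bse)

    def _standard_errors(self, xhat, estimate_scale):
        """Delta-method SEs for (theta, kappa[, scale]) from a finite-
        difference Hessian in the unconstrained parameterisation."""
        def nll(x):
            theta = 1 / (1 + np.exp(-x[0]))
            kappa = np.exp(x[1])
            scale = np.exp(x[2]) if estimate_scale else 1.0
            return -self.loglike(theta, kappa, scale)

        k = len(xhat)
        h = 1e-4
        H = np.zeros((k, k))
        f0 = nll(xhat)
        for i in range(k):
            for j in range(i, k):
                xi = np.array(xhat, dtype=float)
                xj = xi.copy(); xij = xi.copy()
                xi[i] += h; xj[j] += h
                xij[i] += h; xij[j] += h
                H[i, j] = H[j, i] = (nll(xij) - nll(xi) - nll(xj) + f0) / h**2
        try:
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            if (var <= 0).any():
                return None
            se = np.sqrt(var)
        except np.linalg.LinAlgError:
            return None
        theta = 1 / (1 + np.exp(-xhat[0]))
        out = {"theta": se[0] * theta * (1 - theta),
               "kappa": se[1] * np.exp(xhat[1])}
        if estimate_scale:
            out["scale"] = se[2] * np.exp(xhat[2])
        return out


@dataclass
class T92Results:
    """Fitted T92 parameters with uncertainties and a summary table."""

    model: T92Model
    theta: float
    kappa: float
    scale: float
    llf: float
    converged: bool
    bse: dict | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> dict:
        return {"theta": self.theta, "kappa": self.kappa,
                "scale": self.scale}

    @property
    def nobs(self) -> int:
        return self.model.n_sites

    def transition_matrix(self, t: float) -> np.ndarray:
        return t92_transition_matrix(self.theta, self.kappa,
                                     np.asarray(t) * self.scale)

    def map_substitutions(self, mode: str = "endpoint"):
        return map_ws_substitutions(self.model.codes, self.model.taxa,
                                    self.model.arr.tree, self.theta,
                                    self.kappa, scale=self.scale, mode=mode)

    def summary(self) -> str:
        lines = [
            "T92 substitution model (maximum likelihood)",
            "=" * 47,
            f"{'sites':<28}{self.nobs:>12}",
            f"{'variable sites':<28}{self.model.n_variable:>12}",
            f"{'taxa':<28}{len(self.model.taxa):>12}",
            f"{'log-likelihood':<28}{self.llf:>12.3f}",
            "-" * 47,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name in ("theta", "kappa", "scale"):
            se = self.bse.get(name) if self.bse else None
            se_s = f"{se:>12.4g}" if se is not None else f"{'--':>12}"
            lines.append(f"{name:<10}{self.params[name]:>12.4f}{se_s}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Substitution mapping
# ---------------------------------------------------------------------------

@dataclass
class BranchSubstitutionCounts:
    """Expected W->S / S->W counts per branch plus site opportunities.

    ``table`` columns: branch_id, node (postorder index), parent, length,
    is_tip, E_WS, E_SW, W_opp, S_opp. ``tip_paths`` maps each tip label to
    the postorder node indices on its root path.
    """

    table: pd.DataFrame
    tip_paths: dict[str, list[int]]
    n_sites: int
    mode: str


def _labeled_count_matrices(theta, kappa, t):
    """E[#label events | parent=x, child=y] for W->S and S->W labels.

    Uses the eigen-decomposition integral for expected labelled Markov
    transitions (exact, not the endpoint approximation).
    """
    Q = t92_rate_matrix(theta, kappa)
    lam, U = np.linalg.eig(Q)
    lam = lam.real
    U = U.real
    Uinv = np.linalg.inv(U)
    P = t92_transition_matrix(theta, kappa, t)
    out = {}
    dl = np.subtract.outer(lam, lam)
    el = np.exp(lam * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(np.abs(dl) > 1e-12,
                     np.subtract.outer(el, el) / np.where(dl == 0, 1, dl),
                     t * el[:, None])
    for name, (src, dst) in (("WS", (WEAK, STRONG)), ("SW", (STRONG, WEAK))):
        L = np.zeros((4, 4))
        for i in src:
            for j in dst:
                L[i, j] = Q[i, j]
        inner = (Uinv @ L @ U) * F
        J = (U @ inner @ Uinv).real
        with np.errstate(divide="ignore", invalid="ignore"):
            out[name] = np.where(P > 1e-300, J / np.maximum(P, 1e-300), 0.0)
    return out


def map_ws_substitutions(codes: np.ndarray, taxa: list[str],
                         tree: LabeledTree, theta: float, kappa: float,
                         scale: float = 1.0, mode: str = "endpoint"
                         ) -> BranchSubstitutionCounts:
    """Expected per-branch W->S and S->W substitution counts.

    Per site, the joint posterior over parent-child state pairs at each
    branch is computed with inside-outside (pruning + downward) passes
    under the fitted model. ``mode='endpoint'`` counts a substitution when
    the endpoint states differ (adequate on short branches);
    ``mode='labeled'`` weighs each state pair by the analytic expected
    number of labelled events, accounting for multiple hits.

    Site opportunities (expected number of weak/strong parent states) are
    reported per branch so rate-normalised GC* can be formed downstream.
    """
    if mode not in ("endpoint", "labeled"):
        raise ValueError("mode must be 'endpoint' or 'labeled'")
    arr = TreeArrays(tree)
    patterns, weights, _ = _compress_patterns(codes)
    tipL = _tip_partials(patterns)
    npat = patterns.shape[1]
    lengths = arr.length * scale
    P = t92_transition_matrix(theta, kappa, lengths)
    pi = t92_stationary(theta)

    taxon_row = {t_: r for r, t_ in enumerate(taxa)}
    down = np.ones((arr.n_nodes, npat, 4))
    for label, i in arr.tip_index.items():
        if label in taxon_row:
            down[i] = tipL[taxon_row[label]]
    # inside pass (no rescaling: fine for trees of this size)
    M = np.ones((arr.n_nodes, npat, 4))   # message child -> parent
    for i, node in enumerate(arr.nodes):
        if not node.is_leaf:
            acc = np.ones((npat, 4))
            for ch in node.children:
                ci = arr.index[id(ch)]
                M[ci] = down[ci] @ P[ci].T
                acc = acc * M[ci]
            down[i] = acc
    siteL = down[arr.root] @ pi

    # outside pass
    up = np.ones((arr.n_nodes, npat, 4))
    up[arr.root] = pi
    for i in range(arr.n_nodes - 1, -1, -1):
        node = arr.nodes[i]
        for ch in node.children:
            ci = arr.index[id(ch)]
            sib = up[i].copy()
            for ch2 in node.children:
                if ch2 is not ch:
                    sib *= M[arr.index[id(ch2)]]
            up[ci] = sib @ P[ci]          # note: not yet conditioned on below

    rows = []
    if mode == "labeled":
        lab = {i: _labeled_count_matrices(theta, kappa, lengths[i])
               for i in range(arr.n_nodes) if i != arr.root}
    for i, node in enumerate(arr.nodes):
        if i == arr.root:
            continue
        p = arr.parent[i]
        sib = up[p].copy()
        for ch2 in arr.nodes[p].children:
            ci2 = arr.index[id(ch2)]
            if ci2 != i:
                sib *= M[ci2]
        # joint[x, y] per pattern: sib(x) * P[i][x,y] * down[i](y)
        joint = sib[:, :, None] * P[i][None, :, :] * down[i][:, None, :]
        with np.errstate(invalid="ignore"):
            joint /= siteL[:, None, None]
        flagged = ~np.isfinite(joint).all(axis=(1, 2))
        if flagged.any():
            joint[flagged] = 0.0
        wjoint = (joint * weights[:, None, None]).sum(axis=0)
        if mode == "endpoint":
            e_ws = wjoint[np.ix_(WEAK, STRONG)].sum()
            e_sw = wjoint[np.ix_(STRONG, WEAK)].sum()
        else:
            e_ws = (wjoint * lab[i]["WS"]).sum()
            e_sw = (wjoint * lab[i]["SW"]).sum()
        parent_marg = wjoint.sum(axis=1)
        rows.append({
            "branch_id": _node_branch_id(node), "node": i, "parent": p,
            "length": lengths[i], "is_tip": node.is_leaf,
            "E_WS": float(e_ws), "E_SW": float(e_sw),
            "W_opp": float(parent_marg[list(WEAK)].sum()),
            "S_opp": float(parent_marg[list(STRONG)].sum()),
        })
    tip_paths = {label: arr.root_path(label)
                 for label in arr.tip_index if label in taxon_row}
    return BranchSubstitutionCounts(table=pd.DataFrame(rows),
                                    tip_paths=tip_paths,
                                    n_sites=codes.shape[1], mode=mode)


def _node_branch_id(node: TreeNode) -> str:
    from .coalescent import branch_id
    return branch_id(node)


# ---------------------------------------------------------------------------
# GC3*
# ---------------------------------------------------------------------------

def _star(e_ws, e_sw, w_opp_t, s_opp_t, normalized):
    tot = e_ws + e_sw
    if tot <= 0:
        return np.nan
    if not normalized:
        return e_ws / tot
    if w_opp_t <= 0 or s_opp_t <= 0:
        return np.nan
    u = e_ws / w_opp_t
    v = e_sw / s_opp_t
    return u / (u + v)


def gc3_star(counts: BranchSubstitutionCounts,
             scope: str = "per_tip_root_path",
             normalized: bool = True):
    """Equilibrium GC3* from mapped substitution counts.

    scope:
      - ``per_tip_root_path``: counts summed over all branches from the
        root to each tip before the ratio -> Series by tip label.
      - ``per_branch``: branch-wise GC3* -> DataFrame.
      - ``whole_tree``: one value over all branches.

    With ``normalized=True`` (default) the ratio is of per-opportunity
    rates u/(u+v); with ``normalized=False`` it is the raw summed-count
    ratio W->S/(W->S + S->W).
    """
    tb = counts.table.set_index("node")
    if scope == "per_tip_root_path":
        out = {}
        for tip, path in counts.tip_paths.items():
            sub = tb.loc[path]
            out[tip] = _star(sub["E_WS"].sum(), sub["E_SW"].sum(),
                             (sub["W_opp"] * sub["length"]).sum(),
                             (sub["S_opp"] * sub["length"]).sum(),
                             normalized)
        return pd.Series(out, name="gc3_star").sort_index()
    if scope == "per_branch":
        vals = [
            _star(r.E_WS, r.E_SW, r.W_opp * r.length, r.S_opp * r.length,
                  normalized)
            for r in tb.itertuples()]
        out = counts.table[["branch_id", "is_tip"]].copy()
        out["gc3_star"] = vals
        return out
    if scope == "whole_tree":
        return _star(tb["E_WS"].sum(), tb["E_SW"].sum(),
                     (tb["W_opp"] * tb["length"]).sum(),
                     (tb["S_opp"] * tb["length"]).sum(), normalized)
    raise ValueError(f"unknown scope {scope!r}")
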