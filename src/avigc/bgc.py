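"""GC-biased gene conversion: fixation bias and approach to equilibrium.

gBGC makes GC alleles in A/C / G/T heteroduplexes behave as if positively
selected with a selection-equivalent conversion coefficient b. With
per-generation W->S substitution rate u per weak site and S->W rate v per
strong site, GC content follows

    g(t) = g* + (g0 - g*) e^{-(u+v) t},   g* = u / (u + v),

so the time to halve the distance to equilibrium is t_half = ln 2 / (u+v),
independent of the starting composition. An optional population layer
derives u and v from mutation rates, Ne and b via Kimura-form fixation
probabilities (haploid-equivalent bookkeeping: substitution rate =
2 Ne * mu * P_fix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["fixation_probability", "GBGCDynamics", "dynamics_from_population",
           "gc_halving_time", "gc_trajectory"]


def fixation_probability(ne: float, b: float) -> float:
    """Fixation probability of a new mutant with conversion coefficient b.

    P = (1 - e^{-2b}) / (1 - e^{-4 Ne b}) for b != 0; the neutral limit is
    1/(2 Ne). Overflow-guarded for large |Ne*b|.
    """
    if ne < 1:
        raise ValueError("Ne must be >= 1")
    if b == 0:
        return 1.0 / (2.0 * ne)
    x = 4.0 * ne * b
    if b < -350:           # both terms overflow; P = e^{x-2b}(...) -> 0
        return 0.0
    num = -math.expm1(-2.0 * b)
    if x > 700:            # denominator ~ 1
        return min(1.0, num)
    if x < -700:           # strongly disfavoured: P ~ -num * e^{x} -> 0
        return abs(num) * math.exp(x) if x - math.log(max(abs(num), 1e-300)) \
            > -745 else 0.0
    return num / -math.expm1(-x)


@dataclass
class GBGCDynamics:
    """Deterministic approach of GC content to its equilibrium.

    u, v are per-generation substitution rates per weak / strong site.
    """

    g0: float
    u: float
    v: float

    def __post_init__(self):
        if not 0 <= self.g0 <= 1:
            raise ValueError("g0 must be in [0,1]")
        if self.u < 0 or self.v < 0:
            raise ValueError("rates must be >= 0")

    @property
    def g_star(self) -> float:
        if self.u + self.v == 0:
            return float("nan")
        return self.u / (self.u + self.v)

    @property
    def t_half(self) -> float:
        """Generations to halve |g - g*|; infinite when u + v = 0."""
        if self.u + self.v == 0:
            return float("inf")
        return math.log(2.0) / (self.u + self.v)

    def trajectory(self, t):
        """g(t) = g* + (g0 - g*) exp(-(u+v) t); t in generations."""
        t = np.asarray(t, dtype=float)
        if self.u + self.v == 0:
            return np.full_like(t, self.g0)
        return self.g_star + (self.g0 - self.g_star) * np.exp(
            -(self.u + self.v) * t)


def dynamics_from_population(g0: float, ne: float, mu_ws: float,
                             mu_sw: float, b: float) -> GBGCDynamics:
    """Population layer: u = 2 Ne * mu_WS * P_fix(Ne, +b) and
    v = 2 Ne * mu_SW * P_fix(Ne, -b).

    mu rates are per site per generation; b is the conversion coefficient
    favouring the strong allele.
    """
    if mu_ws < 0 or mu_sw < 0:
        raise ValueError("mutation rates must be >= 0")
    u = 2.0 * ne * mu_ws * fixation_probability(ne, +b)
    v = 2.0 * ne * mu_sw * fixation_probability(ne, -b)
    return GBGCDynamics(g0=g0, u=u, v=v)


def gc_halving_time(dynamics: GBGCDynamics) -> float:
    return dynamics.t_half


def gc_trajectory(dynamics: GBGCDynamics, t):
    return dynamics.trajectory(t)


def iterate_gc(dynamics: GBGCDynamics, n_generations: int) -> float:
    """Per-generation update g <- g + u(1-g) - v g, iterated explicitly.

    Independent discrete-time route used to cross-check the closed form.
    """
    g = dynamics.g0
    u, v = dynamics.u, dynamics.v
    for _ in range(int(n_generations)):
        g = g + u * (1.0 - g) - v * g
    return g


def wright_fisher_fixation(ne: int, b: float, n_reps: int, seed,
                           p0: float | None = None) -> float:
    """Forward Wright-Fisher fixation frequency of a GC mutant.

    2*Ne haploid copies; the strong allele's frequency advances by
    p' = p(1+b) / (1 + p b) (additive conversion advantage) before binomial
    resampling. Returns the fraction of ``n_reps`` replicates that fix.
    Vectorised over replicates.
    """
    rng = np.random.default_rng(seed)
    n = 2 * int(ne)
    count = np.full(n_reps, 1 if p0 is None else int(round(p0 * n)),
                    dtype=np.int64)
    fixed = 0
    while count.size:
        p = count / n
        p = p * (1 + b) / (1 + p * b)
        count = rng.binomial(n, p)
        fixed += int((count == n).sum())
        count = count[(count > 0) & (count < n)]
    return fixed / n_reps
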