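# Methods

`avigc` tests whether GC-biased gene conversion (gBGC), modulated by life
history, can account for between-lineage differences in avian base
composition. The pipeline has six analysis stages — nucleotide composition,
trait correlations, the time-corrected GC3 conservation index γ, ancestral
population sizes from gene-tree discordance, equilibrium GC3* from
substitution mapping, and recombination-window statistics — plus a
synthetic-data generator that realises the statistical structure the
analysis assumes, so every stage is testable without external genome data.

## Composition

GC fractions are counts of G+C over counted sites (gaps and N excluded from
numerator and denominator; a codon containing a gap still contributes its
non-gap positions). Pooling across orthologs sums counts before dividing —
length-weighted, never a mean of fractions — so short sequences do not add
noise. Pooled comparisons are restricted to orthologs present in all
species. The GC123 numerator and denominator are exactly the sums of the
per-position ones on every input; this identity is asserted in tests.

Orthologs are ranked by between-species sample variance (n−1) of GC3; the
top-k and bottom-k (k defaults to 830, capped at half the rankable set)
form the high/low-variance partitions, with lexicographic tie-breaks for
determinism.

The "homogeneity" label is a species × {strong, weak} contingency
chi-square on third-position counts (df = n_species − 1, default
α = 0.01). It is an interface-compatible stand-in for a
nonstationary-versus-stationary model comparison, not a likelihood-ratio
test against a nonstationary substitution model; the LRT hook is left as
an extension point. Its type-I error is calibrated by simulation
(stationary genes rejected at ≈ α).

## Trait statistics

Rank correlations use Spearman (average ranks) or Kendall τ-b. For n ≤ 9
pairs the two-sided p is exact, from the full permutation distribution
conditional on the observed (possibly tied) ranks; larger n uses the
asymptotic approximation. Rank-sum comparisons are two-sided Mann–Whitney,
exact by enumeration of rank assignments when both samples have ≤ 8 values
(valid under ties), tie-corrected normal approximation otherwise.

Phylogenetically independent contrasts follow the standard recursive
pruning (contrast (x₁−x₂)/√(v₁+v₂); ancestral value weighted by inverse
branch lengths; branch extended by v₁v₂/(v₁+v₂)); trait–trait association
on contrasts is a correlation through the origin. The gene-subset
randomization test draws subsets without replacement and reports the
one-sided add-one-corrected p, (r+1)/(n+1), so "none of N randomizations"
is reported as p < 1/(N+1) rather than zero.

The conservation index for a species pair is γ = −t / ln τ, with τ the
Kendall τ-b of per-gene GC3 between the two species over shared genes
(≥ 10 required) and t the divergence time in whatever units are supplied
(γ is comparable only within a run; the log is natural). γ is undefined
for τ ≤ 0 (flagged) and +∞ for τ = 1. Because τ is a rank statistic, γ is
exactly invariant under strictly monotone transformations of either
species' values. Pair selection (disjoint pairs, exclusions, depth
preference) is a documented, configurable policy helper, not computation.

## Coalescent branch lengths and ancestral Ne

Gene trees are reconciled with the species tree by topology-only LCA
mapping via a double-recursive traversal; for each species-tree branch the
number of gene lineages at its rootward and tipward ends is recorded. Over
all gene trees, n12 counts trees entering a branch with two lineages and
leaving with one (coalescence inside the branch) and nkk counts trees
entering and leaving with the same k ≥ 2 lineages.

A pair that fails to coalesce inside the branch still produces the
concordant clade deeper in the tree with probability 1/3 (when it mixes
with one other lineage), and is then indistinguishable from an in-branch
coalescence under topology-only mapping. The raw count ratio therefore
understates non-coalescence by a factor 2/3, and the default estimator
corrects for it:

    length = ln( (n12 + nkk) / (1.5 · nkk) ),  clipped at 0.

The correction is exact for branches entered by two lineages — the cherry
branches to which the population-size analysis is restricted — and is
validated by simulation (recovery within 3 binomial SE over T ∈
[0.2, 2]). `correction="none"` gives the literal ln((n12+nkk)/nkk).
Terminal branches are undefined (no information with one lineage per
species); nkk = 0 gives +∞, flagged. Polytomies map all children upward
and land in nkk (conservative). Gene trees with missing species
contribute only where both descendant sides retain a sampled lineage —
this falls out of the counting rather than being special-cased.

Population size for a branch is N = span / (2 · length · g), with span the
internodal time span (yr) and g the mean generation time at the branch's
two ends. With a maturity proxy for g these values are overestimates;
outputs carry a rank column and should be read as rank order. Default
filters: coalescent length ≥ 0.1, node support ≥ 50, cherry branches only.

## T92 model, substitution mapping and GC3*

The T92 model fixes π_G = π_C = θ/2, π_A = π_T = (1−θ)/2 with
transition/transversion ratio κ; rates are normalised to one expected
substitution per site per unit branch length at stationarity
(β = 1/(κθ(1−θ) + ½)). Transition probabilities use the closed form (the
within-class eigenvalue is β(κ+1)/2, the mixing eigenvalue β), verified
against a matrix-exponential oracle to 1e-10.

Fitting maximises the pruning-algorithm likelihood over (θ, κ[, global
branch scale]) with bounded quasi-Newton from deterministic starts
(θ = observed GC, κ = 2, scale = 1), tolerance 1e-8 on the log-likelihood;
invariant alignments return observed-frequency θ with a flag. Standard
errors come from a finite-difference Hessian in the unconstrained
parameterisation, delta-method transformed. `T92Model(...).fit()` returns
a results object with estimates, SEs, and `summary()`.

Mapping computes, per site and branch, the joint posterior over
parent–child state pairs by inside–outside passes. Two counting rules:
`endpoint` (default) counts posterior mass on W→S / S→W state pairs —
adequate on short branches but blind to multiple hits; `labeled` weighs
each state pair by the analytic expected number of labelled Markov events
(eigen-decomposition integral), exact under the model and the rule used
when counts are compared with logged true events. Both are cross-validated
against an event-logging simulator.

GC3* is estimated from mapped counts. The raw summed-count ratio
W→S/(W→S+S→W) tends to 1/2 at stationarity for any θ, because the two
total fluxes balance (π_W·u = π_S·v at equilibrium); it cannot estimate
the equilibrium composition. The default estimator therefore normalises by
opportunity: u = ΣE_WS / Σ(W_opp·t), v = ΣE_SW / Σ(S_opp·t), GC3* =
u/(u+v), where W_opp/S_opp are the expected numbers of weak/strong parent
states on each branch. Under stationary simulation this recovers θ
(within 0.03 at 50k sites); under terminal-branch shifts GC3* runs ahead
of current GC3, with a regression slope of GC3* on GC3 above 1 — the
signature of recent, ongoing GC gain. `normalized=False` retains the raw
ratio. Scope is per-tip root-path sums by default; per-branch and
whole-tree scopes cover branch-level analyses.

## gBGC dynamics

With per-generation rates u (W→S per weak site) and v (S→W per strong
site), GC follows g(t) = g* + (g0 − g*)e^{−(u+v)t}, g* = u/(u+v), so the
half-life of the distance to equilibrium is t½ = ln2/(u+v), independent
of g0 and exactly ∝ 1/(u+v). The optional population layer sets
u = 2Ne·μ_WS·P_fix(+b) and v = 2Ne·μ_SW·P_fix(−b) (haploid-equivalent
bookkeeping; the diploid constant cancels in the ratios of interest), with
Kimura-form fixation P = (1−e^{−2b})/(1−e^{−4Ne·b}) for a conversion
coefficient b acting like additive selection. The formula is validated
against forward Wright–Fisher simulation (2Ne copies, p′ = p(1+b)/(1+pb)).

Defaults: μ_WS = 1e-9, μ_SW = 2e-9 per site per generation (AT-biased
mutation, 2:1), b = 1e-6, giving a population-scaled strength
B = 4Ne·b between 0.4 and 4 over Ne ∈ [1e5, 1e6] — the genome-wide range
usually inferred for gBGC. Under these settings the halving time is
1.6–2.5 × 1e8 generations across that Ne range: equilibrium is approached
on timescales far longer than the divergences studied, which is why
current GC3 lags GC3*.

## Recombination windows

Orthologs are assigned to the recombination-map window with maximal bp
overlap (ties to the lower start); windows are taken as given, with no
re-binning or interpolation. Per-ortholog between-species mean and sd of
GC3 are correlated (Spearman) with window rates; intronic per-window GC is
pooled counts over the introns in the window and suppressed below 10
introns. Chromosome size classes default to 1–9 (large) versus 10+
(small), configurable, and are compared by two-sided rank-sum tests.

## Synthetic data

The generator emulates the structure the analysis assumes: body mass
log-normal (median ≈ 300 g, one decade sd); generation time and Ne
allometric in mass (g = 0.55·m^0.2 yr; Ne ∝ m^−0.35 around 5e5); a random
ultrametric species tree of 40 species with root age 100 My; terminal
equilibrium GC3 θ_tip = 0.42 + 0.05 + 0.08·(rank of 1/mass, centred)
+ N(0, 0.01) — an overall recent upward shift plus a negative mass link;
internal branches stationary at θ = 0.42. Third positions evolve site-
independently under branch-specific T92 (κ = 4, 3e-3 substitutions/site/My);
first/second positions use compressed deviations (15%) and a slower clock
(×0.3), mimicking selective constraint; introns sit in between. Each
gene's deviation is scaled by a multiplier equal to its window's
recombination rate (unit mean), so high-recombination windows carry
high-variance, high-GC genes. Two syntenic maps share chromosome-class
structure (small chromosomes ≈ 6 cM/Mb median versus 2 for large — at
least one crossover per chromosome) with the shared-noise weight
calibrated so the overall between-map Spearman hits its target (0.4)
including the class-mean component. Gene trees follow the standard MSC
with per-branch coalescent lengths T = span_yr/(2·Ne·g). One master seed
spawns named substreams per generator, so outputs are bit-identical under
(config, seed) and changing the gene count does not perturb trait draws.

Not emulated: codon structure (positions are simulated, not
back-translated), CpG hypermutability, indels, selection, demography,
rate heterogeneity across sites. Passing tests therefore show the
estimators recover the assumed structure, not that real genomes satisfy
it.

An event-logging mode simulates the jump chain per site and records true
W→S / S→W events (multiple hits included), providing the independent
oracle for the mapping.

## Validation studies and their designs

`avigc.validation` regenerates data under known truth for each estimator.
Design choices that matter:

- Branch-length recovery uses a four-taxon tree whose measured branch is
  surrounded by long branches, so a non-coalescing pair always mixes with
  exactly one extra lineage (the regime where the 3/2 correction is
  exact); the Ne study's caterpillar of 8 cherries places a single-taxon
  outgroup at the base for the same reason. 10,000 gene trees per study.
- GC3* studies use 20-tip trees whose splits lie in the older two-thirds
  of the depth, so every terminal branch expresses a measurable share of
  the shift; 50,000 third positions.
- Mapped-versus-true count comparisons use branches with ≥ 1000 logged
  events: an expectation can only be compared to a single realisation
  where the realisation's own sampling noise (≈1/√N) is well below the
  10% margin being tested.
- The trait-correlation power study runs 100 replicate datasets at
  generator defaults (40 species, 1,500 genes, 300 codons) simulating
  third positions only — the statistic (pooled GC3 versus mass) is
  unchanged — and 100 null replicates with the mass effect switched off
  for type-I calibration. This is the battery's dominant cost (minutes).

## Numerical choices and degenerate inputs

Likelihood pruning runs unscaled in float64 (safe to ~100 taxa at these
depths) with per-node max-rescaling in the fitting path; optimisation is
L-BFGS-B on (logit θ, log κ, log scale). Zero counted sites give flagged
missing values, never 0. Division-by-zero paths (nkk = 0, u+v = 0, τ ≤ 0,
empty opportunity) return flagged inf/NaN rather than raising. Ranking
ties break lexicographically. Fixation probabilities are overflow-guarded
for large |Ne·b|. All coordinates are 0-based half-open internally.

## Package shape

The package is organised as a pipeline of estimator modules behind flat
TSV interfaces with a thin `avigc` CLI — the natural shape for a
multi-stage comparative analysis. The one place a statistical model is
fitted to data, the T92 fit, follows the Model/Results convention
(`T92Model(...).fit() -> T92Results` with `summary()`).

## Limitations

Absolute Ne values inherit the generation-time proxy and are rank-order
quantities. The homogeneity classifier detects compositional
heterogeneity, not nonstationarity of the substitution process. The
endpoint counting rule undercounts on long branches (use `labeled`).
γ depends on the time units supplied and is comparable only within a run.
The literal raw-count GC3* and uncorrected coalescent lengths are kept as
options for comparability with count-ratio summaries, but both are biased
(toward 1/2 and upward by ln 1.5 respectively) and the defaults avoid
them.
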