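import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avigc.composition import (classify_homogeneity, composition_table,
                               gc_by_class, pooled_gc, universal_ortholog_set,
                               variance_partition)
from avigc.io import OrthologAlignment


def brute_force_gc(seq, cols):
    """Independent per-column counter (the oracle)."""
    sub = [seq[i] for i in cols]
    gc = sum(c in "GC" for c in sub)
    at = sum(c in "AT" for c in sub)
    return (gc / (gc + at) if gc + at else np.nan), gc + at


def test_hand_counted_positions(toy_coding):
    # codons ATG, GCC: c1 = {A,G}, c2 = {T,C}, c3 = {G,C}
    for cls, expect in (("c1", 0.5), ("c2", 0.5), ("c3", 1.0)):
        out = gc_by_class(toy_coding, cls)
        assert out.loc["a", "gc_fraction"] == expect


def test_gap_codon_contributes_remaining_positions():
    aln = OrthologAlignment("x", "coding", {"a": "ATG---GCA"})
    out = gc_by_class(aln, "c3")
    # third positions: G, -, A -> counted {G, A}
    assert out.loc["a", "gc_fraction"] == 0.5
    assert out.loc["a", "sites"] == 2


def test_zero_counted_sites_flagged_missing():
    aln = OrthologAlignment("x", "coding", {"a": "NNN"})
    out = gc_by_class(aln, "c3")
    assert np.isnan(out.loc["a", "gc_fraction"])


@pytest.mark.parametrize("cls,offsets", [("c1", (0,)), ("c3", (2,)),
                                         ("c12", (0, 1)),
                                         ("c123", (0, 1, 2))])
def test_matches_bruteforce_column_counter(rng, cls, offsets):
    chars = np.array(list("ACGTN-"))
    seq = "".join(rng.choice(chars, p=[.2, .25, .2, .2, .1, .05],
                             size=900))
    aln = OrthologAlignment("x", "coding", {"a": seq})
    cols = [i for i in range(900) if i % 3 in offsets]
    frac, sites = brute_force_gc(seq, cols)
    out = gc_by_class(aln, cls)
    assert out.loc["a", "sites"] == sites
    assert out.loc["a", "gc_fraction"] == pytest.approx(frac)


def test_gc123_count_identity(rng):
    """gc123 numerator and denominator are the sums over c1+c2+c3."""
    chars = np.array(list("ACGTN-"))
    for _ in range(5):
        seq = "".join(rng.choice(chars, size=300))
        aln = OrthologAlignment("x", "coding", {"a": seq})
        tab = composition_table([aln]).iloc[0]
        num123 = round(tab["gc123"] * tab["gc123_sites"])
        parts = sum(round(tab[f"gc{i}"] * tab[f"gc{i}_sites"])
                    if tab[f"gc{i}_sites"] else 0 for i in (1, 2, 3))
        assert num123 == parts
        assert tab["gc123_sites"] == sum(tab[f"gc{i}_sites"]
                                         for i in (1, 2, 3))


def test_pooled_is_count_weighted():
    a1 = OrthologAlignment("g1", "coding", {"a": "GCGGCG" + "GCG"})  # 3 GC3
    a2 = OrthologAlignment("g2", "coding", {"a": "ATA" * 300})
    pooled = pooled_gc([a1, a2], "c3")
    assert pooled["a"] == pytest.approx(3 / 303)


def test_pooled_single_gene_equals_per_gene(toy_coding):
    assert pooled_gc([toy_coding], "c3")["a"] == \
        gc_by_class(toy_coding, "c3").loc["a", "gc_fraction"]


def test_pooled_equals_concatenation_oracle(rng):
    chars = np.array(list("ACGTN-"))
    alns, concat = [], {"x": "", "y": ""}
    for g in range(50):
        L = int(rng.integers(1, 40)) * 3
        seqs = {sp: "".join(rng.choice(chars, size=L)) for sp in ("x", "y")}
        alns.append(OrthologAlignment(f"g{g}", "coding", seqs))
        for sp in concat:
            concat[sp] += alns[-1].sequences[sp]
    pooled = pooled_gc(alns, "c3")
    big = OrthologAlignment("all", "coding", concat)
    direct = gc_by_class(big, "c3")
    for sp in ("x", "y"):
        assert pooled[sp] == pytest.approx(direct.loc[sp, "gc_fraction"])


def test_pooled_missing_species_is_error(toy_coding):
    only_a = OrthologAlignment("g2", "coding", {"a": "ATG"})
    with pytest.raises(ValueError, match="absent"):
        pooled_gc([toy_coding, only_a], "c3")


def test_universal_set(rng):
    species = [f"s{i}" for i in range(8)]
    alns, expected = [], []
    for g in range(100):
        drop = rng.random(8) < 0.1
        present = [s for s, d in zip(species, drop) if not d]
        if not present:
            continue
        alns.append(OrthologAlignment(
            f"g{g:03d}", "coding", {s: "ATG" for s in present}))
        if len(present) == 8:
            expected.append(f"g{g:03d}")
    # brute-force membership scan as the oracle
    assert universal_ortholog_set(alns, roster=species) == sorted(expected)


def test_variance_partition_ranking_and_ties():
    rows = []
    for oid, vals in (("gA", [0.5, 0.5]), ("gB", [0.4, 0.6]),
                      ("gC", [0.3, 0.7])):
        rows += [{"ortholog_id": oid, "species": f"s{i}", "gc3": v}
                 for i, v in enumerate(vals)]
    tab = pd.DataFrame(rows)
    part = variance_partition(tab, 1)
    assert part.high == ["gC"] and part.low == ["gA"]
    with pytest.raises(ValueError):
        variance_partition(tab, 2)
    # ties broken lexicographically
    tied = tab.copy()
    tied["gc3"] = [0.4, 0.6] * 3
    p2 = variance_partition(tied, 1)
    assert p2.high == ["gA"] and p2.low == ["gC"]


def test_variance_partition_matches_sort_oracle(rng):
    rows = []
    var_by_gene = {}
    for g in range(40):
        vals = rng.normal(0.5, rng.uniform(0.01, 0.1), 6)
        var_by_gene[f"g{g:02d}"] = np.var(vals, ddof=1)
        rows += [{"ortholog_id": f"g{g:02d}", "species": f"s{i}",
                  "gc3": v} for i, v in enumerate(vals)]
    part = variance_partition(pd.DataFrame(rows), 10)
    ranked = sorted(var_by_gene, key=lambda k: (-var_by_gene[k], k))
    assert part.high == sorted(ranked[:10])
    assert part.low == sorted(ranked[-10:])


def test_homogeneity_identical_counts_homogenous():
    aln = OrthologAlignment("x", "coding",
                            {"a": "ATG" * 50, "b": "ATG" * 50})
    label, p, flags = classify_homogeneity(aln)
    assert label == "homogenous" and p == 1.0


def test_homogeneity_extreme_contrast_matches_chi2_oracle():
    # 90 GC vs 10 GC out of 100 third positions
    a = "ATG" * 90 + "ATA" * 10
    b = "ATG" * 10 + "ATA" * 90
    aln = OrthologAlignment("x", "coding", {"a": a, "b": b})
    label, p, _ = classify_homogeneity(aln, alpha=0.01)
    stat, p_oracle, _, _ = stats.chi2_contingency(
        [[90, 10], [10, 90]], correction=False)
    assert label == "non-homogenous"
    assert p == pytest.approx(p_oracle)


def test_homogeneity_false_rejection_rate_near_alpha(rng):
    """Stationary genes should be rejected at about the nominal rate."""
    alpha, reps, n_sp, n_sites = 0.05, 1000, 6, 120
    rejected = 0
    for _ in range(reps):
        gc = rng.binomial(n_sites, 0.5, n_sp)
        table = np.column_stack([gc, n_sites - gc])
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        rejected += p < alpha
    # same test statistic as classify_homogeneity; 3 binomial SE band
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rejected / reps - alpha) < 3 * se


def test_classifier_on_simulated_stationary_alignments(rng):
    """End-to-end: the classifier itself on stationary alignments."""
    alpha, reps = 0.05, 200
    rejections = 0
    for _ in range(reps):
        seqs = {}
        for s in range(4):
            third = rng.choice(list("GCAT"), size=60)
            seqs[f"s{s}"] = "".join("AT" + t for t in third)
        label, _, _ = classify_homogeneity(
            OrthologAlignment("x", "coding", seqs), alpha=alpha)
        rejections += label == "non-homogenous"
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rejections / reps - alpha) < 4 * se
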