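import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from avigc.io import read_tree, encode
from avigc.simulate import simulate_t92_alignment, _random_ultrametric_tree
from avigc.substitution import (BranchSubstitutionCounts, T92Model, gc3_star,
                                map_ws_substitutions, t92_rate_matrix,
                                t92_stationary, t92_transition_matrix)


def test_zero_length_is_identity():
    assert np.allclose(t92_transition_matrix(0.45, 4.0, 0.0), np.eye(4))


def test_long_branch_reaches_stationarity():
    P = t92_transition_matrix(0.3, 2.0, 150.0)
    pi = t92_stationary(0.3)
    assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-8)


def test_matches_matrix_exponential_oracle(rng):
    for _ in range(20):
        th = rng.uniform(0.05, 0.95)
        ka = rng.uniform(0.2, 10)
        t = rng.uniform(0, 4)
        P = t92_transition_matrix(th, ka, t)
        assert np.allclose(P, expm(t92_rate_matrix(th, ka) * t),
                           atol=1e-10)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-12)
        assert (P >= 0).all()


def test_detailed_balance(rng):
    for _ in range(5):
        th, ka = rng.uniform(0.1, 0.9), rng.uniform(0.5, 8)
        pi = t92_stationary(th)
        F = pi[:, None] * t92_transition_matrix(th, ka, 0.7)
        assert np.allclose(F, F.T, atol=1e-12)


def test_unit_mean_rate(rng):
    th, ka = 0.37, 3.0
    Q = t92_rate_matrix(th, ka)
    assert -float(t92_stationary(th) @ np.diag(Q)) == pytest.approx(1.0)


def test_invalid_parameters():
    with pytest.raises(ValueError):
        t92_transition_matrix(1.2, 2.0, 1.0)
    with pytest.raises(ValueError):
        t92_rate_matrix(0.5, -1.0)
    with pytest.raises(ValueError):
        t92_transition_matrix(0.5, 2.0, -0.1)


# -- fitting -------------------------------------------------------------

def test_fit_on_invariant_alignment_returns_observed_gc():
    tree = read_tree("(A:0.1,B:0.1);", "substitutions")
    codes = np.vstack([encode("GGCCAATT"), encode("GGCCAATT")])
    with pytest.warns(UserWarning, match="no variable sites"):
        fit = T92Model(codes, ["A", "B"], tree).fit()
    assert fit.theta == pytest.approx(0.5)
    assert "no_variable_sites" in fit.flags


def test_fit_recovers_simulation_parameters(rng):
    tree = _random_ultrametric_tree(12, 1.0, rng)
    for n in tree.postorder():
        if n.length is not None:
            n.length *= 0.3
    codes, taxa, _ = simulate_t92_alignment(tree, 0.45, 4.0, 20000, rng)
    fit = T92Model(codes, taxa, tree).fit()
    assert abs(fit.theta - 0.45) < 0.015
    assert abs(fit.kappa - 4.0) / 4.0 < 0.15
    # likelihood at truth beats perturbed parameters
    model = fit.model
    ll_true = model.loglike(0.45, 4.0)
    for th, ka in ((0.35, 4.0), (0.55, 4.0), (0.45, 2.0), (0.45, 8.0)):
        assert ll_true > model.loglike(th, ka)
    assert "log-likelihood" in fit.summary()


# -- mapping -------------------------------------------------------------

def test_identical_sequences_have_negligible_counts():
    tree = read_tree("(A:0.001,B:0.001);", "substitutions")
    codes = np.vstack([encode("ACGT" * 25)] * 2)
    counts = map_ws_substitutions(codes, ["A", "B"], tree, 0.5, 2.0)
    per_site = counts.table[["E_WS", "E_SW"]].values / counts.n_sites
    assert (per_site <= 1e-6).all()


def test_single_site_posterior_matches_direct_bayes():
    """Two taxa, one site A vs G: compare with the hand-computed joint
    posterior over root states from the 4x4 matrices."""
    theta, kappa, t = 0.5, 2.0, 0.05
    tree = read_tree("(A:0.05,B:0.05);", "substitutions")
    codes = np.array([[0], [2]])  # A vs G
    counts = map_ws_substitutions(codes, ["A", "B"], tree, theta, kappa)
    pi = t92_stationary(theta)
    P = t92_transition_matrix(theta, kappa, t)
    # joint over (root x, tipA a, tipB b) with a=A, b=G fixed
    denom = sum(pi[x] * P[x, 0] * P[x, 2] for x in range(4))
    expected_ws_A = sum(  # W->S on branch to B (endpoint G)
        pi[x] * P[x, 0] * P[x, 2] / denom
        for x in (0, 3))
    branch_b = counts.table.set_index("branch_id").loc["B"]
    assert branch_b["E_WS"] == pytest.approx(expected_ws_A, abs=1e-10)
    total = counts.table[["E_WS", "E_SW"]].values.sum()
    assert total == pytest.approx(1.0, abs=0.25)  # ~one substitution seen


def test_endpoint_and_labeled_agree_on_short_branches(rng):
    tree = _random_ultrametric_tree(6, 1.0, rng)
    for n in tree.postorder():
        if n.length is not None:
            n.length *= 0.05
    codes, taxa, _ = simulate_t92_alignment(tree, 0.45, 4.0, 5000, rng)
    fit = T92Model(codes, taxa, tree).fit()
    a = fit.map_substitutions("endpoint").table.set_index("branch_id")
    b = fit.map_substitutions("labeled").table.set_index("branch_id")
    for col in ("E_WS", "E_SW"):
        assert np.allclose(a[col], b[col], rtol=0.03, atol=0.05)


def test_total_substitutions_track_branch_lengths(rng):
    """Counts of all substitution classes sum to about length*sites."""
    tree = _random_ultrametric_tree(8, 1.0, rng)
    for n in tree.postorder():
        if n.length is not None:
            n.length *= 0.2
    n_sites = 20000
    codes, taxa, _ = simulate_t92_alignment(tree, 0.5, 4.0, n_sites, rng)
    fit = T92Model(codes, taxa, tree).fit()
    counts = fit.map_substitutions("labeled")
    tb = counts.table
    # W->S + S->W is the transversion-plus-some share; compare the summed
    # W<->S flux with its stationary expectation length*sites*flux
    pi = t92_stationary(fit.theta)
    Q = t92_rate_matrix(fit.theta, fit.kappa)
    flux_ws = sum(pi[i] * Q[i, j] for i in (0, 3) for j in (1, 2))
    flux_sw = sum(pi[i] * Q[i, j] for i in (1, 2) for j in (0, 3))
    expected = (tb["length"] * n_sites * (flux_ws + flux_sw)).sum()
    got = (tb["E_WS"] + tb["E_SW"]).sum()
    assert got == pytest.approx(expected, rel=0.10)


# -- GC3* ----------------------------------------------------------------

def _counts_frame(e_ws, e_sw, w_opp=1.0, s_opp=1.0):
    tb = pd.DataFrame([{
        "branch_id": "b", "node": 0, "parent": 1, "length": 1.0,
        "is_tip": True, "E_WS": e_ws, "E_SW": e_sw,
        "W_opp": w_opp, "S_opp": s_opp}])
    return BranchSubstitutionCounts(table=tb, tip_paths={"A": [0]},
                                    n_sites=100, mode="endpoint")


def test_raw_count_ratio_arithmetic():
    counts = _counts_frame(30.0, 10.0)
    assert gc3_star(counts, "whole_tree", normalized=False) == \
        pytest.approx(0.75)


def test_zero_counts_undefined():
    counts = _counts_frame(0.0, 0.0)
    assert np.isnan(gc3_star(counts, "whole_tree"))
    assert np.isnan(gc3_star(counts, "per_tip_root_path")["A"])


def test_normalized_ratio_uses_opportunity():
    # equal counts but weak sites twice as abundant -> GC* < 0.5
    counts = _counts_frame(10.0, 10.0, w_opp=200.0, s_opp=100.0)
    star = gc3_star(counts, "whole_tree")
    assert star == pytest.approx((10 / 200) / (10 / 200 + 10 / 100))
    assert star < 0.5


def test_scope_per_branch():
    counts = _counts_frame(30.0, 10.0)
    out = gc3_star(counts, "per_branch", normalized=False)
    assert out["gc3_star"].iloc[0] == pytest.approx(0.75)
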