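"""Synthetic generators, network inference, noise injectors and the
contingency-matrix evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from signedclust import (
    SignedGraph,
    add_multinomial_noise,
    evaluate,
    generate_biclusters,
    generate_glv,
    infer_network,
    permute_fraction,
    shift_weights,
)
from signedclust.clustering import ClusterAssignment
from signedclust.synthetic import _integrate_glv


# -- gLV generator ---------------------------------------------------------


def test_interaction_matrix_has_requested_connectivity():
    ds = generate_glv(n_species=100, connectivity=0.05, seed=1)
    a = ds.interaction_matrix
    off_diag = a[~np.eye(a.shape[0], dtype=bool)]
    count = np.count_nonzero(off_diag)
    # Binomial(9900, 0.05): mean 495, sd ~21.7; allow 5 sd
    assert abs(count - 495) < 5 * 21.7


def test_glv_dataset_is_reproducible_and_nonnegative():
    a = generate_glv(n_species=30, samples_per_condition=10, seed=7)
    b = generate_glv(n_species=30, samples_per_condition=10, seed=7)
    pd.testing.assert_frame_equal(a.abundances, b.abundances)
    assert a.truth == b.truth
    assert (a.abundances.values >= 0).all()
    assert set(a.truth) == set(a.abundances.index)


def test_noiseless_uncoupled_glv_reaches_logistic_fixed_point():
    # dx/dt = x(b - x) has the closed-form fixed point x* = b
    rng = np.random.default_rng(0)
    n = 10
    a = -np.eye(n)
    b = np.full(n, 3.0)
    x0 = rng.uniform(0.1, 1.1, size=(n, 8))
    final = _integrate_glv(a, b, x0, rng, noise_sd=0.0, steps=5000)
    np.testing.assert_allclose(final, 3.0, rtol=1e-3)
    # identical steady states mean constant rows: the inferred network
    # has no testable correlations at all
    g = infer_network(np.round(final, 12), alpha=0.05)
    assert g.n_edges == 0


def test_explosive_dynamics_reported():
    rng = np.random.default_rng(0)
    a = np.array([[1.0, 0.0], [0.0, 1.0]])  # positive self-interaction
    x0 = np.ones((2, 3))
    assert _integrate_glv(a, np.ones(2), x0, rng, noise_sd=0.0) is None


# -- bicluster generator ---------------------------------------------------


def test_biclusters_reproducible_with_disjoint_truth():
    a = generate_biclusters(n_features=40, n_samples=40, seed=3)
    b = generate_biclusters(n_features=40, n_samples=40, seed=3)
    pd.testing.assert_frame_equal(a.abundances, b.abundances)
    assert set(a.truth.values()) == {1, 2}  # default blocks tile all features
    assert (a.abundances.values >= 0).all()


def test_overlapping_blocks_rejected():
    with pytest.raises(ValueError, match="disjoint"):
        generate_biclusters(
            n_features=20, n_samples=20,
            positions=[(range(0, 10), range(0, 10)),
                       (range(5, 15), range(10, 20))],
        )


def test_anti_correlated_blocks_give_signed_structure():
    ds = generate_biclusters(n_features=50, n_samples=60, n_clusters=2,
                             signal=3.0, seed=11)
    g = infer_network(ds.abundances, alpha=0.01)
    within_pos = between_neg = within = between = 0
    for u, v, w in g.edges():
        tu, tv = ds.truth[u], ds.truth[v]
        if tu == tv and tu > 0:
            within += 1
            within_pos += w > 0
        elif tu > 0 and tv > 0 and tu != tv:
            between += 1
            between_neg += w < 0
    assert within and between
    assert within_pos / within > 0.9
    assert between_neg / between > 0.9


def test_zero_signal_blocks_leave_only_null_edges():
    ds = generate_biclusters(n_features=40, n_samples=40, signal=0.0, seed=5)
    g = infer_network(ds.abundances, alpha=0.05)
    n_pairs = 40 * 39 / 2
    assert g.n_edges < 0.12 * n_pairs  # only type-I-rate edges survive


# -- network inference -----------------------------------------------------


def test_duplicate_rows_yield_unit_edge():
    rng = np.random.default_rng(0)
    base = rng.normal(size=20)
    data = np.vstack([base, base, rng.normal(size=20)])
    g = infer_network(data, alpha=0.05)
    assert g.weight("f0", "f1") == pytest.approx(1.0)


def test_anticorrelated_pair_gets_negative_edge():
    rng = np.random.default_rng(1)
    base = rng.normal(size=30)
    g = infer_network(np.vstack([base, -base]), alpha=0.05)
    assert g.weight("f0", "f1") == pytest.approx(-1.0)


def test_null_data_edge_rate_matches_alpha():
    rng = np.random.default_rng(123)
    data = rng.normal(size=(40, 60))
    g = infer_network(data, alpha=0.05)
    n_pairs = 40 * 39 / 2
    rate = g.n_edges / n_pairs
    # Binomial(780, 0.05): mean 39, sd ~6.1; 4 sd band on the rate
    assert 0.05 - 4 * 6.1 / 780 < rate < 0.05 + 4 * 6.1 / 780


def test_constant_rows_excluded_with_warning(caplog):
    data = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0) * 2])
    with caplog.at_level("WARNING"):
        g = infer_network(data, alpha=0.05)
    assert "f0" not in g.nodes
    assert any("constant" in r.message for r in caplog.records)


def test_spearman_agrees_with_pearson_on_monotone_data():
    rng = np.random.default_rng(5)
    base = rng.normal(size=40)
    data = np.vstack([base, np.exp(base)])
    g = infer_network(data, method="spearman", alpha=0.05)
    assert g.weight("f0", "f1") == pytest.approx(1.0)


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        infer_network(np.ones((3, 2)))


# -- noise injectors -------------------------------------------------------


def test_permute_zero_fraction_is_identity():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 7))
    np.testing.assert_array_equal(permute_fraction(data, 0.0, seed=1), data)


def test_permute_full_fraction_preserves_multiset():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 7))
    out = permute_fraction(data, 1.0, seed=1)
    assert sorted(out.ravel()) == sorted(data.ravel())
    assert not np.array_equal(out, data)


def test_permute_half_touches_at_most_the_selected_cells():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(10, 10))
    out = permute_fraction(data, 0.5, seed=3)
    out2 = permute_fraction(data, 0.5, seed=3)
    np.testing.assert_array_equal(out, out2)  # reproducible
    changed = np.count_nonzero(out != data)
    assert 0 < changed <= 50
    assert sorted(out.ravel()) == sorted(data.ravel())


def test_permute_rows_mode_preserves_row_multisets():
    rng = np.random.default_rng(4)
    data = rng.normal(size=(5, 12))
    out = permute_fraction(data, 0.8, seed=1, mode="rows")
    for row_in, row_out in zip(data, out):
        assert sorted(row_in) == sorted(row_out)


def test_multinomial_noise_totals_and_zeros():
    data = np.array([[10.0, 0.0], [0.0, 5.0], [30.0, 15.0]])
    out = add_multinomial_noise(data, scale=1000, seed=0)
    np.testing.assert_array_equal(out.sum(axis=0), [40000, 20000])
    assert out[1, 0] == 0 and out[0, 1] == 0  # zero species stay zero


def test_multinomial_noise_recovers_proportions_at_large_scale():
    data = np.array([[1.0], [2.0], [7.0]])
    out = add_multinomial_noise(data, scale=1e6, seed=1)
    np.testing.assert_allclose(out[:, 0] / out[:, 0].sum(),
                               [0.1, 0.2, 0.7], atol=1e-3)


def test_shift_weights_affine_map():
    g = SignedGraph([("a", "b", -0.5), ("b", "c", 0.2), ("a", "c", 1.0)])
    out = shift_weights(g)
    assert out.weight("a", "b") == pytest.approx(0.25)
    assert out.weight("b", "c") == pytest.approx(0.6)
    assert out.weight("a", "c") == pytest.approx(1.0)


def test_shift_drops_weight_minus_one_with_warning(caplog):
    g = SignedGraph([("a", "b", -1.0), ("b", "c", 0.0001)])
    with caplog.at_level("WARNING"):
        out = shift_weights(g)
    assert not out.has_edge("a", "b")
    assert any("dropped" in r.message for r in caplog.records)


# -- evaluation ------------------------------------------------------------


def two_cluster_truth():
    return {f"n{i}": 0 for i in range(5)} | {f"n{i}": 1 for i in range(5, 10)}


def test_perfect_assignment_scores_one_everywhere():
    truth = two_cluster_truth()
    result = evaluate(dict(truth), truth)
    assert (result.Sn, result.PPV, result.Acc, result.Sep) == (1, 1, 1, 1)
    assert not result.pathological


def test_one_misassigned_node_matches_hand_computed_table():
    truth = two_cluster_truth()
    predicted = dict(truth)
    predicted["n4"] = 1  # contingency: [[4, 1], [0, 5]]
    result = evaluate(predicted, truth)
    assert result.Sn == pytest.approx(0.9)
    assert result.PPV == pytest.approx(0.9)
    assert result.Acc == pytest.approx(0.9)
    # sep_ij = t_ij^2/(row_i * col_j): 16/20, 1/30, 0, 25/30
    expected_sep = np.sqrt(
        np.mean([16 / 20 + 1 / 30, 25 / 30]) * np.mean([16 / 20, 1 / 30 + 25 / 30])
    )
    assert result.Sep == pytest.approx(expected_sep)


def test_weak_nodes_count_as_unassigned():
    truth = two_cluster_truth()
    predicted = ClusterAssignment(
        membership=dict(truth),
        weak={n: n == "n0" for n in truth},
        k=2, sparsity=1.0,
    )
    result = evaluate(predicted, truth)
    assert result.Sn == pytest.approx(0.9)  # n0 no longer covers cluster 0
    assert result.PPV == pytest.approx(1.0)


def test_single_giant_cluster_is_pathological():
    truth = {f"n{i}": i % 2 for i in range(10)}
    predicted = {f"n{i}": 0 for i in range(10)}
    result = evaluate(predicted, truth)
    assert result.pathological and "80%" in result.reason


def test_pathological_thresholds_are_strict():
    # exactly 80% in one cluster: not pathological
    truth = {f"n{i}": i % 2 for i in range(10)}
    predicted = {f"n{i}": (0 if i < 8 else 1) for i in range(10)}
    assert not evaluate(predicted, truth).pathological
    # exactly 50 clusters: not pathological; 51 is
    truth60 = {f"n{i}": i % 2 for i in range(60)}
    pred50 = {f"n{i}": min(i, 49) for i in range(60)}
    assert not evaluate(pred50, truth60).pathological
    pred51 = {f"n{i}": min(i, 50) for i in range(60)}
    result = evaluate(pred51, truth60)
    assert result.pathological and "50" in result.reason


@pytest.mark.parametrize("seed", range(10))
def test_metric_identities_on_random_assignments(seed):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(30)]
    truth = {n: int(rng.integers(0, 3)) for n in nodes}
    predicted = {n: int(rng.integers(0, 4)) for n in nodes}
    result = evaluate(predicted, truth)
    assert result.Acc == pytest.approx(np.sqrt(result.Sn * result.PPV))
    for value in (result.Sn, result.PPV, result.Acc):
        assert 0.0 <= value <= 1.0
    assert result.Sep <= min(result.Sn, result.PPV) + 1e-9


def test_empty_prediction_rejected():
    with pytest.raises(ValueError):
        evaluate({}, {"a": 0})


def test_full_benchmark_beats_random_partitions():
    """On seeded gLV datasets with two environmental clusters, the full
    pipeline separates the clusters (median Sep > 0.5) and its sparsity
    beats a random two-way split of the same graphs."""
    from signedclust import DiffusionParams, cluster_signed_network, sparsity_score

    seps, sparsities, random_sparsities = [], [], []
    rng = np.random.default_rng(99)
    for _ in range(10):
        s = int(rng.integers(0, 2**31 - 1))
        ds = generate_glv(seed=s)
        g = infer_network(ds.abundances, alpha=0.05)
        res = cluster_signed_network(g, DiffusionParams(seed=s))
        truth = {n: ds.truth[n] for n in g.nodes}
        seps.append(evaluate(res.assignment, truth).Sep)
        sparsities.append(res.assignment.sparsity)
        random_membership = {n: int(rng.integers(0, 2)) for n in g.nodes}
        random_sparsities.append(sparsity_score(g, random_membership))
    assert np.median(seps) > 0.5
    assert np.median(sparsities) > np.median(random_sparsities)
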