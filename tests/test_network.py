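import numpy as np
import pytest

from switchnet import (
    CartographyThresholds,
    build_correlation_network,
    classify_nodes,
    compute_cartography,
    kmeans_communities,
    permutation_r_threshold,
    switch_genes,
)
from switchnet.network import NetworkError, pearson_matrix
from tests.conftest import communities, small_network, toy_matrix


# ------------------------------------------------------------------ the network

def test_identical_profiles_make_unit_edge():
    x = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 1.0, 3.0, 2.0],
        ]
    )
    net = build_correlation_network(toy_matrix(x, 2, 2), 0.99)
    assert net.graph.has_edge("g0", "g1")
    assert net.graph["g0"]["g1"]["weight"] == pytest.approx(1.0)


def test_anticorrelation_kept_with_negative_weight():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    x = np.vstack([base, 2 * base.mean() - base, [4.0, 1.0, 3.0, 2.0]])
    net = build_correlation_network(toy_matrix(x, 2, 2), 0.99)
    assert net.graph["g0"]["g1"]["weight"] == pytest.approx(-1.0)


def test_isolated_node_dropped():
    # brute force on this fixture: r(g0,g1) = 1, both correlations to g2 ≈ 0.32
    x = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [1.0, -1.0, 2.0, 1.5],
        ]
    )
    r = np.corrcoef(x)
    assert abs(r[0, 2]) < 0.8 and abs(r[1, 2]) < 0.8
    net = build_correlation_network(toy_matrix(x, 2, 2), 0.8)
    assert sorted(net.nodes) == ["g0", "g1"]
    assert net.graph.number_of_edges() == 1


def test_zero_variance_gene_excluded():
    x = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )
    net = build_correlation_network(toy_matrix(x, 2, 2), 0.5)
    assert "g2" not in net.nodes


def test_no_edges_errors():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 6))
    with pytest.raises(NetworkError, match="lower"):
        build_correlation_network(toy_matrix(x, 3, 3), 0.9999999)


def test_invalid_threshold_rejected():
    x = np.random.default_rng(0).normal(size=(4, 4))
    for bad in (0.0, 1.0, -0.5):
        with pytest.raises(NetworkError):
            build_correlation_network(toy_matrix(x, 2, 2), bad)


def test_pearson_matches_bruteforce_loop():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(12, 9))
    m = toy_matrix(x, 5, 4)
    r = pearson_matrix(m).to_numpy()
    for i in range(12):
        for j in range(12):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert r[i, j] == pytest.approx(expected, abs=1e-12)


def test_permutation_threshold_deterministic_and_sane(default_dataset):
    m, _ = default_dataset
    t1 = permutation_r_threshold(m, seed=42)
    t2 = permutation_r_threshold(m, seed=42)
    assert t1 == t2
    assert 0.2 < t1 < 0.9  # null |r| tail for 40 samples


# ------------------------------------------------------------------- clustering

def _clouds(k, per, seed=0, n_samples=8):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(k, n_samples)) * 50
    x = np.vstack(
        [centers[i] + rng.normal(scale=0.1, size=(per, n_samples)) for i in range(k)]
    )
    return toy_matrix(x, n_samples // 2, n_samples - n_samples // 2)


def test_kmeans_separates_well_separated_clouds():
    # clouds large enough that splitting one further cannot buy a big SSE drop
    per = 60
    m = _clouds(3, per, n_samples=16)
    net = build_correlation_network(m, 0.5)
    comm = kmeans_communities(m, net, k_range=range(2, 7), n_replicates=10, seed=1)
    assert comm.k == 3
    labels = [comm.labels[f"g{i}"] for i in range(3 * per)]
    for block in range(3):
        assert len(set(labels[block * per : (block + 1) * per])) == 1
    assert len(set(labels)) == 3


def test_sse_zero_at_number_of_distinct_profiles():
    rng = np.random.default_rng(2)
    distinct = rng.normal(size=(3, 6)) * 10
    x = np.repeat(distinct, 4, axis=0)  # 12 genes, 3 distinct profiles
    m = toy_matrix(x, 3, 3)
    net = build_correlation_network(m, 0.5)
    comm = kmeans_communities(m, net, k_range=[2, 3], n_replicates=10, seed=0)
    sse_at_3 = dict(comm.scree)[3]
    assert sse_at_3 == pytest.approx(0.0, abs=1e-20)


def test_scree_nonincreasing_over_random_fixtures():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 10)) + rng.normal(size=(15, 1)) * 2
        m = toy_matrix(x, 5, 5)
        net = build_correlation_network(m, 0.1)
        comm = kmeans_communities(m, net, k_range=range(2, 8), n_replicates=20, seed=seed)
        sses = [s for _, s in comm.scree]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))


def test_bad_k_range_errors():
    m = _clouds(2, 4)
    net = build_correlation_network(m, 0.5)
    with pytest.raises(NetworkError, match="k_range"):
        kmeans_communities(m, net, k_range=[])
    with pytest.raises(NetworkError, match="k_range"):
        kmeans_communities(m, net, k_range=range(2, 100))


# ------------------------------------------------------------------ cartography

def _two_community_net():
    # community 1: a,b,c with within-degrees (2,1,1); community 2: d,e
    edges = [
        ("a", "b", 0.9), ("a", "c", 0.9), ("d", "e", 0.8),
        ("b", "d", -0.4),
    ]
    return small_network(edges), communities({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2})


def test_zg_hand_computation_population_sd():
    net, comm = _two_community_net()
    cart = compute_cartography(net, comm)
    assert cart.loc["a", "zg"] == pytest.approx(np.sqrt(2), abs=1e-12)
    assert cart.loc["b", "zg"] == pytest.approx(-np.sqrt(2) / 2, abs=1e-12)
    assert cart.loc["c", "zg"] == pytest.approx(-np.sqrt(2) / 2, abs=1e-12)


def test_kpi_limits_and_hand_value():
    net, comm = _two_community_net()
    cart = compute_cartography(net, comm)
    assert cart.loc["a", "kpi"] == 0.0  # all links internal
    assert cart.loc["b", "kpi"] == pytest.approx(0.75, abs=1e-12)  # 1 of 2 internal
    ext_net = small_network([("x", "y", 0.9)])
    ext = compute_cartography(ext_net, communities({"x": 1, "y": 2}))
    assert ext.loc["x", "kpi"] == 1.0  # all links external


def test_apcc_is_mean_of_neighbor_correlations():
    net = small_network([("n", "p", 1.0), ("n", "q", -1.0), ("s", "t", -0.4)])
    cart = compute_cartography(
        net, communities({"n": 1, "p": 1, "q": 1, "s": 2, "t": 2})
    )
    assert cart.loc["n", "apcc"] == pytest.approx(0.0, abs=1e-12)
    assert cart.loc["s", "apcc"] == pytest.approx(-0.4, abs=1e-12)


def test_zg_standardized_within_community(default_run):
    result, _ = default_run
    cart = result.cartography
    for c, grp in cart.groupby("community"):
        kappa_sd_nonzero = grp["zg"].abs().sum() > 0
        if kappa_sd_nonzero and len(grp) > 1:
            assert grp["zg"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["zg"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    assert cart["kpi"].between(0, 1).all()
    assert cart["apcc"].between(-1, 1).all()


# --------------------------------------------------------------- classification

def _cart_row(zg, kpi, apcc):
    import pandas as pd

    cart = pd.DataFrame(
        {"community": [1], "zg": [zg], "kpi": [kpi], "apcc": [apcc]}, index=["node"]
    )
    return classify_nodes(cart).iloc[0]


def test_switch_criteria_met():
    row = _cart_row(2.4, 0.85, -0.1)
    assert row["is_switch"] and row["region"] == "R4" and row["hub_class"] == "fight-club"


def test_positive_apcc_is_not_switch():
    row = _cart_row(2.4, 0.85, +0.1)
    assert not row["is_switch"]


def test_local_hub_is_not_switch():
    row = _cart_row(6.0, 0.9, -0.2)
    assert row["hub_class"] == "fight-club" and row["is_hub"] and not row["is_switch"]


def test_hub_taxonomy_by_apcc():
    assert _cart_row(1.0, 0.5, 0.6)["hub_class"] == "party"
    assert _cart_row(1.0, 0.5, 0.2)["hub_class"] == "date"
    assert _cart_row(1.0, 0.5, -0.2)["hub_class"] == "fight-club"


def test_switch_set_invariant_to_order_and_relabeling():
    net, comm = _two_community_net()
    cart = classify_nodes(compute_cartography(net, comm))
    # reversed node insertion order
    edges = [
        ("b", "d", -0.4), ("d", "e", 0.8), ("a", "c", 0.9), ("a", "b", 0.9),
    ]
    net2 = small_network(edges)
    # community indices relabeled 1<->2
    comm2 = communities({"a": 2, "b": 2, "c": 2, "d": 1, "e": 1})
    cart2 = classify_nodes(compute_cartography(net2, comm2))
    assert switch_genes(cart) == switch_genes(cart2)
    assert np.allclose(cart[["zg", "kpi", "apcc"]], cart2[["zg", "kpi", "apcc"]])
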