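"""Co-expression network: adjacency, TOM, modules, eigengenes, hubs.

TOM and eigengenes are checked against brute-force oracles (triple loop,
full singular decomposition); module/hub recovery is checked against the
planted truth of the default synthetic atlas.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueatlas import (
    adjacency,
    build_network,
    detect_modules,
    eigengene_network,
    gene_module_statistics,
    hub_genes,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)
from tissueatlas.network import GREY, tissue_indicator_traits


def _random_adjacency(rng, n=30):
    r = rng.uniform(0, 1, size=(n, n))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    labels = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=labels, columns=labels)


def _random_log_expr(rng, n_genes=60, n_samples=11):
    X = rng.normal(3, 1, size=(n_genes, n_samples))
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"t{i}" for i in range(n_samples)],
    )


# --- soft threshold ----------------------------------------------------------


def test_mean_connectivity_strictly_decreasing_in_beta(rng):
    df = _random_log_expr(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pick_soft_threshold(df, powers=range(1, 21))
    mean_k = report.table["mean_k"].to_numpy()
    assert (np.diff(mean_k) < 0).all()


def test_soft_threshold_on_modular_atlas(network_input):
    log_expr, _ = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pick_soft_threshold(log_expr)
    assert report.chosen_beta >= 1
    assert report.fit_at_chosen >= 0.8


def test_degenerate_duplicated_profiles_all_ones(rng):
    profile = rng.normal(size=8)
    X = np.tile(profile, (25, 1)) + 0.0
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(25)],
                      columns=[f"t{i}" for i in range(8)])
    adj = adjacency(df, 6)
    np.testing.assert_allclose(adj.to_numpy(), 1.0, atol=1e-10)


# --- adjacency ----------------------------------------------------------------


def test_adjacency_power_arithmetic(rng):
    # two genes engineered to correlate exactly 0.5 on raw values
    base = rng.normal(size=11)
    base = (base - base.mean()) / base.std()
    other = rng.normal(size=11)
    other -= other.mean()
    other -= base * (base @ other) / (base @ base)  # orthogonal to base
    other /= other.std()
    y = 0.5 * base + np.sqrt(1 - 0.25) * other
    df = pd.DataFrame([base, y, rng.normal(size=11)],
                      index=["a", "b", "c"], columns=[f"t{i}" for i in range(11)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj = adjacency(df, 2)
    assert adj.loc["a", "b"] == pytest.approx(0.25, abs=1e-10)
    assert adj.loc["a", "a"] == 1.0


def test_adjacency_symmetric_in_unit_interval_matches_loop(rng):
    df = _random_log_expr(rng, n_genes=30)
    adj = adjacency(df, 6)
    A = adj.to_numpy()
    assert ((A >= 0) & (A <= 1)).all()
    np.testing.assert_allclose(A, A.T, atol=1e-12)
    X = df.to_numpy()
    for i in range(0, 30, 7):
        for j in range(0, 30, 5):
            if i == j:
                continue
            r = np.corrcoef(X[i], X[j])[0, 1]
            assert A[i, j] == pytest.approx(abs(r) ** 6, abs=1e-12)


# --- TOM -----------------------------------------------------------------------


def test_tom_fully_connected_is_one():
    a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
    np.testing.assert_allclose(tom_similarity(a).to_numpy(), 1.0)


def test_tom_disconnected_off_diagonal_zero():
    a = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
    tom = tom_similarity(a).to_numpy()
    assert tom[~np.eye(4, dtype=bool)].max() == 0.0
    np.testing.assert_allclose(np.diag(tom), 1.0)


def test_tom_matches_triple_loop_oracle(rng):
    a = _random_adjacency(rng, n=30)
    tom = tom_similarity(a).to_numpy()
    A = a.to_numpy()
    n = len(A)
    k = A.sum(axis=1) - 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            L = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            expected = (L + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
            assert tom[i, j] == pytest.approx(expected, abs=1e-12)


def test_tom_rejects_asymmetric_input():
    a = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        tom_similarity(a)


# --- module detection ------------------------------------------------------------


def _planted_blocks(rng, sizes=(60, 50, 40), n_bg=40, n_samples=12):
    # orthonormal latents: the stated condition is across-block r ~ 0
    Q, _ = np.linalg.qr(rng.normal(size=(n_samples, len(sizes))))
    latents = Q.T * np.sqrt(n_samples)
    rows, names, truth = [], [], []
    for b, size in enumerate(sizes):
        latent = latents[b]
        for i in range(size):
            rows.append(latent + rng.normal(0, 0.35, size=n_samples))
            names.append(f"b{b}_{i}")
            truth.append(b)
    for i in range(n_bg):
        rows.append(rng.normal(size=n_samples))
        names.append(f"bg{i}")
        truth.append(-1)
    df = pd.DataFrame(rows, index=names, columns=[f"s{i}" for i in range(n_samples)])
    return df, np.array(truth)


def test_detect_modules_recovers_planted_blocks(rng):
    from sklearn.metrics import adjusted_rand_score

    df, truth = _planted_blocks(rng)
    adj = adjacency(df, 6)
    tom = tom_similarity(adj)
    labels, _ = detect_modules(tom)
    block = truth >= 0
    ari = adjusted_rand_score(truth[block], labels.to_numpy()[block])
    assert ari >= 0.9
    assert labels.value_counts().sum() == len(df)  # conservation incl. grey


def test_detect_modules_uncorrelated_pool_all_grey(rng):
    df = _random_log_expr(rng, n_genes=80)
    adj = adjacency(df, 10)
    tom = tom_similarity(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels, _ = detect_modules(tom, min_module_size=30)
    assert (labels == GREY).mean() > 0.9


def test_module_size_conservation_on_atlas(network_input):
    log_expr, _ = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(log_expr)
    assert int(net.module_sizes.sum()) == len(log_expr)


# --- eigengenes -------------------------------------------------------------------


def test_eigengene_of_identical_profiles_is_shared_pattern(rng):
    profile = rng.normal(size=9)
    X = np.tile(profile, (20, 1))
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                      columns=[f"s{i}" for i in range(9)])
    labels = pd.Series(["blue"] * 20, index=df.index)
    eig, flags = module_eigengenes(df, labels)
    me = eig.loc["blue"].to_numpy()
    z = (profile - profile.mean()) / profile.std()
    r = np.corrcoef(me, z)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)
    assert np.linalg.norm(me) == pytest.approx(1.0)


def test_eigengene_matches_svd_oracle_up_to_sign(rng):
    df = _random_log_expr(rng, n_genes=40)
    labels = pd.Series(["blue"] * 25 + [GREY] * 15, index=df.index)
    eig, _ = module_eigengenes(df, labels)
    block = df.iloc[:25].to_numpy()
    z = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    dot = abs(float(eig.loc["blue"].to_numpy() @ vt[0]))
    assert dot >= 1 - 1e-10


def test_eigengenes_recover_planted_latents(network_input):
    log_expr, truth = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(log_expr)
    module_genes = {m: genes for m, genes in truth.module_map.items()}
    for planted, genes in module_genes.items():
        recovered = net.labels.loc[genes].value_counts().index[0]
        me = net.eigengenes.loc[recovered].to_numpy()
        r = np.corrcoef(me, truth.module_latents[planted])[0, 1]
        assert abs(r) >= 0.9


# --- module-trait statistics --------------------------------------------------------


def test_module_trait_correlation_extremes_and_t_oracle():
    samples = [f"s{i}" for i in range(11)]
    traits = tissue_indicator_traits([f"tis{i}" for i in range(11)])
    traits.index = samples
    indicator = traits.iloc[:, 0].to_numpy(dtype=float)
    eig = pd.DataFrame([indicator], index=["blue"], columns=samples)
    r, p = module_trait_correlation(eig, traits)
    assert r.iloc[0, 0] == pytest.approx(1.0)
    assert p.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_module_trait_p_matches_t_distribution():
    # engineered eigengene with known r against a quantitative trait
    rng = np.random.default_rng(1)
    n = 11
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    noise = rng.normal(size=n)
    noise -= noise.mean()
    noise -= x * (x @ noise) / (x @ x)
    y = 0.6 * x + np.sqrt(1 - 0.36) * (noise / noise.std())
    eig = pd.DataFrame([y], index=["m"], columns=[f"s{i}" for i in range(n)])
    traits = pd.DataFrame({"trait": x}, index=[f"s{i}" for i in range(n)])
    r, p = module_trait_correlation(eig, traits)
    assert r.iloc[0, 0] == pytest.approx(0.6, abs=1e-9)
    t = 0.6 * np.sqrt((n - 2) / (1 - 0.36))
    assert p.iloc[0, 0] == pytest.approx(2 * stats.t.sf(t, df=n - 2), abs=1e-9)
    assert p.iloc[0, 0] == pytest.approx(0.051, abs=0.002)


def test_gene_module_statistics_kme_bounds_and_self(network_input):
    log_expr, _ = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(log_expr)
        traits = tissue_indicator_traits(log_expr.columns)
        traits.index = log_expr.columns
        out = gene_module_statistics(log_expr, net.eigengenes, net.labels, traits)
    kme = out["kme"].to_numpy()
    assert (np.abs(kme) <= 1 + 1e-9).all()
    assert not out["gs_mm"].empty


def test_planted_hubs_have_higher_kme(network_input):
    log_expr, truth = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(log_expr)
        traits = tissue_indicator_traits(log_expr.columns)
        traits.index = log_expr.columns
        out = gene_module_statistics(log_expr, net.eigengenes, net.labels, traits)
    for planted, genes in truth.module_map.items():
        recovered = net.labels.loc[genes].value_counts().index[0]
        hubs = truth.hub_ids[planted]
        non_hubs = [g for g in genes if g not in hubs]
        hub_kme = out["kme"].loc[hubs, recovered].abs().mean()
        other_kme = out["kme"].loc[non_hubs, recovered].abs().mean()
        assert hub_kme > other_kme


# --- hubs ----------------------------------------------------------------------------


@pytest.mark.parametrize("size,expected", [(171, 8), (10, 1), (40, 2), (19, 1)])
def test_hub_count_rule(rng, size, expected):
    a = _random_adjacency(rng, n=size)
    labels = pd.Series(["brown"] * size, index=a.index)
    hub = hub_genes(a, labels, fraction=0.05)
    assert len(hub.hubs["brown"]) == expected


def test_hub_selection_orders_by_intramodular_connectivity(rng):
    a = _random_adjacency(rng, n=40)
    labels = pd.Series(["blue"] * 40, index=a.index)
    hub = hub_genes(a, labels, fraction=0.1)
    A = a.to_numpy()
    kim = A.sum(axis=1) - 1.0
    expected = [a.index[i] for i in np.argsort(-kim, kind="stable")[:4]]
    assert hub.hubs["blue"] == expected


def test_hub_recovery_on_atlas(network_input):
    log_expr, truth = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(log_expr)
    hub = hub_genes(net.adjacency, net.labels, fraction=0.05)
    assert GREY not in hub.hubs
    for planted, genes in truth.module_map.items():
        recovered = net.labels.loc[genes].value_counts().index[0]
        selected = set(hub.hubs[recovered])
        planted_hubs = set(truth.hub_ids[planted])
        assert len(selected & planted_hubs) / len(planted_hubs) >= 0.5


# --- eigengene network ---------------------------------------------------------------


def test_eigengene_network_symmetric_unit_diagonal(network_input):
    log_expr, _ = network_input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(log_expr)
    enet = eigengene_network(net.eigengenes)
    E = enet.to_numpy()
    np.testing.assert_allclose(E, E.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(E), 1.0)
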