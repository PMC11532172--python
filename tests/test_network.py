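"""Adjacency, soft-threshold selection, TOM, and mutual rank."""

import numpy as np
import pandas as pd
import pytest

from nrbgrn.network import (WeightedNetwork, mutual_rank, pearson_adjacency,
                            pick_soft_threshold, tom)

from oracles import mutual_rank_brute_force, tom_brute_force


def _random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def _net(a, genes=None):
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    return WeightedNetwork(genes, a, "adjacency", 1.0, np.ones_like(a, dtype=np.int8))


# -- adjacency -----------------------------------------------------------------


def test_adjacency_matches_pairwise_loop_oracle(rng):
    x = pd.DataFrame(rng.normal(size=(10, 6)), index=[f"g{i}" for i in range(10)])
    beta = 3.0
    net = pearson_adjacency(x, beta)
    for i in range(10):
        for j in range(10):
            if i == j:
                assert net.weights[i, j] == 0.0
                continue
            r = np.corrcoef(x.iloc[i], x.iloc[j])[0, 1]
            assert net.weights[i, j] == pytest.approx(abs(r) ** beta, abs=1e-12)
            assert net.corr_sign[i, j] == np.sign(r)


def test_perfect_anticorrelation_is_weight_one_sign_minus():
    x = pd.DataFrame([[1.0, 2, 3, 4], [-1.0, -2, -3, -4]], index=["gA", "gB"])
    x = pd.concat([x, pd.DataFrame([[0.3, 1.1, 0.2, 2.0]], index=["gC"])])
    net = pearson_adjacency(x, 6.0)
    assert net.weights[0, 1] == pytest.approx(1.0)
    assert net.corr_sign[0, 1] == -1


def test_zero_variance_gene_rejected_by_name():
    x = pd.DataFrame([[1.0, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "ok"])
    with pytest.raises(ValueError, match="flat"):
        pearson_adjacency(x, 2.0)


# -- soft threshold ------------------------------------------------------------


def test_single_candidate_power_is_returned(rng):
    x = pd.DataFrame(rng.normal(size=(50, 12)))
    assert pick_soft_threshold(x, powers=[7]) == 7.0


def test_mean_connectivity_decreases_with_power(rng):
    x = pd.DataFrame(rng.normal(size=(60, 12)))
    _, table = pick_soft_threshold(x, powers=[1, 2, 4, 8], return_table=True)
    assert (np.diff(table["mean_k"]) < 0).all()


def test_modular_data_reaches_near_target_r2():
    """On strongly modular expression (low-rank latent factors with a broad
    loading gradient) the selected power fits scale-free topology with
    signed R² within 0.15 of the 0.9 target."""
    from scipy.interpolate import CubicSpline

    rng = np.random.default_rng(0)
    n, n_stages, n_reps, d = 2000, 15, 3, 6
    knots = np.linspace(0, 1, 5)
    factors = np.array([CubicSpline(knots, rng.normal(size=5))(
        np.linspace(0, 1, n_stages)) for _ in range(d)])
    factors = (factors - factors.mean(1, keepdims=True)) / factors.std(1, keepdims=True)
    directions = rng.normal(size=(n, d))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    r = 0.95 * rng.beta(1.2, 2.5, n)
    lam = 0.3 * r / np.sqrt(1 - r**2)
    stage_of = np.repeat(np.arange(n_stages), n_reps)
    x = rng.normal(0, 0.3, size=(n, n_stages * n_reps)) + \
        (lam[:, None] * (directions @ factors))[:, stage_of]
    beta, table = pick_soft_threshold(pd.DataFrame(x), return_table=True)
    r2 = float(table.loc[table["power"] == beta, "signed_r2"].iloc[0])
    assert abs(r2 - 0.9) <= 0.15


# -- topological overlap --------------------------------------------------------


def test_tom_complete_triangle_is_all_ones():
    a = np.ones((3, 3)) - np.eye(3)
    omega = tom(_net(a)).weights
    assert np.allclose(omega, 1.0)


def test_tom_single_edge_hand_value():
    # a_12 = 0.5, others 0: ω_12 = 0.5 / (0.5 + 1 − 0.5) = 0.5
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 0.5
    omega = tom(_net(a)).weights
    assert omega[0, 1] == pytest.approx(0.5, abs=1e-12)
    assert omega[0, 2] == 0.0


def test_tom_matches_triple_loop_oracle(rng):
    a = _random_adjacency(rng, 20)
    omega = tom(_net(a)).weights
    assert np.max(np.abs(omega - tom_brute_force(a))) < 1e-10


def test_tom_requires_symmetric_adjacency(rng):
    a = _random_adjacency(rng, 5)
    a[0, 1] += 0.2
    with pytest.raises(ValueError, match="symmetric"):
        _net(a)


def test_tom_stays_in_unit_interval(rng):
    for _ in range(5):
        a = _random_adjacency(rng, 15)
        omega = tom(_net(a)).weights
        off = omega[~np.eye(15, dtype=bool)]
        assert off.min() >= 0.0 and off.max() <= 1.0


# -- mutual rank ----------------------------------------------------------------


def test_mutual_top_partners_score_one():
    a = np.array([[0.0, 0.9, 0.1, 0.2],
                  [0.9, 0.0, 0.2, 0.1],
                  [0.1, 0.2, 0.0, 0.3],
                  [0.2, 0.1, 0.3, 0.0]])
    mr = mutual_rank(_net(a))
    assert mr.iloc[0, 1] == pytest.approx(1.0)


def test_mutual_weakest_partners_score_one_over_n():
    # g0 and g1 are each other's weakest of N = 3 partners
    a = np.array([[0.0, 0.05, 0.5, 0.6],
                  [0.05, 0.0, 0.7, 0.8],
                  [0.5, 0.7, 0.0, 0.4],
                  [0.6, 0.8, 0.4, 0.0]])
    mr = mutual_rank(_net(a))
    assert mr.iloc[0, 1] == pytest.approx(1.0 / 3.0)


def test_mutual_rank_matches_brute_force_including_ties(rng):
    for _ in range(5):
        a = np.round(_random_adjacency(rng, 8), 1)  # rounding forces ties
        mr = mutual_rank(_net(a)).to_numpy()
        assert np.allclose(mr, mutual_rank_brute_force(a), atol=1e-12)


def test_mutual_rank_invariant_under_monotone_transform(rng):
    a = _random_adjacency(rng, 9)
    mr_raw = mutual_rank(_net(a))
    mr_sq = mutual_rank(_net(a**2))               # strictly monotone on [0,1]
    assert np.allclose(mr_raw.to_numpy(), mr_sq.to_numpy(), atol=1e-12)


def test_raw_convention_is_the_low_is_good_geometric_mean(rng):
    a = _random_adjacency(rng, 6)
    raw = mutual_rank(_net(a), convention="raw").to_numpy()
    # independent reconstruction: 1-based descending ranks per row
    n = 6
    ranks = np.zeros((n, n))
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        order = sorted(partners, key=lambda j: -a[i, j])
        for pos, j in enumerate(order, start=1):
            ranks[i, j] = pos
    expected = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(expected, 0.0)
    assert np.allclose(raw, expected, atol=1e-12)
    with pytest.raises(ValueError, match="convention"):
        mutual_rank(_net(a), convention="banana")


def test_mutual_rank_subset_too_small(rng):
    a = _random_adjacency(rng, 4)
    with pytest.raises(ValueError, match="≥2"):
        mutual_rank(_net(a), ["g0"])


def test_within_module_tom_exceeds_between(study1, tpm1):
    """Planted regulons are visible as elevated topological overlap."""
    from nrbgrn.quantify import expression_floor

    floored = tpm1.subset_genes(expression_floor(tpm1, 5.0))
    nrb = floored.samples_where(tissue_class="NRB")
    logx = np.log2(floored.values[nrb] + 1.0)
    beta = pick_soft_threshold(logx)
    tnet = tom(pearson_adjacency(logx, beta))
    idx = {g: i for i, g in enumerate(tnet.genes)}
    module_of = study1.ledger.module_of
    genes = list(module_of)
    within, between = [], []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            w = tnet.weights[idx[ga], idx[gb]]
            (within if module_of[ga] == module_of[gb] else between).append(w)
    assert np.median(within) > np.median(between)
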