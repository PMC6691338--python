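"""Diffusion engine: hand-checked toys, a dense transition-matrix oracle,
conservation, and structural invariants."""

import numpy as np
import pytest

from netpharm.catalog_io import DTICatalog, DTIRecord
from netpharm.errors import CapabilityError, ConfigurationError, ParameterError
from netpharm.netinfer import (
    DiffusionParams,
    build_network,
    diffuse,
    predict_targets,
    rank_targets,
)
from netpharm.substructures import SubstructureMatrix
from netpharm.synthgen import SynthConfig, gen_world


def dense_oracle(network, query_drug, params):
    """Independent reference: build the phase-A and phase-B stochastic
    matrices node by node and take their k-th power.

    Node order: drugs, then substructures, then targets.  Deliberately
    naive (python loops over explicit neighbour lists) so it shares no code
    path with the vectorized implementation.
    """
    drugs = list(network.drug_ids)
    subs = list(network.substructure_ids)
    targets = list(network.target_ids)
    n_d, n_s, n_t = len(drugs), len(subs), len(targets)
    n = n_d + n_s + n_t

    def neighbours_of_drug(i):
        out = []
        for j in range(n_s):
            if network.b_ds[i, j] > 0:
                out.append(("s", j))
        for j in range(n_t):
            if network.b_dt[i, j] > 0:
                out.append(("t", j))
        return out

    def degree(kind, j):
        if kind == "s":
            return sum(network.b_ds[i, j] > 0 for i in range(n_d))
        return sum(network.b_dt[i, j] > 0 for i in range(n_d))

    # phase A: substructure/target nodes split equally over drug neighbours;
    # drug nodes keep their resource
    m_a = np.zeros((n, n))
    for i in range(n_d):
        m_a[i, i] = 1.0
    for j in range(n_s):
        holders = [i for i in range(n_d) if network.b_ds[i, j] > 0]
        for i in holders:
            m_a[n_d + j, i] = 1.0 / len(holders)
    for j in range(n_t):
        holders = [i for i in range(n_d) if network.b_dt[i, j] > 0]
        for i in holders:
            m_a[n_d + n_s + j, i] = 1.0 / len(holders)

    # phase B: drugs redistribute with weight (edge type) * deg(receiver)^gamma,
    # renormalized per drug; non-drug nodes keep their resource
    m_b = np.zeros((n, n))
    for j in range(n_s):
        m_b[n_d + j, n_d + j] = 1.0
    for j in range(n_t):
        m_b[n_d + n_s + j, n_d + n_s + j] = 1.0
    for i in range(n_d):
        nbrs = neighbours_of_drug(i)
        if not nbrs:
            continue
        raw = []
        for kind, j in nbrs:
            w = params.beta if kind == "s" else 1.0 - params.beta
            raw.append(w * degree(kind, j) ** params.gamma)
        z = sum(raw)
        if z <= 0:  # degenerate weighting: uniform split
            raw = [1.0] * len(nbrs)
            z = float(len(nbrs))
        for (kind, j), w in zip(nbrs, raw):
            col = n_d + j if kind == "s" else n_d + n_s + j
            m_b[i, col] = w / z

    qi = drugs.index(query_drug)
    f0 = np.zeros(n)
    t_edges = [j for j in range(n_t) if network.b_dt[qi, j] > 0]
    s_edges = [j for j in range(n_s) if network.b_ds[qi, j] > 0]
    if not t_edges and not s_edges:
        raise ValueError("query without edges")
    if not t_edges:
        for j in s_edges:
            f0[n_d + j] = 1.0 / len(s_edges)
    elif not s_edges:
        for j in t_edges:
            f0[n_d + n_s + j] = 1.0 / len(t_edges)
    else:
        for j in t_edges:
            f0[n_d + n_s + j] = (1.0 - params.alpha) / len(t_edges)
        for j in s_edges:
            f0[n_d + j] = params.alpha / len(s_edges)

    f = f0
    for _ in range(params.k):
        f = f @ m_a
        f = f @ m_b
    return f[:n_d], f[n_d:n_d + n_s], f[n_d + n_s:]


def random_network(rng, max_nodes=30):
    """Small random tripartite network with every layer non-empty."""
    n_d = int(rng.integers(2, 8))
    n_s = int(rng.integers(1, 10))
    n_t = int(rng.integers(1, max(2, max_nodes - n_d - n_s)))
    b_ds = (rng.random((n_d, n_s)) < 0.5).astype(float)
    b_dt = (rng.random((n_d, n_t)) < 0.4).astype(float)
    for i in range(n_d):  # every drug gets at least one substructure
        if b_ds[i].sum() == 0:
            b_ds[i, rng.integers(n_s)] = 1
    # every target needs a drug; drop empty target columns
    keep = b_dt.sum(axis=0) > 0
    if not keep.any():
        b_dt[rng.integers(n_d), 0] = 1
        keep = b_dt.sum(axis=0) > 0
    b_dt = b_dt[:, keep]
    drugs = tuple(f"d{i}" for i in range(n_d))
    matrix = SubstructureMatrix(drugs, tuple(f"s{j}" for j in range(n_s)), b_ds)
    catalog = DTICatalog(
        tuple(
            DTIRecord(drugs[i], f"T{j}")
            for i in range(n_d)
            for j in range(b_dt.shape[1])
            if b_dt[i, j] > 0
        )
    )
    return build_network(catalog, matrix)


def random_params(rng):
    return DiffusionParams(
        alpha=float(rng.uniform(0, 1)),
        beta=float(rng.uniform(0.05, 0.95)),
        gamma=float(rng.uniform(-1.0, 0.5)),
        k=int(rng.integers(1, 4)),
    )


class TestToyT1:
    def test_hand_propagation_k1(self, toy_t1):
        _, _, net = toy_t1
        f = diffuse(net, "d1", DiffusionParams(alpha=0.1, beta=0.1, gamma=0.0, k=1))
        assert f.targets[0] == pytest.approx(0.45, abs=1e-14)
        assert f.substructures[0] == pytest.approx(0.55, abs=1e-14)

    def test_hand_propagation_k2(self, toy_t1):
        _, _, net = toy_t1
        f = diffuse(net, "d1", DiffusionParams(alpha=0.1, beta=0.1, gamma=0.0, k=2))
        assert f.targets[0] == pytest.approx(0.6525, abs=1e-14)

    def test_ranked_list_from_diffusion(self, toy_t1):
        catalog, matrix, net = toy_t1
        f = diffuse(net, "d1", DiffusionParams(alpha=0.1, beta=0.1, gamma=0.0, k=1))
        ranked = rank_targets(f, net, "d1", L=20)
        assert ranked.entries == (("T1", pytest.approx(0.45)),)

    def test_added_edge_dilutes_t1(self, toy_t1):
        """Giving d2 a second target cannot increase T1's score: d2's
        outflow is shared."""
        _, matrix, net = toy_t1
        params = DiffusionParams(alpha=0.1, beta=0.1, gamma=0.0, k=1)
        base = diffuse(net, "d1", params).targets[0]
        bigger = build_network(
            DTICatalog((DTIRecord("d2", "T1"), DTIRecord("d2", "T2"))), matrix
        )
        grown = diffuse(bigger, "d1", params)
        t1_score = grown.targets[list(bigger.target_ids).index("T1")]
        assert t1_score < base


class TestNetworkConstruction:
    def test_toy_counts(self):
        """2 drugs x 2 substructures (full block) + 1 target on d2: 5 nodes,
        5 edges."""
        matrix = SubstructureMatrix(("d1", "d2"), ("s1", "s2"), np.ones((2, 2)))
        net = build_network(DTICatalog((DTIRecord("d2", "T1"),)), matrix)
        assert (net.n_drugs, net.n_substructures, net.n_targets) == (2, 2, 1)
        assert net.n_edges == 5

    def test_empty_matrix_rejected(self):
        matrix = SubstructureMatrix((), ("s1",), np.zeros((0, 1)))
        with pytest.raises(ConfigurationError):
            build_network(DTICatalog((DTIRecord("d1", "T1"),)), matrix)

    def test_empty_catalog_rejected(self):
        matrix = SubstructureMatrix(("d1",), ("s1",), np.ones((1, 1)))
        with pytest.raises(ConfigurationError):
            build_network(DTICatalog(()), matrix)

    def test_network_is_simple(self):
        """Binarization collapses duplicated incidence into single edges."""
        matrix = SubstructureMatrix(("d1", "d2"), ("s1",), np.array([[3], [1]]))
        net = build_network(DTICatalog((DTIRecord("d2", "T1"),)), matrix)
        assert net.n_edges == 3

    def test_query_without_any_edge_is_capability_error(self):
        matrix = SubstructureMatrix(("d1", "d2"), ("s1",), np.array([[0], [1]]))
        net = build_network(DTICatalog((DTIRecord("d2", "T1"),)), matrix)
        with pytest.raises(CapabilityError):
            diffuse(net, "d1")


class TestOracleEquivalence:
    def test_matches_dense_transition_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            net = random_network(rng)
            params = random_params(rng)
            query = net.drug_ids[int(rng.integers(net.n_drugs))]
            f = diffuse(net, query, params)
            od, os_, ot = dense_oracle(net, query, params)
            assert np.allclose(f.drugs, od, atol=1e-10, rtol=0)
            assert np.allclose(f.substructures, os_, atol=1e-10, rtol=0)
            assert np.allclose(f.targets, ot, atol=1e-10, rtol=0)

    def test_conservation_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            net = random_network(rng)
            params = random_params(rng)
            query = net.drug_ids[int(rng.integers(net.n_drugs))]
            f = diffuse(net, query, params)
            assert f.total() == pytest.approx(1.0, abs=1e-12)


def nbi_oracle(b_dt, query_idx, k):
    """Classic two-phase network-based inference on a drug-target bipartite
    graph: targets split equally to drugs, drugs split equally to targets."""
    n_d, n_t = b_dt.shape
    f_t = b_dt[query_idx] / b_dt[query_idx].sum()
    for _ in range(k):
        f_d = np.zeros(n_d)
        for j in range(n_t):
            holders = np.flatnonzero(b_dt[:, j])
            for i in holders:
                f_d[i] += f_t[j] / len(holders)
        f_t = np.zeros(n_t)
        for i in range(n_d):
            owned = np.flatnonzero(b_dt[i])
            for j in owned:
                f_t[j] += f_d[i] / len(owned)
    return f_t


def test_reduces_to_classic_nbi_without_substructures():
    """With gamma=0, beta=0.5 and an all-zero substructure matrix (pruned to
    a pure drug-target network), the diffusion is classic NBI."""
    b_dt = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=float)
    drugs = ("d0", "d1", "d2")
    catalog = DTICatalog(
        tuple(DTIRecord(drugs[i], f"T{j}") for i in range(3) for j in range(3) if b_dt[i, j])
    )
    matrix = SubstructureMatrix(drugs, ("s0",), np.zeros((3, 1)))
    net = build_network(catalog, matrix)
    assert net.n_substructures == 0
    for k in (1, 2, 3):
        f = diffuse(net, "d0", DiffusionParams(alpha=0.0, beta=0.5, gamma=0.0, k=k))
        expected = nbi_oracle(b_dt, 0, k)
        assert np.allclose(f.targets, expected, atol=1e-12)


def test_permutation_equivariance():
    """Relabeling nodes permutes scores identically."""
    rng = np.random.default_rng(5)
    net = random_network(rng)
    params = DiffusionParams()
    query = net.drug_ids[0]
    base = dict(zip(net.target_ids, diffuse(net, query, params).targets))

    mapping = {t: f"Z{idx:02d}_{t}" for idx, t in enumerate(reversed(net.target_ids))}
    catalog = DTICatalog(
        tuple(
            DTIRecord(net.drug_ids[i], mapping[net.target_ids[j]])
            for i in range(net.n_drugs)
            for j in range(net.n_targets)
            if net.b_dt[i, j] > 0
        )
    )
    matrix = SubstructureMatrix(net.drug_ids, net.substructure_ids, net.b_ds)
    relabeled = build_network(catalog, matrix)
    scores = dict(zip(relabeled.target_ids, diffuse(relabeled, query, params).targets))
    for t, s in base.items():
        assert scores[mapping[t]] == pytest.approx(s, abs=1e-14)


class TestRankTargets:
    def test_l_must_be_positive(self, toy_t1):
        _, _, net = toy_t1
        f = diffuse(net, "d1")
        with pytest.raises(ParameterError):
            rank_targets(f, net, "d1", L=0)

    def test_equal_scores_break_alphabetically(self):
        matrix = SubstructureMatrix(("d1", "d2"), ("s1",), np.ones((2, 1)))
        catalog = DTICatalog((DTIRecord("d2", "TB"), DTIRecord("d2", "TA")))
        net = build_network(catalog, matrix)
        f = diffuse(net, "d1", DiffusionParams(alpha=0.1, beta=0.1, gamma=0.0, k=1))
        ranked = rank_targets(f, net, "d1", L=5)
        assert ranked.targets == ("TA", "TB")
        assert ranked.scores[0] == ranked.scores[1]

    def test_exclude_known_removes_training_targets(self, small_world):
        catalog, matrix, _, _ = small_world
        drug = catalog.drugs[0]
        known = set(catalog.targets_of(drug))
        with_known = predict_targets(catalog, matrix, drug, L=200, exclude_known=False)
        without = predict_targets(catalog, matrix, drug, L=200, exclude_known=True)
        assert known & set(with_known.targets)
        assert not known & set(without.targets)


def test_end_to_end_recovery_with_strong_signal():
    """A held-out cluster target (signal present in training) lands in the
    query's top 5 almost always under a fully deterministic cluster signal;
    with no signal the hit rate collapses to the random level."""
    hits = 0
    trials = 20
    for seed in range(trials):
        cat, mat, _, truth = gen_world(SynthConfig(seed=seed, signal_strength=1.0))
        drug = cat.drugs[0]
        cluster = truth.clusters[drug]
        pool = set(truth.cluster_targets[cluster]) & set(truth.drug_targets[drug])
        held = sorted(pool)[0]
        train = cat.drop_pairs([(drug, held)])
        ranked = predict_targets(train, mat, drug, L=5)
        hits += held in ranked.targets
    assert hits >= 0.9 * trials
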