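"""Bipartite weighting, projection and eigenvector centrality."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpia import (
    DataError,
    LPIAError,
    PathwayNetwork,
    build_bipartite,
    eigenvector_centrality,
    project,
)
from lpia.core import _centrality_array


def bruteforce_bipartite(P_sets, G_sets, mags):
    """Independent oracle: W_GP by direct set enumeration."""
    out = {}
    for gid, g in G_sets.items():
        for pid, p in P_sets.items():
            inter = sorted(set(g) & set(p))
            if not inter:
                continue
            vals = sorted(abs(mags[x]) for x in inter)
            m = len(vals)
            med = vals[m // 2] if m % 2 else (vals[m // 2 - 1] + vals[m // 2]) / 2
            out[(gid, pid)] = len(inter) / len(set(g) | set(p)) * med
    return out


def bruteforce_project(entries, go_ids, pathway_ids):
    """Independent oracle: dense triple loop for A_ij."""
    n = len(pathway_ids)
    A = np.zeros((n, n))
    for i, pi in enumerate(pathway_ids):
        for j, pj in enumerate(pathway_ids):
            if i == j:
                continue
            A[i, j] = sum(
                entries.get((g, pi), 0.0) * entries.get((g, pj), 0.0) for g in go_ids
            )
    return A


class TestBuildBipartite:
    def test_hand_calculation(self, make_collection, make_degs):
        P = make_collection({"P1": {"g2", "g3", "g4"}})
        G = make_collection({"G1": {"g1", "g2", "g3"}}, category="GO_BP")
        degs = make_degs({"g1": 1.0, "g2": 2.0, "g3": -4.0, "g4": 1.0})
        W = build_bipartite(P, G, degs)
        # Jaccard 2/4 times median{2, 4} = 0.5 * 3
        assert W.entries[("G1", "P1")] == pytest.approx(1.5)

    def test_identical_sets_unit_magnitudes(self, make_collection, make_degs):
        P = make_collection({"P1": {"a", "b"}})
        G = make_collection({"G1": {"a", "b"}}, category="GO_BP")
        W = build_bipartite(P, G, make_degs({"a": 1.0, "b": -1.0}))
        assert W.entries[("G1", "P1")] == pytest.approx(1.0)

    def test_disjoint_sets_have_no_entry(self, make_collection, make_degs):
        P = make_collection({"P1": {"a"}})
        G = make_collection({"G1": {"b"}}, category="GO_BP")
        W = build_bipartite(P, G, make_degs({"a": 1.0, "b": 1.0}))
        assert W.entries == {}

    def test_member_without_de_record_names_gene(self, make_collection, make_degs):
        P = make_collection({"P1": {"a", "missing_gene"}})
        G = make_collection({"G1": {"a"}}, category="GO_BP")
        with pytest.raises(DataError, match="missing_gene"):
            build_bipartite(P, G, make_degs({"a": 1.0}))

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        from factories import build_collection as make_collection
        from factories import build_degs as make_degs

        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(rng.integers(4, 30))]
        P_sets = {
            f"P{i}": set(rng.choice(genes, size=rng.integers(1, len(genes) + 1),
                                    replace=False))
            for i in range(rng.integers(1, 10))
        }
        G_sets = {
            f"G{i}": set(rng.choice(genes, size=rng.integers(1, len(genes) + 1),
                                    replace=False))
            for i in range(rng.integers(1, 10))
        }
        mags = {g: float(rng.lognormal()) * rng.choice([-1, 1]) for g in genes}
        W = build_bipartite(
            make_collection(P_sets), make_collection(G_sets, category="GO_BP"),
            make_degs(mags),
        )
        expected = bruteforce_bipartite(P_sets, G_sets, mags)
        assert set(W.entries) == set(expected)
        for key, v in expected.items():
            assert W.entries[key] == pytest.approx(v, rel=1e-12)


class TestProject:
    def test_hand_calculation(self):
        from lpia import BipartiteWeightMatrix

        W = BipartiteWeightMatrix(
            go_ids=["G1", "G2"], pathway_ids=["P1", "P2"],
            entries={("G1", "P1"): 0.5, ("G1", "P2"): 0.2,
                     ("G2", "P1"): 0.3, ("G2", "P2"): 0.4},
        )
        net = project(W)
        i, j = net.pathway_ids.index("P1"), net.pathway_ids.index("P2")
        assert net.weights[i, j] == pytest.approx(0.22)
        assert net.weights[i, i] == 0 and net.weights[j, j] == 0

    def test_single_shared_term_squares_weight(self):
        from lpia import BipartiteWeightMatrix

        w = 0.7
        W = BipartiteWeightMatrix(
            go_ids=["G1"], pathway_ids=["P1", "P2"],
            entries={("G1", "P1"): w, ("G1", "P2"): w},
        )
        assert project(W).weights[0, 1] == pytest.approx(w * w)

    def test_no_shared_term_gives_zero(self):
        from lpia import BipartiteWeightMatrix

        W = BipartiteWeightMatrix(
            go_ids=["G1", "G2"], pathway_ids=["P1", "P2"],
            entries={("G1", "P1"): 0.5, ("G2", "P2"): 0.5},
        )
        assert project(W).weights[0, 1] == 0.0

    def test_exact_symmetry_and_oracle(self, make_collection, make_degs):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(20)]
        P_sets = {f"P{i}": set(rng.choice(genes, 6, replace=False)) for i in range(8)}
        G_sets = {f"G{i}": set(rng.choice(genes, 5, replace=False)) for i in range(9)}
        W = build_bipartite(
            make_collection(P_sets), make_collection(G_sets, category="GO_BP"),
            make_degs({g: float(rng.lognormal()) for g in genes}),
        )
        net = project(W)
        assert np.array_equal(net.weights, net.weights.T)
        oracle = bruteforce_project(W.entries, W.go_ids, W.pathway_ids)
        np.testing.assert_allclose(net.weights, oracle, rtol=1e-12, atol=1e-15)


def _net(A, ids=None):
    A = np.asarray(A, dtype=float)
    ids = ids or [f"P{i}" for i in range(A.shape[0])]
    return PathwayNetwork(pathway_ids=ids, weights=A)


class TestEigenvectorCentrality:
    def test_two_node_symmetry(self):
        scores = eigenvector_centrality(_net([[0, 1], [1, 0]]))
        assert scores["P0"] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert scores["P1"] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_path_graph_closed_form(self):
        A = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        scores = eigenvector_centrality(_net(A))
        assert scores["P0"] == pytest.approx(0.5, abs=1e-8)
        assert scores["P1"] == pytest.approx(np.sqrt(0.5), abs=1e-8)
        assert scores["P2"] == pytest.approx(0.5, abs=1e-8)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.random((6, 6))
        A = np.triu(A, 1)
        A = A + A.T
        s1 = eigenvector_centrality(_net(A))
        s2 = eigenvector_centrality(_net(17.5 * A))
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-9)

    def test_isolated_node_scored_zero_and_flagged(self):
        from lpia.core import OFF_COMPONENT, PRINCIPAL, component_flags

        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 2.0
        net = _net(A)
        scores = eigenvector_centrality(net)
        flags = component_flags(net)
        assert scores["P2"] == 0.0
        assert flags == {"P0": PRINCIPAL, "P1": PRINCIPAL, "P2": OFF_COMPONENT}

    def test_largest_component_wins(self):
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = 100.0  # heavy 2-node component
        for i, j in [(2, 3), (3, 4)]:  # light 3-node component
            A[i, j] = A[j, i] = 0.1
        scores = eigenvector_centrality(_net(A))
        assert scores["P0"] == 0.0 and scores["P3"] > 0

    def test_edgeless_network_rejected(self):
        with pytest.raises(DataError):
            eigenvector_centrality(_net(np.zeros((3, 3))))

    def test_nonconvergence_reports_residual(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        with pytest.raises(LPIAError, match="residual"):
            _centrality_array(A, tol=0.0, max_iter=2)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        A = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        A = np.triu(A, 1)
        A = A + A.T
        if not np.any(A):
            A[0, 1] = A[1, 0] = 1.0
        scores, mask = _centrality_array(A, tol=1e-12, max_iter=100_000)
        sub = A[np.ix_(mask, mask)]
        vals, vecs = np.linalg.eigh(sub)
        ref = np.abs(vecs[:, -1])
        np.testing.assert_allclose(scores[mask], ref, atol=1e-8)
        assert np.all(scores >= 0)
        assert np.isclose(np.sum(scores**2), 1.0)


class TestPipelineInvariances:
    def test_irrelevant_go_term_changes_nothing(self, make_collection, make_degs):
        degs = make_degs({"a": 2.0, "b": 1.0, "c": 3.0, "zz": 1.0})
        P = make_collection({"P1": {"a", "b"}, "P2": {"b", "c"}})
        G1 = make_collection({"G1": {"a", "b"}, "G2": {"b", "c"}}, category="GO_BP")
        G2 = make_collection(
            {"G1": {"a", "b"}, "G2": {"b", "c"}, "Gx": {"zz"}}, category="GO_BP"
        )
        W1, W2 = (build_bipartite(P, g, degs) for g in (G1, G2))
        assert W1.entries == {k: v for k, v in W2.entries.items()}
        n1, n2 = project(W1), project(W2)
        np.testing.assert_array_equal(n1.weights, n2.weights)
        s1 = eigenvector_centrality(n1)
        s2 = eigenvector_centrality(n2)
        assert s1 == s2

    def test_magnitude_scaling_covariance(self, make_collection, make_degs):
        from lpia import LPIAConfig, bootstrap_significance

        c = 3.7
        P = make_collection({"P1": {"a", "b"}, "P2": {"b", "c"}, "P3": {"c", "d"}})
        G = make_collection(
            {"G1": {"a", "b"}, "G2": {"b", "c"}, "G3": {"c", "d"}}, category="GO_BP"
        )
        base = {"a": 2.0, "b": 1.0, "c": 3.0, "d": 0.5}
        d1 = make_degs(base)
        d2 = make_degs({g: v * c for g, v in base.items()})
        W1, W2 = build_bipartite(P, G, d1), build_bipartite(P, G, d2)
        for k in W1.entries:
            assert W2.entries[k] == pytest.approx(c * W1.entries[k])
        A1, A2 = project(W1), project(W2)
        np.testing.assert_allclose(A2.weights, c**2 * A1.weights)
        s1, s2 = eigenvector_centrality(A1), eigenvector_centrality(A2)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-9)
        cfg = LPIAConfig(n_boot=50, seed=11)
        r1 = bootstrap_significance(P, G, d1, cfg)
        r2 = bootstrap_significance(P, G, d2, cfg)
        assert r1.raw_p == r2.raw_p
        assert r1.adjusted_p == r2.adjusted_p
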