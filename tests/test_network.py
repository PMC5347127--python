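import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pccorrnet as pcn
from pccorrnet.datatypes import FrustrationError, ValidationError

from conftest import frustration_fixture, run_pccorr

# magnitudes bounded away from 0: loadings of a unit-norm PC are not denormal
finite_loadings = st.lists(
    st.floats(min_value=-1, max_value=1, allow_nan=False).filter(
        lambda v: abs(v) >= 1e-6
    ),
    min_size=2,
    max_size=30,
)


class TestLoadingNormalization:
    def test_worked_example(self):
        nl = pcn.normalize_loadings([0.9, 0.1])
        assert nl.mean_abs == pytest.approx(0.5)
        np.testing.assert_allclose(nl.v_star, [0.44716, 0.07918], atol=1e-5)
        scaled = pcn.scale_loadings(nl)
        np.testing.assert_allclose(scaled.v_new, [1.0, 0.17707], atol=1e-4)

    def test_equal_magnitudes_all_log2(self):
        nl = pcn.normalize_loadings([0.5, -0.5, 0.5, -0.5])
        np.testing.assert_allclose(np.abs(nl.v_star), np.log10(2))
        np.testing.assert_allclose(np.sign(nl.v_star), [1, -1, 1, -1])
        scaled = pcn.scale_loadings(nl)
        assert set(np.round(scaled.v_new, 12)) == {1.0, -1.0}

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            pcn.normalize_loadings([0.0, 0.0])

    def test_scaling_idempotent(self):
        nl = pcn.process_loadings([0.3, -0.8, 0.05])
        again = pcn.scale_loadings(nl)
        np.testing.assert_array_equal(nl.v_new, again.v_new)

    @given(finite_loadings)
    def test_sign_and_rank_order_preserved(self, v):
        v = np.asarray(v)
        nl = pcn.process_loadings(v)
        np.testing.assert_array_equal(np.sign(nl.v_new), np.sign(v))
        # |v_star| strictly increasing in |v_raw|
        order = np.argsort(np.abs(v), kind="mergesort")
        mags = np.abs(nl.v_star)[order]
        raw = np.abs(v)[order]
        for a, b, ra, rb in zip(mags[:-1], mags[1:], raw[:-1], raw[1:]):
            if rb > ra:
                assert b > a
        assert np.max(np.abs(nl.v_new)) == pytest.approx(1.0)


class TestPearsonMatrix:
    def test_duplicate_and_negated_features(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(8)
        m = pcn.OmicMatrix(
            np.column_stack([base, base, -base]),
            [f"s{i}" for i in range(8)],
            ["f", "dup", "neg"],
        )
        c = pcn.pearson_matrix(m)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.standard_normal((5, 4))
        m = pcn.OmicMatrix(vals, [f"s{i}" for i in range(5)],
                           [f"f{j}" for j in range(4)])
        c = pcn.pearson_matrix(m)
        for i in range(4):
            for j in range(4):
                xi = vals[:, i] - vals[:, i].mean()
                xj = vals[:, j] - vals[:, j].mean()
                ref = (xi * xj).sum() / np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
                assert c[i, j] == pytest.approx(ref, abs=1e-12)

    def test_constant_feature_zeroed(self):
        m = pcn.OmicMatrix([[1, 5], [2, 5], [3, 5]], list("abc"), ["f1", "f2"])
        with pytest.warns(UserWarning, match="constant"):
            c = pcn.pearson_matrix(m)
        assert c[0, 1] == 0.0
        assert c[1, 1] == 1.0


class TestEdgeFormula:
    @pytest.mark.parametrize(
        "c, vi, vj, expected",
        [
            (0.8, 1.0, 0.6, 0.6),
            (-0.9, 0.95, 0.85, -0.85),
            (0.0, 0.7, 0.9, 0.0),
        ],
    )
    def test_hand_values(self, c, vi, vj, expected):
        assert pcn.pccorr_edge(c, vi, vj) == pytest.approx(expected)

    def test_matches_scalar_oracle_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            c, vi, vj = rng.uniform(-1, 1, size=3)
            oracle = np.sign(c) * min(abs(c), abs(vi), abs(vj))
            assert pcn.pccorr_edge(c, vi, vj) == oracle

    def test_matrix_matches_elementwise_oracle(self, and_gate_data):
        matrix, labels, _ = and_gate_data
        net, sel, pcc = run_pccorr(matrix, labels)
        c, v = pcc.corr, pcc.v_new
        n = len(v)
        for i in range(n):
            for j in range(n):
                expected = 0.0 if i == j else np.sign(c[i, j]) * min(
                    abs(c[i, j]), abs(v[i]), abs(v[j])
                )
                assert pcc.weights[i, j] == pytest.approx(expected, abs=1e-15)

    def test_bound_property(self, and_gate_data):
        matrix, labels, _ = and_gate_data
        _, _, pcc = run_pccorr(matrix, labels)
        cap = np.minimum(
            np.abs(pcc.corr),
            np.minimum(np.abs(pcc.v_new)[:, None], np.abs(pcc.v_new)[None, :]),
        )
        off = ~np.eye(len(pcc.v_new), dtype=bool)
        np.testing.assert_allclose(np.abs(pcc.weights)[off], cap[off], atol=1e-15)

    def test_zero_loading_annihilates_row(self):
        v = np.array([0.0, 1.0, 0.8])
        c = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]])
        pcc = pcn.pccorr_from_corr(c, v, ["a", "b", "c"])
        assert (pcc.weights[0] == 0).all()


def singleton_fixture():
    names = ["A", "B", "C", "E"]
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 0.7   # AB
    W[1, 2] = W[2, 1] = 0.4   # BC
    W[2, 3] = W[3, 2] = 0.2   # CE
    return pcn.PCCorrMatrix(W, None, np.ones(4), names)


class TestThresholding:
    def test_singleton_removal(self):
        net = pcn.threshold_network(singleton_fixture(), 0.5)
        assert net.edge_set() == {("A", "B")}
        assert net.node_set() == {"A", "B"}

    def test_cutoff_above_max_weight_empties(self):
        with pytest.warns(UserWarning, match="empty"):
            net = pcn.threshold_network(singleton_fixture(), 1.0)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_monotone_in_cutoff(self, and_gate_data):
        matrix, labels, _ = and_gate_data
        _, _, pcc = run_pccorr(matrix, labels)
        previous = None
        for cutoff in (0.8, 0.7, 0.6, 0.5, 0.4):
            edges = pcn.threshold_network(pcc, cutoff).edge_set()
            if previous is not None:
                assert previous <= edges
            previous = edges

    def test_cutoff_bounds(self):
        with pytest.raises(ValidationError):
            pcn.threshold_network(singleton_fixture(), 1.5)

    def test_node_group_attribution_by_medians(self, and_gate_data):
        matrix, labels, truth = and_gate_data
        net, _, _ = run_pccorr(matrix, labels, cutoff=0.5)
        shift = dict(zip(truth.table["feature"], truth.table["shift_sign"]))
        # features shifted upward in group B must be attributed to group B
        for row in net.nodes.itertuples(index=False):
            if shift.get(row.feature) == 1:
                assert row.group == "B"


class TestFrustration:
    def test_enumeration_fixture_one_third(self):
        net = pcn.threshold_network(frustration_fixture(), 0.5)
        fr = pcn.compute_frustration(net)
        assert fr.fraction == pytest.approx(1 / 3)
        assert fr.frustrated == [("n1", "n3")]

    def test_all_consistent_edges_zero(self):
        names = ["a", "b", "c"]
        W = np.full((3, 3), 0.7)
        np.fill_diagonal(W, 0.0)
        pcc = pcn.PCCorrMatrix(W, None, np.array([0.9, 0.8, 0.7]), names)
        fr = pcn.compute_frustration(pcn.threshold_network(pcc, 0.5))
        assert fr.fraction == 0.0

    def test_global_node_sign_flip_invariance(self):
        # frustration depends on the endpoint sign *product*, so flipping
        # every node sign (edges unchanged) preserves each edge's status
        pcc = frustration_fixture()
        flipped = pcn.PCCorrMatrix(
            pcc.weights, None, -pcc.v_new, pcc.feature_names
        )
        a = pcn.compute_frustration(pcn.threshold_network(pcc, 0.5))
        b = pcn.compute_frustration(pcn.threshold_network(flipped, 0.5))
        assert a.fraction == b.fraction
        assert a.frustrated == b.frustrated


def drop_fixture(n_frustrated):
    """Two 6-cliques of same-sign nodes (30 edges, weight 0.7) with
    ``n_frustrated`` edges inside the positive clique flipped negative."""
    names = [f"p{i}" for i in range(6)] + [f"m{i}" for i in range(6)]
    v = np.array([0.9] * 6 + [-0.9] * 6)
    W = np.zeros((12, 12))
    for block in (range(6), range(6, 12)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 0.7
    flips = [(0, 1), (2, 3)][:n_frustrated]
    for i, j in flips:
        W[i, j] = W[j, i] = -0.7
    return pcn.PCCorrMatrix(W, None, v, names)


class TestResolveFrustration:
    def test_report_annotates_only(self):
        net, log = pcn.resolve_frustration(frustration_fixture(), 0.5, "report")
        assert net.n_edges == 3
        assert log["initial_fraction"] == pytest.approx(1 / 3)

    def test_drop_under_five_percent(self):
        net, log = pcn.resolve_frustration(drop_fixture(1), 0.5, "drop")
        assert net.n_edges == 29
        assert log["dropped"] == [("p0", "p1")]

    def test_drop_refuses_at_five_percent(self):
        with pytest.raises(FrustrationError):
            pcn.resolve_frustration(drop_fixture(2), 0.5, "drop")

    def test_frustration_free_network_is_fixed_point(self):
        pcc = drop_fixture(0)
        for policy in ("report", "drop", "raise"):
            net, log = pcn.resolve_frustration(pcc, 0.5, policy)
            assert net.n_edges == 30
            assert log["final_cutoff"] == 0.5

    def test_raise_policy_terminates_at_engineered_cutoff(self):
        names = ["A", "B", "C", "D"]
        v = np.array([1.0, 0.9, -0.95, 0.8])
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.9    # A-B (+,+) fine
        W[1, 3] = W[3, 1] = 0.85   # B-D fine
        W[0, 3] = W[3, 0] = 0.8    # A-D fine
        W[0, 2] = W[2, 0] = 0.71   # A-C (+,-) positive: frustrated until 0.72
        pcc = pcn.PCCorrMatrix(W, None, v, names)
        net, log = pcn.resolve_frustration(pcc, 0.6, "raise")
        assert log["final_cutoff"] == pytest.approx(0.72)
        assert pcn.compute_frustration(net).fraction == 0.0
        assert net.edge_set() == {("A", "B"), ("B", "D"), ("A", "D")}
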