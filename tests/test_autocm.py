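import numpy as np
import pytest

from pedree.autocm import (
    ConnectivityMap, brute_force_mst_weight, central_node, distance_matrix,
    minimum_spanning_tree, scale_unit, semantic_map, train_autocm,
)
from pedree.errors import DataContractError, DegenerateVariableError, InvalidConfigError


class TestScaleUnit:
    def test_basic(self):
        scaled, mins, rng = scale_unit(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(scaled.ravel(), [0, 0.5, 1])

    def test_already_unit(self):
        x = np.array([[0.0, 0.25], [0.5, 0.5], [1.0, 1.0], [0.2, 0.0]])
        scaled, _, _ = scale_unit(x)
        assert np.allclose(scaled, x)

    def test_constant_column_named(self):
        import pandas as pd
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(DegenerateVariableError, match="flat"):
            scale_unit(df)


class TestTraining:
    def test_single_record_energy_monotone(self, rng):
        for _ in range(3):
            x = rng.uniform(0, 1, (1, 13))
            model = train_autocm(x, C=13.0, max_epochs=400)
            e = np.array(model.energy_history)
            assert np.all(np.diff(e) <= 1e-12)

    def test_deterministic(self, rng):
        x = rng.uniform(0, 1, (50, 5))
        m1 = train_autocm(x, max_epochs=50)
        m2 = train_autocm(x, max_epochs=50)
        assert np.array_equal(m1.w, m2.w) and np.array_equal(m1.v, m2.v)

    def test_weights_bounded_by_c_throughout(self, rng):
        # growing epoch budgets sample the whole trajectory
        x = rng.uniform(0, 1, (30, 6))
        for epochs in (1, 2, 5, 10, 40):
            m = train_autocm(x, max_epochs=epochs, tolerance=0.0)
            assert m.v.min() >= 0 and m.v.max() <= m.C + 1e-12
            assert m.w.min() >= 0 and m.w.max() <= m.C + 1e-12

    def test_correlated_pair_stronger_than_independent(self, rng):
        n = 200
        a = rng.normal(size=n)
        x = np.c_[a, a + 0.05 * rng.normal(size=n),
                  rng.normal(size=n), rng.normal(size=n)]
        scaled, _, _ = scale_unit(x)
        m = train_autocm(scaled, max_epochs=300)
        s = 1.0 - distance_matrix(m)
        assert s[0, 1] > s[2, 3]
        assert s[0, 1] > s[0, 2]

    def test_zero_epochs(self, rng):
        x = rng.uniform(0, 1, (10, 3))
        m = train_autocm(x, max_epochs=0)
        assert not m.converged
        assert np.all(m.w == 0) and np.all(m.v == 0)

    def test_c_below_one_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            train_autocm(rng.uniform(0, 1, (5, 3)), C=0.5)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(InvalidConfigError):
            train_autocm(np.array([[0.5, 1.5]]))


class TestDistanceMatrix:
    def test_limits(self):
        from pedree.autocm import AutoCmModel
        C = 4.0
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = C
        model = AutoCmModel(["a", "b", "c"], np.zeros(3), w, C, 1, True)
        d = distance_matrix(model)
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestMst:
    def test_forced_tree(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.2], [0.9, 0.2, 0.0]])
        cm = minimum_spanning_tree(d, ["A", "B", "C"])
        pairs = {(a, b) for a, b, _ in cm.edges}
        assert pairs == {("A", "B"), ("B", "C")}

    def test_thirteen_nodes_twelve_edges(self, rng):
        x = rng.uniform(size=(13, 13))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        cm = minimum_spanning_tree(d)
        assert len(cm.edges) == 12 and cm.is_tree

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(0.05, 1.0, size=(6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        cm = minimum_spanning_tree(d)
        names = cm.nodes
        total = sum(1.0 - s for _, _, s in cm.edges)  # strength back to distance
        assert total == pytest.approx(brute_force_mst_weight(d), abs=1e-9)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(DataContractError):
            minimum_spanning_tree(d)


class TestCentralNode:
    def test_path(self):
        cm = ConnectivityMap(["A", "B", "C"],
                             [("A", "B", 0.5), ("B", "C", 0.5)], True)
        assert central_node(cm) == "B"

    def test_star(self):
        cm = ConnectivityMap(
            ["H", "a", "b", "c"],
            [("H", "a", 0.5), ("H", "b", 0.5), ("H", "c", 0.5)], True)
        assert central_node(cm) == "H"

    def test_seven_node_hand_pruned(self):
        # a-b-c-d-e with leaves f on c and g on d; pruning by hand:
        # round 1 removes a,e,f,g -> path b-c-d; round 2 removes b -> wait,
        # b and d are now leaves, leaving c. Centre is c.
        edges = [("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7),
                 ("d", "e", 0.6), ("c", "f", 0.5), ("d", "g", 0.4)]
        cm = ConnectivityMap(list("abcdefg"), edges, True)
        assert central_node(cm) == "c"

    def test_two_survivors_strength_tiebreak(self):
        # even path a-b-c-d: survivors b,c; c has larger incident strength
        edges = [("a", "b", 0.2), ("b", "c", 0.5), ("c", "d", 0.9)]
        cm = ConnectivityMap(list("abcd"), edges, True)
        assert central_node(cm) == "c"

    def test_non_tree_rejected(self):
        cm = ConnectivityMap(["A", "B", "C"],
                             [("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.5)],
                             False)
        with pytest.raises(DataContractError):
            central_node(cm)


class TestBlockStructure:
    def test_block_coherent_mst_agrees_with_correlation_oracle(self, rng):
        n = 300
        base1, base2 = rng.normal(size=n), rng.normal(size=n)
        cols = [base1 + 0.3 * rng.normal(size=n) for _ in range(4)]
        cols += [base2 + 0.3 * rng.normal(size=n) for _ in range(4)]
        x = np.column_stack(cols)
        names = [f"v{i}" for i in range(8)]

        import pandas as pd
        _, cm = semantic_map(pd.DataFrame(x, columns=names), max_epochs=300)
        within = sum(1 for a, b, _ in cm.edges if (int(a[1]) < 4) == (int(b[1]) < 4))
        across = len(cm.edges) - within
        assert within > across

        # independent oracle: MST on (1 - |pearson r|)
        d = 1.0 - np.abs(np.corrcoef(x.T))
        np.fill_diagonal(d, 0.0)
        oracle = minimum_spanning_tree(d, names)
        o_within = sum(1 for a, b, _ in oracle.edges if (int(a[1]) < 4) == (int(b[1]) < 4))
        assert o_within > len(oracle.edges) - o_within


def test_map_exports(tmp_path, rng):
    import pandas as pd
    x = pd.DataFrame(rng.uniform(size=(40, 4)), columns=list("abcd"))
    _, cm = semantic_map(x, max_epochs=50)
    j = cm.to_json(tmp_path / "m.json")
    dot = cm.to_dot(tmp_path / "m.dot")
    assert "central_node" in j and "--" in dot
    assert (tmp_path / "m.json").exists() and (tmp_path / "m.dot").exists()
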