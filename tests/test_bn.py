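import itertools
import math
import re

import numpy as np
import pytest
from scipy.special import gammaln

from mmibn import (
    BayesianNetworkModel,
    DiscretizedDataset,
    ScoreConfig,
    edge_strength,
    export_dot,
    family_score,
    generate_bn_fixture,
    learn_structure,
    sparse_candidates,
)


def disc(variables, cards, data):
    return DiscretizedDataset(
        variables, cards, np.asarray(data),
        [f"s{i}" for i in range(np.asarray(data).shape[1])],
    )


def all_dags(nodes):
    """Every DAG over the node list (25 for three nodes)."""
    pairs = list(itertools.permutations(nodes, 2))
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, m in zip(pairs, mask) if m]
        if not _cyclic(nodes, edges):
            yield edges


def _cyclic(nodes, edges):
    children = {n: [v for u, v in edges if u == n] for n in nodes}
    state = {n: 0 for n in nodes}

    def visit(n):
        if state[n] == 1:
            return True
        if state[n] == 2:
            return False
        state[n] = 1
        if any(visit(c) for c in children[n]):
            return True
        state[n] = 2
        return False

    return any(visit(n) for n in nodes)


def brute_force_best_score(data, cfg):
    best = -math.inf
    for edges in all_dags(data.variables):
        total = sum(
            family_score(data, v, [u for u, w in edges if w == v], cfg)
            for v in data.variables
        )
        best = max(best, total)
    return best


def parse_dot(text):
    """Minimal independent DOT reader: returns (nodes, {(u,v): label})."""
    assert text.strip().startswith("digraph")
    nodes, edges = set(), {}
    for line in text.splitlines()[1:]:
        line = line.strip().rstrip(";")
        if not line or line == "}":
            continue
        m = re.match(r'"([^"]+)"\s*->\s*"([^"]+)"\s*\[label="([^"]*)"', line)
        if m:
            edges[(m.group(1), m.group(2))] = m.group(3)
            continue
        m = re.match(r'"([^"]+)"$', line)
        if m:
            nodes.add(m.group(1))
    return nodes, edges


# root marginals deliberately unequal: with fair coins the XOR joint is
# fully symmetric and the three collider orientations are likelihood-
# identical, so "collider at Z" would be unidentifiable
XOR_CPDS = {
    "X": {"levels": 2, "parents": [], "probs": [[0.65, 0.35]]},
    "Y": {"levels": 2, "parents": [], "probs": [[0.35, 0.65]]},
    "Z": {
        "levels": 2,
        "parents": ["X", "Y"],
        "probs": [[0.95, 0.05], [0.05, 0.95], [0.05, 0.95], [0.95, 0.05]],
    },
}

CHAIN_CPDS = {
    "X": {"levels": 2, "parents": [], "probs": [[0.5, 0.5]]},
    "Y": {"levels": 2, "parents": ["X"], "probs": [[0.95, 0.05], [0.05, 0.95]]},
    "Z": {"levels": 2, "parents": ["Y"], "probs": [[0.95, 0.05], [0.05, 0.95]]},
}


class TestFamilyScore:
    def test_no_parent_binary_counts_3_1(self):
        data = disc(["c"], [2], [[0, 0, 0, 1]])
        got = family_score(data, "c", [], ScoreConfig(ess=1.0))
        # log[ B(0.5+3, 0.5+1) / B(0.5, 0.5) ] by direct Gamma evaluation
        def logB(a, b):
            return gammaln(a) + gammaln(b) - gammaln(a + b)
        assert got == pytest.approx(logB(3.5, 1.5) - logB(0.5, 0.5), abs=1e-12)

    def test_unobserved_parent_config_contributes_zero(self):
        # parent always 0: score equals the same family with q=2 prior but
        # only the observed config accumulating counts
        data = disc(["p", "c"], [2, 2], [[0, 0, 0, 0], [0, 1, 0, 1]])
        cfg = ScoreConfig(ess=2.0)
        got = family_score(data, "c", ["p"], cfg)
        a = cfg.ess / (2 * 2)
        expected = (
            gammaln(2 * a) - gammaln(2 * a + 4)
            + (gammaln(a + 2) - gammaln(a)) * 2
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_row_order_invariance(self, rng):
        vals = rng.integers(0, 2, (2, 50))
        data = disc(["a", "b"], [2, 2], vals)
        perm = rng.permutation(50)
        data2 = disc(["a", "b"], [2, 2], vals[:, perm])
        assert family_score(data, "b", ["a"]) == pytest.approx(
            family_score(data2, "b", ["a"]), abs=1e-12
        )

    def test_child_in_parents_errors(self):
        data = disc(["a"], [2], [[0, 1]])
        with pytest.raises(ValueError):
            family_score(data, "a", ["a"])

    def test_unknown_variable_errors(self):
        data = disc(["a"], [2], [[0, 1]])
        with pytest.raises(KeyError):
            family_score(data, "zz", [])


class TestSparseCandidates:
    def test_identical_variables_are_candidates(self, rng):
        x = rng.integers(0, 2, 200)
        z = rng.integers(0, 2, 200)
        data = disc(["X", "Y", "Z"], [2, 2, 2], [x, x, z])
        cand = sparse_candidates(data, 1)
        assert "Y" in cand["X"] and "X" in cand["Y"]

    def test_full_sets_when_m_large(self, rng):
        data = disc(["a", "b", "c"], [2, 2, 2], rng.integers(0, 2, (3, 50)))
        cand = sparse_candidates(data, 10)
        for v, others in cand.items():
            assert others == frozenset({"a", "b", "c"}) - {v}

    def test_chain_neighbors_recovered(self):
        hits = 0
        for seed in range(10):
            data = generate_bn_fixture(
                [("X", "Y"), ("Y", "Z")], CHAIN_CPDS, n=1000, seed=seed
            )
            cand = sparse_candidates(data, 1)
            hits += int("X" in cand["Y"] or "Z" in cand["Y"])
            hits += int("Y" in cand["X"])
        assert hits >= 18  # >= 9/10 seeds for both checks


class TestLearnStructure:
    def test_independent_variables_empty_graph(self, rng):
        data = disc(
            ["a", "b", "c"], [2, 2, 2], rng.integers(0, 2, (3, 2000))
        )
        model = learn_structure(data, ScoreConfig(seed=0))
        assert model.edges == []

    def test_v_structure_recovered(self):
        good = 0
        for seed in range(10):
            data = generate_bn_fixture(
                [("X", "Z"), ("Y", "Z")], XOR_CPDS, n=2000, seed=seed
            )
            model = learn_structure(data, ScoreConfig(seed=seed))
            skeleton = {frozenset(e) for e in model.edges}
            collider = (
                skeleton == {frozenset({"X", "Z"}), frozenset({"Y", "Z"})}
                and ("X", "Z") in model.edges
                and ("Y", "Z") in model.edges
            )
            good += int(collider)
        assert good >= 8

    def test_chain_recovered(self):
        data = generate_bn_fixture([("X", "Y"), ("Y", "Z")], CHAIN_CPDS, n=2000, seed=1)
        model = learn_structure(data, ScoreConfig(seed=1))
        skeleton = {frozenset(e) for e in model.edges}
        assert skeleton == {frozenset({"X", "Y"}), frozenset({"Y", "Z"})}

    def test_matches_brute_force_on_3_nodes(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(30, 201))
            data = generate_bn_fixture(
                [("X", "Y"), ("Y", "Z")], CHAIN_CPDS, n=n, seed=seed + 100
            )
            cfg = ScoreConfig(seed=seed)
            model = learn_structure(data, cfg)
            assert model.log_score == pytest.approx(
                brute_force_best_score(data, cfg), abs=1e-6
            )

    def test_score_trace_monotone(self, rng):
        data = generate_bn_fixture([("X", "Z"), ("Y", "Z")], XOR_CPDS, n=500, seed=3)
        model = learn_structure(data, ScoreConfig(seed=3))
        trace = np.asarray(model.score_trace)
        assert (np.diff(trace) > 0).all()

    def test_total_score_decomposable(self):
        data = generate_bn_fixture([("X", "Y"), ("Y", "Z")], CHAIN_CPDS, n=400, seed=4)
        model = learn_structure(data, ScoreConfig(seed=4))
        assert model.log_score == pytest.approx(model.total_score(data), abs=1e-9)

    def test_deterministic_given_seed(self):
        data = generate_bn_fixture([("X", "Z"), ("Y", "Z")], XOR_CPDS, n=600, seed=5)
        m1 = learn_structure(data, ScoreConfig(seed=7))
        m2 = learn_structure(data, ScoreConfig(seed=7))
        assert m1.edges == m2.edges and m1.log_score == m2.log_score

    def test_acyclic_model_enforced(self):
        with pytest.raises(ValueError, match="cycle"):
            BayesianNetworkModel(["a", "b"], [("a", "b"), ("b", "a")], 0.0)


class TestEdgeStrength:
    def test_copy_edge_strong(self, rng):
        x = rng.integers(0, 2, 100)
        data = disc(["X", "Y"], [2, 2], [x, x])
        model = learn_structure(data, ScoreConfig(seed=0))
        assert len(model.edges) == 1
        assert model.edge_strengths[model.edges[0]] > 5

    def test_equals_family_score_difference(self):
        data = generate_bn_fixture([("X", "Y"), ("Y", "Z")], CHAIN_CPDS, n=300, seed=6)
        model = learn_structure(data, ScoreConfig(seed=6))
        for (u, v), s in model.edge_strengths.items():
            parents = model.parents_of(v)
            diff = family_score(data, v, parents) - family_score(
                data, v, [p for p in parents if p != u]
            )
            assert s == pytest.approx(diff / math.log(10), abs=1e-9)

    def test_missing_edge_errors(self):
        model = BayesianNetworkModel(["a", "b"], [], 0.0)
        data = disc(["a", "b"], [2, 2], [[0, 1] * 10, [0, 1] * 10])
        with pytest.raises(ValueError):
            edge_strength(model, data, ("a", "b"))


class TestExportDot:
    def test_empty_model_has_nodes_no_edges(self):
        model = BayesianNetworkModel(["n1", "n2"], [], 0.0)
        nodes, edges = parse_dot(export_dot(model))
        assert nodes == {"n1", "n2"} and edges == {}

    def test_edge_label_formatting(self):
        model = BayesianNetworkModel(
            ["A", "B"], [("A", "B")], 0.0, edge_strengths={("A", "B"): 14.13}
        )
        text = export_dot(model)
        assert '"A" -> "B"' in text and 'label="14.13"' in text

    def test_roundtrip_with_independent_parser(self):
        data = generate_bn_fixture([("X", "Y"), ("Y", "Z")], CHAIN_CPDS, n=500, seed=8)
        model = learn_structure(data, ScoreConfig(seed=8))
        nodes, edges = parse_dot(export_dot(model))
        assert nodes == set(model.nodes)
        assert set(edges) == set(model.edges)
        for e, label in edges.items():
            assert label == f"{model.edge_strengths[e]:.2f}"

    def test_model_json_roundtrip(self, tmp_path):
        data = generate_bn_fixture([("X", "Z"), ("Y", "Z")], XOR_CPDS, n=300, seed=9)
        model = learn_structure(data, ScoreConfig(seed=9))
        model.to_json(tmp_path / "m.json")
        back = BayesianNetworkModel.from_json(tmp_path / "m.json")
        assert back.edges == model.edges
        assert back.edge_strengths == model.edge_strengths
        assert back.config == model.config


class TestScoreConfig:
    def test_invalid_ess(self):
        with pytest.raises(ValueError):
            ScoreConfig(ess=0.0)

    def test_candidates_vs_max_parents(self):
        with pytest.raises(ValueError):
            ScoreConfig(max_parents=5, candidates_per_node=3)
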