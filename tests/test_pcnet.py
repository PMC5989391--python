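"""PC-algorithm pruning: stagewise behavior and structural recovery."""

import numpy as np
import pytest
from scipy import stats

from methnet.containers import VariableVector
from methnet.errors import ValidationError
from methnet.pcnet import (
    PcParams,
    apply_mi_floor,
    build_complete_graph,
    edge_seed,
    infer_network,
    prune_by_cmi,
    prune_by_mi,
    write_edges,
)

from conftest import as_vectors


def _chain(seed, n=1000):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = a + rng.standard_normal(n)
    c = b + rng.standard_normal(n)
    return as_vectors({"A": a, "B": b, "C": c})


class TestBuildCompleteGraph:
    @pytest.mark.parametrize("n_vars,n_edges", [(2, 1), (4, 6), (6, 15)])
    def test_edge_count(self, rng, n_vars, n_edges):
        variables = as_vectors(
            {f"v{i}": rng.standard_normal(30) for i in range(n_vars)}
        )
        net = build_complete_graph(variables)
        assert len(net.edges) == n_edges

    def test_single_variable_errors(self, rng):
        with pytest.raises(ValidationError):
            build_complete_graph(as_vectors({"v": rng.standard_normal(30)}))

    def test_duplicate_ids_error(self, rng):
        dup = [
            VariableVector("x", rng.standard_normal(30)),
            VariableVector("x", rng.standard_normal(30)),
        ]
        with pytest.raises(ValidationError):
            build_complete_graph(dup)


class TestPruneByMi:
    def test_independent_pair_removed_dependent_kept(self):
        removed = kept = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(500)
            noise = rng.standard_normal(500)
            close = x + 0.2 * rng.standard_normal(500)
            net = build_complete_graph(
                as_vectors({"x": x, "noise": noise, "close": close})
            )
            pruned = prune_by_mi(net, PcParams(seed=seed))
            removed += frozenset(("x", "noise")) not in pruned.edges
            kept += frozenset(("x", "close")) in pruned.edges
        assert removed >= 9
        assert kept == 10

    def test_empty_edge_set_passthrough(self, rng):
        net = build_complete_graph(
            as_vectors({"a": rng.standard_normal(50), "b": rng.standard_normal(50)})
        )
        net.graph.remove_edges_from(list(net.graph.edges))
        assert prune_by_mi(net, PcParams()).edges == set()

    def test_surviving_edges_carry_mi(self, rng):
        x = rng.standard_normal(300)
        y = x + 0.3 * rng.standard_normal(300)
        net = prune_by_mi(
            build_complete_graph(as_vectors({"x": x, "y": y})), PcParams()
        )
        attrs = net.edge_attrs("x", "y")
        assert attrs["mi_bits"] > 0
        assert 0 <= attrs["p_value"] < 0.01


class TestPruneByCmi:
    def test_chain_indirect_edge_removed(self):
        wins = 0
        for seed in range(10):
            params = PcParams(seed=seed)
            net = prune_by_mi(build_complete_graph(_chain(seed)), params)
            net = prune_by_cmi(net, params)
            wins += net.edges == {frozenset("AB"), frozenset("BC")}
        assert wins >= 9

    def test_collider_spouses_unlinked_after_mi(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(1000)
            b = rng.standard_normal(1000)
            c = a + b + rng.standard_normal(1000)
            params = PcParams(seed=seed)
            net = prune_by_mi(
                build_complete_graph(as_vectors({"A": a, "B": b, "C": c})), params
            )
            assert frozenset("AB") not in net.edges

    def test_edge_without_common_neighbors_untouched(self, rng):
        x = rng.standard_normal(400)
        y = x + 0.3 * rng.standard_normal(400)
        params = PcParams(seed=1)
        net = prune_by_mi(build_complete_graph(as_vectors({"x": x, "y": y})), params)
        assert prune_by_cmi(net, params).edges == {frozenset(("x", "y"))}


class TestMiFloor:
    def _net_with_bits(self, rng, bits):
        x = rng.standard_normal(200)
        y = x + 0.1 * rng.standard_normal(200)
        net = prune_by_mi(
            build_complete_graph(as_vectors({"x": x, "y": y})), PcParams()
        )
        net.graph.edges["x", "y"]["mi_bits"] = bits
        return net

    def test_weak_edge_removed(self, rng):
        net = self._net_with_bits(rng, 0.05)
        assert apply_mi_floor(net, PcParams()).edges == set()

    def test_strong_edge_kept(self, rng):
        net = self._net_with_bits(rng, 0.25)
        assert apply_mi_floor(net, PcParams()).edges == {frozenset(("x", "y"))}

    def test_boundary_is_strict(self, rng):
        net = self._net_with_bits(rng, 0.1)
        assert apply_mi_floor(net, PcParams(mi_floor_bits=0.1)).edges == set()

    def test_zero_floor_identity(self, rng):
        net = self._net_with_bits(rng, 0.02)
        assert apply_mi_floor(net, PcParams(mi_floor_bits=0.0)).edges == {
            frozenset(("x", "y"))
        }


class TestInferNetwork:
    def test_deterministic_replay(self):
        variables = _chain(3)
        a = infer_network(variables, PcParams(seed=7))
        b = infer_network(variables, PcParams(seed=7))
        assert a.edges == b.edges

    def test_monotone_pruning(self):
        params = PcParams(seed=5)
        net0 = build_complete_graph(_chain(5))
        net1 = prune_by_mi(net0, params)
        net2 = prune_by_cmi(net1, params)
        net3 = apply_mi_floor(net2, params)
        assert net1.edges <= net0.edges
        assert net2.edges <= net1.edges
        assert net3.edges <= net2.edges

    def test_order_robustness(self):
        variables = _chain(9)
        forward = infer_network(variables, PcParams(seed=2))
        backward = infer_network(variables[::-1], PcParams(seed=2))
        assert forward.edges == backward.edges

    def test_independent_variables_rarely_linked(self):
        total_edges = 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(seed + 100)
            variables = as_vectors(
                {f"v{i}": rng.standard_normal(300) for i in range(10)}
            )
            total_edges += len(infer_network(variables, PcParams(seed=seed)).edges)
        assert total_edges / n_runs <= 1.0

    def test_star_hub_recovered(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            h = rng.standard_normal(1000)
            data = {"H": h}
            want = set()
            for i in range(4):
                data[f"L{i}"] = h + rng.standard_normal(1000)
                want.add(frozenset(("H", f"L{i}")))
            net = infer_network(as_vectors(data), PcParams(seed=seed))
            wins += net.edges == want
        assert wins >= 9

    def test_oracle_equivalence_partial_correlation(self):
        """Skeleton matches an exhaustive analytic partial-correlation PC oracle."""

        def oracle_skeleton(data: dict, alpha=0.01):
            names = list(data)
            n = len(next(iter(data.values())))
            crit = stats.norm.ppf(1 - alpha / 2)

            def indep(x, y, zs):
                if not zs:
                    r = stats.pearsonr(data[x], data[y])[0]
                else:
                    zc = np.column_stack(
                        [np.ones(n)] + [data[w] for w in zs]
                    )
                    rx = data[x] - zc @ np.linalg.lstsq(zc, data[x], rcond=None)[0]
                    ry = data[y] - zc @ np.linalg.lstsq(zc, data[y], rcond=None)[0]
                    r = stats.pearsonr(rx, ry)[0]
                zstat = abs(np.arctanh(r)) * np.sqrt(n - 3 - len(zs))
                return zstat < crit

            edges = {
                frozenset((a, b))
                for i, a in enumerate(names)
                for b in names[i + 1:]
                if not indep(a, b, [])
            }
            adj = {a: {b for e in edges for b in e if a in e and b != a}
                   for a in names}
            keep = set()
            for e in edges:
                a, b = sorted(e)
                common = adj[a] & adj[b]
                if all(not indep(a, b, [k]) for k in common):
                    keep.add(e)
            return keep

        matches = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(800)
            b = a + rng.standard_normal(800)
            c = b + rng.standard_normal(800)
            d = rng.standard_normal(800)
            data = {"A": a, "B": b, "C": c, "D": d}
            got = infer_network(
                as_vectors(data), PcParams(seed=seed, mi_floor_bits=0.0)
            ).edges
            matches += got == oracle_skeleton(data)
        assert matches >= 18

    def test_edge_seed_stable_and_symmetric(self):
        assert edge_seed(3, "a", "b") == edge_seed(3, "b", "a")
        assert edge_seed(3, "a", "b") != edge_seed(4, "a", "b")
        assert edge_seed(3, "a", "b") != edge_seed(3, "a", "c")

    def test_edge_writer_roundtrip(self, rng, tmp_path):
        x = rng.standard_normal(300)
        y = x + 0.3 * rng.standard_normal(300)
        net = infer_network(as_vectors({"x": x, "y": y}), PcParams(seed=0))
        path = tmp_path / "edges.tsv"
        write_edges(net, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "node_a", "node_b", "mi_bits", "normalized_mi", "p_value"
        ]
        assert len(lines) == 1 + len(net.edges)
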