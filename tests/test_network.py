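"""Knowledge-graph construction: normalization, deciles, filters, summary."""



import networkx as nx
import numpy as np
import pytest

from surname_affinity import network
from surname_affinity.errors import DataIntegrityError, DegenerateInputError, EmptyResultError, ParameterError
from surname_affinity.network import (
    FilterParams, PairCount, assign_deciles, build_kg, collapsed_graph,
    count_occurrences, count_pairs, kcore_prune, mateos_filter,
    modularity_score, normalize_ses, remove_rare, summarize,
)
from surname_affinity.synthetic import IndividualRecord


def rec(p, m, ses=0.0, block="B1"):
    return IndividualRecord(paternal=p, maternal=m, ses_raw=ses, block=block)


class TestNormalizeSes:
    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_ses([5, 5, 5])

    @pytest.mark.parametrize("values,expected", [
        ([0, 10], [0.0, 100.0]),
        ([2, 4, 8], [0.0, 100.0 / 3.0, 100.0]),
    ])
    def test_minmax_formula(self, values, expected):
        assert np.allclose(normalize_ses(values).normalized, expected)

    def test_order_preserving(self, rng):
        x = rng.normal(size=50)
        z = normalize_ses(x).normalized
        assert np.array_equal(np.argsort(x), np.argsort(z))


class TestAssignDeciles:
    def test_even_split_of_20_distinct_values(self):
        d = assign_deciles(np.arange(20.0))
        assert np.array_equal(np.bincount(d, minlength=11)[1:], [2] * 10)

    def test_all_identical_go_to_lowest_decile(self):
        assert np.array_equal(assign_deciles([7.0] * 13), [1] * 13)

    def test_uniform_100_values_balanced(self, rng):
        d = assign_deciles(rng.random(100))
        assert np.array_equal(np.bincount(d, minlength=11)[1:], [10] * 10)

    def test_ties_share_lower_decile(self):
        # two tied values straddling a decile boundary land together
        values = [1.0, 1.0] + list(range(2, 20))
        d = assign_deciles(values)
        assert d[0] == d[1] == 1


class TestCountPairs:
    def test_singleton(self):
        pairs = count_pairs([rec("A", "B")], [3])
        assert len(pairs) == 1
        assert pairs[0].key == ("A", "B")
        assert pairs[0].per_decile.tolist() == [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_order_irrelevance(self):
        pairs = count_pairs([rec("A", "B"), rec("B", "A")], [3, 7])
        assert len(pairs) == 1
        assert pairs[0].total == 2
        assert pairs[0].per_decile[2] == 1 and pairs[0].per_decile[6] == 1

    def test_self_pairs_skipped(self):
        assert count_pairs([rec("A", "A")], [1]) == []

    def test_matches_brute_force_tally(self, rng):
        names = [f"S{i}" for i in range(12)]
        records = [rec(*rng.choice(names, size=2, replace=False)) for _ in range(100)]
        deciles = rng.integers(1, 11, size=100)
        pairs = {p.key: p.per_decile.copy() for p in count_pairs(records, deciles)}
        # independent tally with frozenset keys
        expected = {}
        for r, d in zip(records, deciles):
            k = frozenset((r.paternal, r.maternal))
            expected.setdefault(k, np.zeros(10, int))[d - 1] += 1
        assert len(pairs) == len(expected)
        for key, vec in pairs.items():
            assert np.array_equal(vec, expected[frozenset(key)])

    def test_count_conservation(self, small_records):
        deciles = assign_deciles([r.ses_raw for r in small_records])
        pairs = count_pairs(small_records, deciles)
        n_distinct = sum(1 for r in small_records if r.paternal != r.maternal)
        assert sum(p.total for p in pairs) == n_distinct


def make_pair(s1, s2, total, decile=1):
    vec = np.zeros(10, int)
    vec[decile - 1] = total
    return PairCount(s1=s1, s2=s2, per_decile=vec)


class TestMateosFilter:
    def test_boundary_kept(self):
        # threshold 20*50*20/1000 = 20; equality keeps the pair
        pairs = [make_pair("A", "B", 20)]
        occ = {"A": 50, "B": 20}
        assert mateos_filter(pairs, occ, N=1000, k_security=20) == pairs

    def test_below_threshold_removed(self):
        pairs = [make_pair("A", "B", 19)]
        occ = {"A": 50, "B": 20}
        assert mateos_filter(pairs, occ, N=1000, k_security=20) == []

    def test_missing_occurrence_raises(self):
        with pytest.raises(DataIntegrityError):
            mateos_filter([make_pair("A", "B", 5)], {"A": 50}, N=100, k_security=2)

    def test_nesting_in_k(self, small_records):
        deciles = assign_deciles([r.ses_raw for r in small_records])
        pairs = count_pairs(small_records, deciles)
        occ = count_occurrences(small_records)
        N = len(small_records)
        survivors = {}
        for k in (10, 20, 30):
            kept = mateos_filter(pairs, occ, N, k)
            # brute-force re-check of the rule itself
            assert {p.key for p in kept} == {
                p.key for p in pairs
                if p.total >= k * occ[p.s1] * occ[p.s2] / N
            }
            survivors[k] = {p.key for p in kept}
        assert survivors[30] <= survivors[20] <= survivors[10]


class TestRemoveRare:
    def test_rare_surname_pairs_removed(self):
        pairs = [make_pair("A", "B", 3), make_pair("B", "C", 4)]
        occ = {"A": 19, "B": 100, "C": 25}
        kept = remove_rare(pairs, occ, min_occurrence=20)
        assert [p.key for p in kept] == [("B", "C")]

    def test_vacuous_threshold_is_identity(self):
        pairs = [make_pair("A", "B", 1)]
        assert remove_rare(pairs, {"A": 1, "B": 1}, min_occurrence=1) == pairs

    def test_monotone_in_min_occurrence(self, small_records):
        deciles = assign_deciles([r.ses_raw for r in small_records])
        pairs = count_pairs(small_records, deciles)
        occ = count_occurrences(small_records)
        sets = [
            {p.key for p in remove_rare(pairs, occ, m)} for m in (1, 5, 20)
        ]
        assert sets[2] <= sets[1] <= sets[0]


def brute_force_kcore(edges, k):
    """Iterated removal of low-degree nodes until stable."""
    edges = set(edges)
    while True:
        deg = {}
        for a, b in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        drop = {n for n, d in deg.items() if d < k}
        if not drop:
            return edges
        edges = {(a, b) for a, b in edges if a not in drop and b not in drop}


class TestKcorePrune:
    def test_triangle_survives(self):
        pairs = [make_pair("A", "B", 1), make_pair("B", "C", 1), make_pair("A", "C", 1)]
        assert kcore_prune(pairs, 2) == pairs

    def test_path_cascades_to_empty(self):
        pairs = [make_pair("A", "B", 1), make_pair("B", "C", 1)]
        assert kcore_prune(pairs, 2) == []

    def test_matches_peeling_oracle(self, rng):
        nodes = [f"n{i}" for i in range(50)]
        edges = {tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(80)}
        pairs = [make_pair(a, b, 1) for a, b in sorted(edges)]
        kept = {p.key for p in kcore_prune(pairs, 2)}
        assert kept == brute_force_kcore(edges, 2)

    def test_idempotent_and_min_degree(self, rng):
        nodes = [f"n{i}" for i in range(40)]
        edges = {tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(70)}
        pairs = [make_pair(a, b, 1) for a, b in sorted(edges)]
        once = kcore_prune(pairs, 3)
        assert kcore_prune(once, 3) == once
        if once:
            degs = dict(collapsed_graph(once).degree)
            assert min(degs.values()) >= 3


class TestBuildKG:
    def test_triplet_expansion_and_weights(self):
        # pair {A,B} borne by three individuals in two deciles; padding
        # individuals position the decile boundaries
        records = [rec("A", "B", ses=1.0), rec("A", "B", ses=1.0), rec("A", "B", ses=50.0)]
        records += [rec("C", "D", ses=float(v)) for v in range(2, 12)]
        records += [rec("C", "E", ses=100.0), rec("D", "E", ses=100.0),
                    rec("C", "D", ses=100.0)]
        kg = build_kg(records, FilterParams(k_security=1.0001, min_occurrence=1, kcore_k=0))
        deciles = assign_deciles(normalize_ses([r.ses_raw for r in records]).normalized)
        d_low, d_mid = deciles[0], deciles[2]
        assert kg.triplets[("A", f"d{d_low}", "B")] == 2
        assert kg.triplets[("B", f"d{d_low}", "A")] == 2
        assert kg.triplets[("A", f"d{d_mid}", "B")] == 1

    def test_pipeline_equals_manual_composition(self, small_records, small_filter, small_kg):
        ses = normalize_ses([r.ses_raw for r in small_records])
        deciles = assign_deciles(ses.normalized)
        pairs = count_pairs(small_records, deciles)
        occ = count_occurrences(small_records)
        pairs = mateos_filter(pairs, occ, len(small_records), small_filter.k_security)
        pairs = remove_rare(pairs, occ, small_filter.min_occurrence)
        pairs = kcore_prune(pairs, small_filter.kcore_k)
        expected = {}
        for p in pairs:
            for d in range(10):
                if p.per_decile[d] > 0:
                    expected[(p.s1, f"d{d+1}", p.s2)] = int(p.per_decile[d])
                    expected[(p.s2, f"d{d+1}", p.s1)] = int(p.per_decile[d])
        assert small_kg.triplets == expected

    def test_mirror_closure_and_no_self_loops(self, small_kg):
        for (h, r, t), w in small_kg.triplets.items():
            assert h != t
            assert small_kg.triplets[(t, r, h)] == w

    def test_empty_result_carries_diagnostics(self):
        records = [rec("A", "B", ses=float(i)) for i in range(10)]
        with pytest.raises(EmptyResultError) as exc:
            build_kg(records, FilterParams(k_security=500.0, min_occurrence=1, kcore_k=0))
        assert exc.value.diagnostics["pairs_counted"] >= 1


class TestSummarize:
    def test_triangle_single_decile(self):
        kg = network.SurnameKG.from_triplets(
            [("A", "d1", "B"), ("B", "d1", "C"), ("A", "d1", "C")]
        )
        s = summarize(kg)
        assert (s["n_nodes"], s["n_edges"]) == (3, 3)
        assert s["average_degree"] == pytest.approx(2.0)

    def test_decile_fractions_match_direct_tally(self, small_kg):
        s = summarize(small_kg)
        edges = {(min(h, t), max(h, t), r) for (h, r, t) in small_kg.triplets}
        for rel in network.RELATIONS:
            direct = sum(1 for e in edges if e[2] == rel) / len(edges)
            assert s["per_decile_edge_fraction"][rel] == pytest.approx(direct)
        assert sum(s["per_decile_edge_fraction"].values()) == pytest.approx(1.0)


def brute_force_modularity(g, partition):
    m = g.number_of_edges()
    A = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    nodes = sorted(g.nodes)
    deg = A.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if partition[u] == partition[v]:
                q += A[i, j] - deg[i] * deg[j] / (2 * m)
    return q / (2 * m)


class TestModularity:
    def test_single_community_is_zero(self):
        pairs = [make_pair("A", "B", 1), make_pair("B", "C", 1)]
        assert modularity_score(pairs, {"A": 0, "B": 0, "C": 0}) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        pairs = [make_pair(a, b, 1) for a, b in
                 [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")]]
        partition = {"A": 0, "B": 0, "C": 0, "X": 1, "Y": 1, "Z": 1}
        assert modularity_score(pairs, partition) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=7)
        g.remove_nodes_from(list(nx.isolates(g)))
        partition = {n: int(rng.integers(0, 3)) for n in g.nodes}
        assert modularity_score(g, partition) == pytest.approx(
            brute_force_modularity(g, partition)
        )

    def test_missing_node_raises(self):
        pairs = [make_pair("A", "B", 1)]
        with pytest.raises(DataIntegrityError):
            modularity_score(pairs, {"A": 0})


class TestCommunityStructure:
    def test_louvain_beats_degree_preserving_rewires(self, small_kg):
        """Endogamous registries yield community structure well above a
        degree-preserving null."""
        g = network.collapsed_graph_from_kg(small_kg)
        part = network.louvain_partition(g, seed=0)
        q_obs = modularity_score(g, part)
        for i in range(5):
            h = g.copy()
            nx.double_edge_swap(h, nswap=2 * h.number_of_edges(),
                                max_tries=10**6, seed=100 + i)
            q_null = modularity_score(h, network.louvain_partition(h, seed=0))
            assert q_null < q_obs
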