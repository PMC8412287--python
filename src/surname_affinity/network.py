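"""Build the decile-stratified surname affinity knowledge graph.

Pipeline, applied in this order to a registry table:

1. min-max normalize the block-level socioeconomic scores to 0-100;
2. assign each individual to an empirical income decile (rank-based,
   ties share the lower decile);
3. count, per unordered surname pair, the individuals bearing the pair,
   broken down by the bearer's decile (order of paternal/maternal is
   irrelevant; individuals whose two surnames coincide are skipped);
4. drop pairs whose total count falls below the isonymy significance
   threshold k * n_s1 * n_s2 / N (k times the expected co-occurrence
   under random surname pairing) — strictly-below is removed, equality
   is kept;
5. drop pairs touching rare surnames (fewer than ``min_occurrence``
   appearances in either name slot);
6. prune to the k-core of the collapsed simple graph (one edge per
   surviving surname pair regardless of decile), keeping the triangles
   that form the atomic affinity units;
7. expand each surviving pair into mirrored triplets <s1, d, s2> /
   <s2, d, s1> for every decile with a positive count.

Degree conventions: the k-core and the modularity run on the collapsed
simple graph; the summary's edge count and average degree count each
(pair, decile) combination once, so ``average degree = 2 E / N`` on
those edges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .errors import DataIntegrityError, DegenerateInputError, EmptyResultError, ParameterError
from .synthetic import IndividualRecord

__all__ = [
    "SesVector",
    "PairCount",
    "FilterParams",
    "SurnameKG",
    "RELATIONS",
    "normalize_ses",
    "assign_deciles",
    "count_pairs",
    "count_occurrences",
    "mateos_filter",
    "remove_rare",
    "kcore_prune",
    "build_kg",
    "summarize",
    "modularity_score",
    "collapsed_graph",
    "collapsed_graph_from_kg",
    "louvain_partition",
]

RELATIONS = tuple(f"d{i}" for i in range(1, 11))


@dataclass
class SesVector:
    """Raw and 0-100 min-max normalized socioeconomic scores."""

    values: np.ndarray
    normalized: np.ndarray


@dataclass
class PairCount:
    """Counts for one unordered surname pair, stored with s1 < s2."""

    s1: str
    s2: str
    per_decile: np.ndarray  # 10 non-negative ints, index 0 = decile 1

    def __post_init__(self):
        if self.s1 == self.s2:
            raise ParameterError("self-pairs carry no affinity semantics")
        if self.s1 > self.s2:
            self.s1, self.s2 = self.s2, self.s1
        self.per_decile = np.asarray(self.per_decile, dtype=int)
        if self.per_decile.shape != (10,) or np.any(self.per_decile < 0):
            raise ParameterError("per_decile must be 10 non-negative counts")

    @property
    def total(self) -> int:
        return int(self.per_decile.sum())

    @property
    def key(self) -> tuple[str, str]:
        return (self.s1, self.s2)


@dataclass(frozen=True)
class FilterParams:
    """Pruning thresholds: significance parameter k (> 1), minimum
    surname occurrence (default 20) and k-core order (default 2)."""

    k_security: float = 20.0
    min_occurrence: int = 20
    kcore_k: int = 2

    def __post_init__(self):
        if self.k_security <= 1:
            raise ParameterError("k_security must exceed 1")
        if self.min_occurrence < 1:
            raise ParameterError("min_occurrence must be >= 1")
        if self.kcore_k < 0:
            raise ParameterError("kcore_k must be >= 0")


@dataclass
class SurnameKG:
    """Multi-relational surname graph: mirrored weighted triplets over
    decile relations d1..d10, plus the occurrence counts and population
    size the filters were computed from."""

    entities: list[str]
    relations: tuple[str, ...]
    triplets: dict  # (head, relation, tail) -> weight, closed under h<->t swap
    occurrence: dict  # surname -> individual count
    n_individuals: int

    def neighbors(self, node: str, relation: str | None = None) -> set[str]:
        try:
            adj = self._adj
        except AttributeError:
            adj = self._adj = {}
            for (h, r, t) in self.triplets:
                adj.setdefault((h, r), set()).add(t)
        if relation is not None:
            return set(adj.get((node, relation), ()))
        out: set[str] = set()
        for r in self.relations:
            out |= adj.get((node, r), set())
        return out

    def triplet_list(self) -> list[tuple[str, str, str]]:
        return sorted(self.triplets)

    def undirected_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((h, t))) for (h, r, t) in self.triplets}

    @classmethod
    def from_triplets(cls, triplets, weights=None, occurrence=None, n_individuals=0):
        """Rebuild a KG from a triplet list (mirrors added if absent)."""
        store = {}
        for i, (h, r, t) in enumerate(triplets):
            w = 1 if weights is None else weights[i]
            store[(h, r, t)] = w
            store.setdefault((t, r, h), w)
        entities = sorted({h for (h, _, _) in store} | {t for (_, _, t) in store})
        return cls(
            entities=entities,
            relations=RELATIONS,
            triplets=store,
            occurrence=occurrence or {},
            n_individuals=n_individuals,
        )


# ---------------------------------------------------------------------------
# normalization and decile assignment
# ---------------------------------------------------------------------------

def normalize_ses(values) -> SesVector:
    """Min-max normalize scores to the 0-100 range:
    z_i = 100 * (x_i - min x) / (max x - min x). Order-preserving.

    Constant input makes the denominator vanish and is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError("need at least two score values")
    if not np.all(np.isfinite(x)):
        raise ParameterError("scores must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("constant scores: min-max range is zero")
    # divide before scaling so the endpoints map to exactly 0 and 100
    return SesVector(values=x, normalized=100.0 * ((x - lo) / (hi - lo)))


def assign_deciles(normalized) -> np.ndarray:
    """Empirical decile labels in 1..10 by rank.

    Individuals are ranked; the population splits at the 10%, 20%, ...
    90% rank boundaries. Tied values share the decile of their lowest
    rank position (the lower decile), so identical inputs always land in
    the same decile.
    """
    z = np.asarray(normalized, dtype=float)
    if len(z) == 0:
        raise ParameterError("empty input")
    n = len(z)
    min_rank = rankdata(z, method="min")  # 1-based lowest rank among ties
    deciles = ((min_rank - 1) * 10 // n + 1).astype(int)
    return np.minimum(deciles, 10)


# ---------------------------------------------------------------------------
# pair counting and filtering
# ---------------------------------------------------------------------------

def count_pairs(records: list[IndividualRecord], deciles) -> list[PairCount]:
    """Tally unordered surname pairs with per-decile counts.

    The paternal/maternal order is irrelevant; individuals with identical
    paternal and maternal surname are skipped.
    """
    deciles = np.asarray(deciles, dtype=int)
    if len(records) != len(deciles):
        raise ParameterError("records and decile labels must align")
    acc: dict[tuple[str, str], np.ndarray] = {}
    for rec, d in zip(records, deciles):
        if rec.paternal == rec.maternal:
            continue
        key = (rec.paternal, rec.maternal) if rec.paternal < rec.maternal \
            else (rec.maternal, rec.paternal)
        if key not in acc:
            acc[key] = np.zeros(10, dtype=int)
        acc[key][d - 1] += 1
    return [PairCount(s1=k[0], s2=k[1], per_decile=v) for k, v in sorted(acc.items())]


def count_occurrences(records: list[IndividualRecord]) -> Counter:
    """Number of appearances of each surname in either name slot."""
    c: Counter = Counter()
    for rec in records:
        c[rec.paternal] += 1
        c[rec.maternal] += 1
    return c


def mateos_filter(pairs, occurrence, N: int, k_security: float) -> list[PairCount]:
    """Keep a pair iff its count reaches k * n_s1 * n_s2 / N, i.e. k
    times the expected co-occurrence under random pairing; counts
    strictly below the threshold are removed (equality keeps the pair).
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    kept = []
    for p in pairs:
        try:
            n1, n2 = occurrence[p.s1], occurrence[p.s2]
        except KeyError as exc:
            raise DataIntegrityError(f"no occurrence count for surname {exc.args[0]!r}") from exc
        if p.total >= k_security * n1 * n2 / N:
            kept.append(p)
    return kept


def remove_rare(pairs, occurrence, min_occurrence: int = 20) -> list[PairCount]:
    """Drop every pair touching a surname seen fewer than
    ``min_occurrence`` times."""
    kept = []
    for p in pairs:
        try:
            n1, n2 = occurrence[p.s1], occurrence[p.s2]
        except KeyError as exc:
            raise DataIntegrityError(f"no occurrence count for surname {exc.args[0]!r}") from exc
        if n1 >= min_occurrence and n2 >= min_occurrence:
            kept.append(p)
    return kept


def collapsed_graph(pairs) -> nx.Graph:
    """Simple undirected graph with one edge per surname pair, decile
    relations collapsed."""
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.s1, p.s2)
    return g


def collapsed_graph_from_kg(kg: "SurnameKG") -> nx.Graph:
    """Collapsed simple graph of a built knowledge graph."""
    g = nx.Graph()
    g.add_nodes_from(kg.entities)
    g.add_edges_from(kg.undirected_pairs())
    return g


def kcore_prune(pairs, kcore_k: int = 2) -> list[PairCount]:
    """Restrict to pairs whose both endpoints survive in the k-core of
    the collapsed graph (iterated removal of nodes with degree < k until
    a fixpoint; idempotent)."""
    if kcore_k <= 0:
        return list(pairs)
    g = collapsed_graph(pairs)
    core = nx.k_core(g, k=kcore_k)
    keep = set(core.nodes)
    return [p for p in pairs if p.s1 in keep and p.s2 in keep]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_kg(records: list[IndividualRecord], params: FilterParams) -> SurnameKG:
    """Run the full construction pipeline on a registry table."""
    if not records:
        raise ParameterError("empty registry")
    ses = normalize_ses([r.ses_raw for r in records])
    deciles = assign_deciles(ses.normalized)
    pairs = count_pairs(records, deciles)
    occurrence = count_occurrences(records)
    N = len(records)

    diag = {"pairs_counted": len(pairs)}
    pairs = mateos_filter(pairs, occurrence, N, params.k_security)
    diag["after_significance_filter"] = len(pairs)
    pairs = remove_rare(pairs, occurrence, params.min_occurrence)
    diag["after_rare_removal"] = len(pairs)
    pairs = kcore_prune(pairs, params.kcore_k)
    diag["after_kcore"] = len(pairs)
    if not pairs:
        raise EmptyResultError("all surname pairs were filtered out", diag)

    triplets: dict = {}
    for p in pairs:
        for d in range(10):
            w = int(p.per_decile[d])
            if w > 0:
                rel = RELATIONS[d]
                triplets[(p.s1, rel, p.s2)] = w
                triplets[(p.s2, rel, p.s1)] = w
    entities = sorted({h for (h, _, _) in triplets})
    return SurnameKG(
        entities=entities,
        relations=RELATIONS,
        triplets=triplets,
        occurrence=dict(occurrence),
        n_individuals=N,
    )


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N of an undirected graph."""
    if n_nodes <= 0:
        raise ParameterError("need at least one node")
    return 2.0 * n_edges / n_nodes


def summarize(kg: SurnameKG) -> dict:
    """Headline statistics of a knowledge graph.

    An "edge" is a distinct (surname pair, decile) combination counted
    once (mirrored triplets collapse), so the average degree is
    2 * edges / nodes. The degree histogram counts, per node, its
    incident (neighbor, decile) combinations.
    """
    if not kg.triplets:
        raise ParameterError("empty knowledge graph")
    edges = {(min(h, t), max(h, t), r) for (h, r, t) in kg.triplets}
    n_nodes = len(kg.entities)
    n_edges = len(edges)
    degree: Counter = Counter()
    decile_counts = Counter()
    for (a, b, r) in edges:
        degree[a] += 1
        degree[b] += 1
        decile_counts[r] += 1
    hist = Counter(degree.values())
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "average_degree": average_degree(n_nodes, n_edges),
        "degree_histogram": dict(sorted(hist.items())),
        "per_decile_edge_fraction": {
            r: decile_counts.get(r, 0) / n_edges for r in RELATIONS
        },
    }


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity_score(pairs, partition: dict) -> float:
    """Newman-Girvan modularity of a node partition on the collapsed
    unweighted graph:

        Q = sum_c [ e_c / m - (d_c / 2m)^2 ]

    with e_c the number of intra-community edges, d_c the total degree of
    community c, and m the number of edges. Q lies in [-1/2, 1).
    """
    g = pairs if isinstance(pairs, nx.Graph) else collapsed_graph(pairs)
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise DataIntegrityError(f"partition misses {len(missing)} nodes, e.g. {missing[0]!r}")
    m = g.number_of_edges()
    if m == 0:
        raise ParameterError("graph has no edges")
    intra: Counter = Counter()
    deg: Counter = Counter()
    for u, v in g.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] += 1
        deg[partition[u]] += 1
        deg[partition[v]] += 1
    return float(sum(
        intra.get(c, 0) / m - (deg[c] / (2.0 * m)) ** 2
        for c in set(partition[n] for n in g.nodes)
    ))


def louvain_partition(pairs, seed: int = 0) -> dict:
    """Community detection via the Louvain algorithm (library-backed);
    returns a node -> community-id mapping."""
    g = pairs if isinstance(pairs, nx.Graph) else collapsed_graph(pairs)
    communities = nx.community.louvain_communities(g, seed=seed)
    return {n: i for i, comm in enumerate(communities) for n in comm}
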