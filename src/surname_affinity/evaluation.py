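"""Ranking-based evaluation of link prediction.

Each held-out triplet <h, r, t> is scored in both directions: the true
tail is ranked among all candidate tails of the query <h, r, ?>, and the
true head among all candidates of <?, r, t> (via the reciprocal
relation). Ties are broken pessimistically — a candidate with the same
score as the true entity counts as ranked above it — to avoid optimistic
bias. The *filtered* protocol (default) removes other known-true
candidates from the comparison; *raw* keeps them.

Headline metrics pool head and tail ranks: hits@n is the fraction of
ranks <= n and MRR the mean reciprocal rank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .tucker import TuckerModel, _inverse_label, score_all_tails

__all__ = [
    "Split",
    "RankingResult",
    "split",
    "rank_triplet",
    "rank_all",
    "aggregate",
    "per_decile_report",
    "random_baseline",
]


@dataclass
class Split:
    """Disjoint train/valid/test triplet sets (union = input)."""

    train: list[tuple]
    valid: list[tuple]
    test: list[tuple]
    removed_mirrors: list[tuple]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.valid), len(self.test))


@dataclass
class RankingResult:
    """Pessimistic ranks of the true tail and head for one triplet."""

    triplet: tuple
    tail_rank: int
    head_rank: int
    protocol: str  # "raw" | "filtered"

    @property
    def relation(self):
        return self.triplet[1]


def split(
    triplets,
    n_valid: int,
    n_test: int,
    seed: int = 0,
    keep_mirrors: bool = False,
) -> Split:
    """Sample validation and test triplets uniformly without replacement.

    Because the undirected graph stores both orientations of every edge,
    the mirror of a held-out triplet sitting in train leaks the answer;
    by default those mirrors are removed from train (``keep_mirrors=True``
    retains them).
    """
    triplets = sorted(triplets)
    if n_valid < 0 or n_test < 0:
        raise ParameterError("split sizes must be non-negative")
    if n_valid + n_test > 0 and n_valid + n_test >= len(triplets):
        raise ParameterError("held-out sizes must leave a non-empty training set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triplets))
    held = [triplets[i] for i in order[: n_valid + n_test]]
    valid, test = held[:n_valid], held[n_valid:]
    held_set = set(held)
    train = [t for t in triplets if t not in held_set]

    removed = []
    if not keep_mirrors:
        mirrors = {(t, r, h) for (h, r, t) in held}
        kept = []
        for trip in train:
            if trip in mirrors:
                removed.append(trip)
            else:
                kept.append(trip)
        train = kept
    return Split(train=train, valid=valid, test=test, removed_mirrors=removed)


def _pessimistic_rank(scores: np.ndarray, true_idx: int, excluded) -> int:
    """1 + number of non-excluded candidates scoring >= the true entity
    (the true entity itself is never excluded and ties count against it)."""
    mask = np.ones(len(scores), dtype=bool)
    if excluded:
        mask[list(excluded)] = False
    mask[true_idx] = False
    return 1 + int(np.sum(scores[mask] >= scores[true_idx]))


def _known_index(model, known_triplets):
    """(h,r) -> tail index set and (t,r) -> head index set, for the
    filtered protocol."""
    tails: dict = {}
    heads: dict = {}
    for (h, r, t) in known_triplets:
        tails.setdefault((h, r), set()).add(model.entity_index(t))
        heads.setdefault((t, r), set()).add(model.entity_index(h))
    return tails, heads


def _rank_one(model, triplet, tails, heads, protocol) -> RankingResult:
    h, r, t = triplet
    hi, ti = model.entity_index(h), model.entity_index(t)
    ri = model.relation_index(r)
    ri_inv = model.relation_index(_inverse_label(r))

    tail_excl = set()
    head_excl = set()
    if protocol == "filtered":
        tail_excl = tails.get((h, r), set()) - {ti}
        head_excl = heads.get((t, r), set()) - {hi}

    tail_scores = score_all_tails(hi, ri, model).scores
    head_scores = score_all_tails(ti, ri_inv, model).scores
    return RankingResult(
        triplet=triplet,
        tail_rank=_pessimistic_rank(tail_scores, ti, tail_excl),
        head_rank=_pessimistic_rank(head_scores, hi, head_excl),
        protocol=protocol,
    )


def rank_triplet(
    model: TuckerModel,
    triplet: tuple,
    known_triplets,
    protocol: str = "filtered",
) -> RankingResult:
    """Rank the true tail and head of one evaluation triplet.

    ``known_triplets`` is the set of triplets treated as known-true (in
    original orientation, typically train + valid + test); under the
    filtered protocol those candidates are excluded from the comparison.
    """
    if protocol not in ("raw", "filtered"):
        raise ParameterError(f"unknown protocol {protocol!r}")
    tails, heads = _known_index(model, known_triplets)
    return _rank_one(model, triplet, tails, heads, protocol)


def rank_all(model, triplets, known_triplets, protocol="filtered") -> list[RankingResult]:
    """Rank a batch of evaluation triplets against a shared known set."""
    if protocol not in ("raw", "filtered"):
        raise ParameterError(f"unknown protocol {protocol!r}")
    tails, heads = _known_index(model, known_triplets)
    return [_rank_one(model, trip, tails, heads, protocol) for trip in triplets]


def _pooled_ranks(results) -> np.ndarray:
    return np.array([x for res in results for x in (res.tail_rank, res.head_rank)])


def aggregate(results) -> dict:
    """Pooled metrics: hits@{1,3,10} and MRR over head+tail ranks, plus
    per-side MRR for diagnostics."""
    if not results:
        raise ParameterError("no ranking results to aggregate")
    ranks = _pooled_ranks(results)
    tail = np.array([r.tail_rank for r in results])
    head = np.array([r.head_rank for r in results])
    return {
        "hits@1": float(np.mean(ranks <= 1)),
        "hits@3": float(np.mean(ranks <= 3)),
        "hits@10": float(np.mean(ranks <= 10)),
        "mrr": float(np.mean(1.0 / ranks)),
        "mrr_tail": float(np.mean(1.0 / tail)),
        "mrr_head": float(np.mean(1.0 / head)),
        "n": len(results),
        "protocol": results[0].protocol,
    }


def per_decile_report(results) -> dict:
    """Metrics within each decile relation plus the pooled histogram of
    hit counts by rank position 1..10."""
    if not results:
        raise ParameterError("no ranking results")
    by_rel: dict = {}
    for res in results:
        by_rel.setdefault(res.relation, []).append(res)
    table = {rel: aggregate(group) for rel, group in sorted(by_rel.items())}
    hist = Counter(int(x) for x in _pooled_ranks(results) if x <= 10)
    return {
        "per_decile": table,
        "hits_by_rank": {i: hist.get(i, 0) for i in range(1, 11)},
    }


def random_baseline(n_entities: int, degree: int = 1) -> dict:
    """Expected metrics when candidates are ranked by a uniformly random
    permutation.

    With the filtered protocol, a query with ``degree`` known-true
    candidates ranks the evaluated entity among
    m = n_entities - degree + 1 contenders, uniformly, so
    E[hits@n] = min(1, n/m) and E[MRR] = H_m / m (harmonic number).
    """
    if not n_entities > degree >= 1:
        raise ParameterError("need n_entities > degree >= 1")
    m = n_entities - degree + 1
    harm = float(np.sum(1.0 / np.arange(1, m + 1)))
    return {
        "hits@1": min(1.0, 1.0 / m),
        "hits@3": min(1.0, 3.0 / m),
        "hits@10": min(1.0, 10.0 / m),
        "mrr": harm / m,
        "n_candidates": m,
    }
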