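"""Tucker-decomposition link prediction for multi-relational graphs.

The model scores a triplet <h, r, t> by contracting a shared core tensor
``W`` (d_e x d_r x d_e) against the head embedding, the relation embedding
and the tail embedding:

    phi(h, r, t) = W x1 e_h x2 w_r x3 e_t
                 = sum_{p,q,s} W[p,q,s] * E[h,p] * R[r,q] * E[t,s]

A logistic sigmoid maps the score to the probability that the triplet is
observed. Training uses the reciprocal-relation trick (head prediction is
reduced to tail prediction under an auxiliary relation ``r_inv``) and 1:N
scoring: each (head, relation) query is scored against every candidate
tail simultaneously, with a multi-label Bernoulli log-likelihood loss.

Everything is plain numpy: the forward pass, the analytically derived
gradients and the Adam optimizer are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, TrainingError

__all__ = [
    "TuckerModel",
    "TrainConfig",
    "ScoreVector",
    "nmode_product",
    "tucker_score",
    "score_all_tails",
    "bce_loss",
    "add_reciprocals",
    "train",
    "relation_matrix",
    "save_model",
    "load_model",
]

_EPS = 1e-12  # probability clamp for the Bernoulli loss


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TuckerModel:
    """Entity embeddings ``E`` (n_e x d_e), relation embeddings ``R``
    (n_r x d_r) and core tensor ``W`` (d_e x d_r x d_e).

    ``entities`` / ``relations`` hold the label vocabularies in index
    order; they are optional for purely numeric experiments.
    """

    E: np.ndarray
    R: np.ndarray
    W: np.ndarray
    entities: list[str] | None = None
    relations: list[str] | None = None

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        n_e, d_e = self.E.shape
        n_r, d_r = self.R.shape
        if self.W.shape != (d_e, d_r, d_e):
            raise ParameterError(
                f"core tensor shape {self.W.shape} inconsistent with "
                f"embedding dims (expected {(d_e, d_r, d_e)})"
            )
        for name, arr in (("E", self.E), ("R", self.R), ("W", self.W)):
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"non-finite entries in {name}")
        if self.entities is not None and len(self.entities) != n_e:
            raise ParameterError("entity vocabulary length mismatch")
        if self.relations is not None and len(self.relations) != n_r:
            raise ParameterError("relation vocabulary length mismatch")

    @property
    def n_entities(self) -> int:
        return self.E.shape[0]

    @property
    def n_relations(self) -> int:
        return self.R.shape[0]

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (self.E.shape[0], self.R.shape[0], self.E.shape[1], self.R.shape[1])

    def entity_index(self, label: str) -> int:
        if self.entities is None:
            raise ParameterError("model carries no entity vocabulary")
        try:
            return self._ent_idx[label]
        except AttributeError:
            self._ent_idx = {e: i for i, e in enumerate(self.entities)}
            return self._ent_idx[label]

    def relation_index(self, label: str) -> int:
        if self.relations is None:
            raise ParameterError("model carries no relation vocabulary")
        try:
            return self._rel_idx[label]
        except AttributeError:
            self._rel_idx = {r: i for i, r in enumerate(self.relations)}
            return self._rel_idx[label]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the 1:N training loop.

    Defaults follow the configuration that performed best on the surname
    network: d_e=200, d_r=10, batch size 128, Adam at 0.005 with no
    learning-rate decay, and dropout rates (0.5, 0.2, 0.2) at the three
    sites (entity input, relation-core product, final query vector).
    Label smoothing defaults to 0 (off).
    """

    d_e: int = 200
    d_r: int = 10
    batch_size: int = 128
    learning_rate: float = 0.005
    decay_rate: float = 1.0
    dropouts: tuple[float, float, float] = (0.5, 0.2, 0.2)
    epochs: int = 200
    label_smoothing: float = 0.0
    seed: int = 0
    eval_every: int = 10

    def __post_init__(self):
        if self.d_e < 1 or self.d_r < 1:
            raise ParameterError("embedding dimensions must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ParameterError("batch size must be >=1 and epochs >=0")
        if self.learning_rate <= 0 or self.decay_rate <= 0:
            raise ParameterError("rates must be positive")
        if not all(0.0 <= d < 1.0 for d in self.dropouts):
            raise ParameterError("dropout rates must lie in [0, 1)")
        if self.label_smoothing < 0:
            raise ParameterError("label smoothing must be non-negative")


@dataclass
class ScoreVector:
    """1:N scores of one (head, relation) query against every entity."""

    scores: np.ndarray          # raw multilinear scores (logits)
    probabilities: np.ndarray   # sigmoid(scores), clamped to (0, 1)


# ---------------------------------------------------------------------------
# tensor algebra
# ---------------------------------------------------------------------------

def nmode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Contract ``tensor``'s given mode (1-based) against the second index
    of ``matrix``: (X x_N U)[..., j, ...] = sum_i X[..., i, ...] U[j, i].

    The output extent along ``mode`` equals the matrix row count.
    """
    tensor = np.asarray(tensor, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[None, :]
    if mode < 1 or mode > tensor.ndim:
        raise ParameterError(f"mode {mode} out of range for {tensor.ndim}-way tensor")
    axis = mode - 1
    if matrix.shape[1] != tensor.shape[axis]:
        raise ParameterError(
            f"matrix columns ({matrix.shape[1]}) must equal tensor extent "
            f"along mode {mode} ({tensor.shape[axis]})"
        )
    out = np.tensordot(tensor, matrix, axes=([axis], [1]))
    # tensordot moves the contracted mode to the last axis; restore order
    return np.moveaxis(out, -1, axis)


def tucker_score(h: int, r: int, t: int, model: TuckerModel) -> float:
    """Multilinear score of a single triplet; no dropout at inference."""
    n_e, n_r = model.n_entities, model.n_relations
    if not (0 <= h < n_e and 0 <= t < n_e and 0 <= r < n_r):
        raise IndexError(f"triplet ({h},{r},{t}) out of range ({n_e} entities, {n_r} relations)")
    return float(np.einsum("pqs,p,q,s->", model.W, model.E[h], model.R[r], model.E[t]))


def relation_matrix(model: TuckerModel, r: int) -> np.ndarray:
    """M_r = W x2 w_r, the d_e x d_e bilinear form of relation ``r``;
    satisfies phi(h, r, t) = e_h^T M_r e_t."""
    if not 0 <= r < model.n_relations:
        raise IndexError(f"relation {r} out of range")
    return np.einsum("q,pqs->ps", model.R[r], model.W)


def score_all_tails(
    h: int,
    r: int,
    model: TuckerModel,
    training_mode: bool = False,
    dropouts: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> ScoreVector:
    """Score the query <h, r, ?> against every candidate tail.

    In training mode, inverted dropout is applied at the three sites in
    order: the head entity representation, the relation-core product
    M_r = W x2 w_r, and the final query vector e_h^T M_r (the object that
    is multiplied against all candidate entity embeddings).
    """
    if not (0 <= h < model.n_entities and 0 <= r < model.n_relations):
        raise IndexError("head or relation index out of range")
    e_h = model.E[h]
    m_r = relation_matrix(model, r)
    if training_mode and any(d > 0 for d in dropouts):
        if rng is None:
            rng = np.random.default_rng()
        e_h = _dropout(e_h, dropouts[0], rng)
        m_r = _dropout(m_r, dropouts[1], rng)
        query = _dropout(e_h @ m_r, dropouts[2], rng)
    else:
        query = e_h @ m_r
    scores = model.E @ query
    probs = np.clip(_sigmoid(scores), _EPS, 1.0 - _EPS)
    return ScoreVector(scores=scores, probabilities=probs)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _dropout(x: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted dropout: zero with probability ``rate``, scale survivors."""
    if rate <= 0:
        return x
    mask = rng.random(x.shape) >= rate
    return x * mask / (1.0 - rate)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Bernoulli log-likelihood loss, averaged over candidates:

        L = -(1/n) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]

    Probabilities at exactly 0 or 1 are clamped to [1e-12, 1 - 1e-12].
    """
    p = np.clip(np.asarray(probabilities, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ParameterError("probabilities and labels must have equal length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# reciprocal relations
# ---------------------------------------------------------------------------

def add_reciprocals(
    triplets: list[tuple],
    relations: list | None = None,
) -> tuple[list[tuple], list]:
    """Augment a triplet list with reciprocal facts <t, r_inv, h>.

    Every relation ``r`` gains a distinct reciprocal label ``r_inv`` with
    its own embedding row; the relation vocabulary doubles (originals
    first, then their inverses in the same order). The original triplets
    are recoverable by dropping the ``*_inv`` labels.
    """
    if relations is None:
        seen = {}
        for _, r, _ in triplets:
            seen.setdefault(r, None)
        relations = list(seen)
    inv = {r: _inverse_label(r) for r in relations}
    augmented = list(triplets) + [(t, inv[r], h) for (h, r, t) in triplets]
    return augmented, list(relations) + [inv[r] for r in relations]


def _inverse_label(r):
    return f"{r}_inv" if isinstance(r, str) else ("inv", r)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    """Standard Adam with bias correction, one slot per parameter array."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _init_model(n_e: int, n_r: int, config: TrainConfig,
                entities=None, relations=None) -> TuckerModel:
    # small symmetric random init; scale keeps initial scores near 0 so the
    # sigmoid starts close to 0.5 and gradients are well conditioned
    rng = np.random.default_rng(config.seed)
    E = rng.normal(0.0, 0.1, size=(n_e, config.d_e))
    R = rng.normal(0.0, 0.1, size=(n_r, config.d_r))
    W = rng.uniform(-1.0, 1.0, size=(config.d_e, config.d_r, config.d_e))
    return TuckerModel(E=E, R=R, W=W, entities=entities, relations=relations)


def _forward_backward(model, h_idx, r_idx, Y, dropouts, rng):
    """One 1:N batch: forward with dropout, Bernoulli loss, analytic
    gradients. Returns (loss, dE, dR_rows, dW) where dE is dense and
    dR_rows aligns with r_idx (caller scatters)."""
    E, R, W = model.E, model.R, model.W
    B = len(h_idx)
    n_e = E.shape[0]

    eh = E[h_idx]                                   # (B, d_e)
    keep = [1.0 - d for d in dropouts]
    if dropouts[0] > 0:
        mask0 = (rng.random(eh.shape) >= dropouts[0]) / keep[0]
        eh = eh * mask0
    else:
        mask0 = None
    # M[b] = W x2 w_{r_b}  -> (B, d_e, d_e)
    M = np.einsum("bq,pqs->bps", R[r_idx], W)
    if dropouts[1] > 0:
        mask1 = (rng.random(M.shape) >= dropouts[1]) / keep[1]
        M = M * mask1
    else:
        mask1 = None
    q = np.einsum("bp,bps->bs", eh, M)              # query vectors (B, d_e)
    if dropouts[2] > 0:
        mask2 = (rng.random(q.shape) >= dropouts[2]) / keep[2]
        q = q * mask2
    else:
        mask2 = None
    logits = q @ E.T                                # (B, n_e)
    P = np.clip(_sigmoid(logits), _EPS, 1.0 - _EPS)
    loss = float(-np.mean(Y * np.log(P) + (1 - Y) * np.log(1 - P)))

    # dL/dlogits for the clamp-free sigmoid-BCE composition
    dlogits = (P - Y) / (B * n_e)
    dq = dlogits @ E                                # (B, d_e)
    dE = dlogits.T @ q                              # candidate-side gradient
    if mask2 is not None:
        dq = dq * mask2
    deh = np.einsum("bs,bps->bp", dq, M)
    dM = np.einsum("bp,bs->bps", eh, dq)
    if mask1 is not None:
        dM = dM * mask1
    dR_rows = np.einsum("bps,pqs->bq", dM, W)
    dW = np.einsum("bq,bps->pqs", R[r_idx], dM)
    if mask0 is not None:
        deh = deh * mask0
    np.add.at(dE, h_idx, deh)                       # head-side gradient
    return loss, dE, dR_rows, dW


def train(
    triplets: list[tuple],
    config: TrainConfig,
    valid_triplets: list[tuple] | None = None,
    entities: list | None = None,
    relations: list | None = None,
) -> tuple[TuckerModel, dict]:
    """Fit a Tucker link-prediction model with reciprocal-relation 1:N
    mini-batch training.

    Each batch is a set of (head, relation) queries; the label vector of a
    query marks *all* tails observed for it in the training set
    (multi-label targets). Returns the model with the best validation MRR
    (filtered protocol) when ``valid_triplets`` is given, otherwise the
    final model, plus a log dict with per-epoch losses and validation MRR
    trace. Fully reproducible for a fixed config seed.
    """
    if not triplets:
        raise ParameterError("training requires at least one triplet")
    if entities is None:
        # vocabulary spans train and validation so held-out entities are rankable
        seen = {}
        for h, _, t in list(triplets) + list(valid_triplets or []):
            seen.setdefault(h, None)
            seen.setdefault(t, None)
        entities = list(seen)
    ent_idx = {e: i for i, e in enumerate(entities)}

    if relations is None:
        seen_r = {}
        for _, r, _ in list(triplets) + list(valid_triplets or []):
            seen_r.setdefault(r, None)
        relations = list(seen_r)
    augmented, rel_vocab = add_reciprocals(triplets, relations)
    rel_idx = {r: i for i, r in enumerate(rel_vocab)}
    n_e, n_r = len(entities), len(rel_vocab)

    # group observed tails by (head, relation) query
    tails_by_query: dict[tuple[int, int], list[int]] = {}
    for h, r, t in augmented:
        tails_by_query.setdefault((ent_idx[h], rel_idx[r]), []).append(ent_idx[t])
    queries = sorted(tails_by_query)

    model = _init_model(n_e, n_r, config, entities=entities, relations=rel_vocab)
    log: dict = {"train_loss": [], "valid_mrr": [], "config": config}
    if config.epochs == 0:
        return model, log

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    opt = _Adam([model.E.shape, model.R.shape, model.W.shape], config.learning_rate)
    ls = config.label_smoothing
    best = (-np.inf, None)

    # dense multi-label target rows, built per batch
    for epoch in range(config.epochs):
        order = rng.permutation(len(queries))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(queries), config.batch_size):
            batch = [queries[i] for i in order[start:start + config.batch_size]]
            h_idx = np.array([q[0] for q in batch])
            r_idx = np.array([q[1] for q in batch])
            Y = np.zeros((len(batch), n_e))
            for row, qy in enumerate(batch):
                Y[row, tails_by_query[qy]] = 1.0
            if ls > 0:
                Y = Y * (1.0 - ls) + ls / n_e
            loss, dE, dR_rows, dW = _forward_backward(
                model, h_idx, r_idx, Y, config.dropouts, rng
            )
            if not np.isfinite(loss):
                raise TrainingError(
                    "non-finite loss during training",
                    {"epoch": epoch, "batch_start": start, "loss": loss},
                )
            dR = np.zeros_like(model.R)
            np.add.at(dR, r_idx, dR_rows)
            opt.step([model.E, model.R, model.W], [dE, dR, dW])
            epoch_loss += loss
            n_batches += 1
        opt.lr *= config.decay_rate
        log["train_loss"].append(epoch_loss / max(n_batches, 1))

        if valid_triplets and (
            (epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1
        ):
            mrr = _validation_mrr(model, valid_triplets, triplets, ent_idx, rel_idx)
            log["valid_mrr"].append((epoch, mrr))
            if mrr > best[0]:
                best = (mrr, (model.E.copy(), model.R.copy(), model.W.copy()))

    if valid_triplets and best[1] is not None:
        model = TuckerModel(E=best[1][0], R=best[1][1], W=best[1][2],
                            entities=entities, relations=rel_vocab)
        log["best_valid_mrr"] = best[0]
    return model, log


def _validation_mrr(model, valid, train_triplets, ent_idx, rel_idx) -> float:
    """Filtered tail-prediction MRR over the validation triplets (both
    orientations via reciprocals), used for model selection only."""
    known = set()
    for h, r, t in list(train_triplets) + list(valid):
        known.add((ent_idx[h], rel_idx[r], ent_idx[t]))
        known.add((ent_idx[t], rel_idx[_inverse_label(r)], ent_idx[h]))
    rr = []
    for h, r, t in valid:
        for hh, rl, tt in (
            (ent_idx[h], rel_idx[r], ent_idx[t]),
            (ent_idx[t], rel_idx[_inverse_label(r)], ent_idx[h]),
        ):
            scores = score_all_tails(hh, rl, model).scores
            true = scores[tt]
            mask = np.ones(len(scores), bool)
            for e in range(len(scores)):
                if e != tt and (hh, rl, e) in known:
                    mask[e] = False
            rank = 1 + int(np.sum(scores[mask] >= true)) - 1  # true tail ties against itself once
            rr.append(1.0 / max(rank, 1))
    return float(np.mean(rr)) if rr else 0.0


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: TuckerModel, config: TrainConfig | None, path) -> None:
    """Persist embeddings + core tensor (npz) with a JSON sidecar holding
    the vocabularies and training configuration."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), E=model.E, R=model.R, W=model.W)
    meta = {
        "entities": model.entities,
        "relations": model.relations,
        "config": None if config is None else {
            "d_e": config.d_e, "d_r": config.d_r,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "decay_rate": config.decay_rate,
            "dropouts": list(config.dropouts),
            "epochs": config.epochs,
            "label_smoothing": config.label_smoothing,
            "seed": config.seed,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_model(path) -> tuple[TuckerModel, dict]:
    import json
    from pathlib import Path

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    model = TuckerModel(
        E=arrays["E"], R=arrays["R"], W=arrays["W"],
        entities=meta.get("entities"), relations=meta.get("relations"),
    )
    return model, meta
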