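# Methods

## Network construction

The pipeline turns a registry table (one row per person: paternal
surname, maternal surname, raw block-level socioeconomic score, block
id) into a decile-stratified multi-relational surname graph.

**Normalization and deciles.** Raw block scores are min-max normalized,
z_i = 100·(x_i − min x)/(max x − min x); a constant score vector is
rejected as degenerate. Individuals are then assigned empirical income
deciles by rank, with the population split at the 10%, …, 90% rank
boundaries. Ties share the decile of their lowest rank position (the
lower decile), which makes the assignment deterministic and keeps every
resident of a block in the same decile. Because min-max normalization is
order-preserving, the multiplication by 100 affects no downstream
decile.

**Pair counting.** For every unordered surname pair we count the
individuals bearing it, broken down by the bearer's decile;
paternal/maternal order is irrelevant, and individuals whose two
surnames coincide are skipped (a self-loop carries no affinity
semantics).

**Filtering, in order:**

1. *Significance threshold.* A pair with total count n_ss is kept iff
   n_ss ≥ k·n_s1·n_s2/N, where n_s is the number of appearances of a
   surname in either name slot, N the number of individuals, and k > 1
   a security parameter (default 20). The right-hand side is k times
   the expected co-occurrence under random pairing, so surviving ties
   are k-fold over-represented. Removal is strict ("less than"), so
   equality keeps the pair.
2. *Rare-surname removal.* Pairs touching a surname with fewer than 20
   appearances (default) are dropped: their counts are too small for
   the significance test to be meaningful.
3. *k-core pruning* (default k = 2) on the collapsed simple graph (one
   edge per surviving pair, deciles collapsed), removing peripheral
   nodes while preserving the triangles that form the atomic affinity
   units.

Each surviving pair expands into mirrored triplets ⟨s1, d, s2⟩ /
⟨s2, d, s1⟩ for every decile with a positive count. Degree conventions:
k-core and modularity operate on the collapsed simple graph; the
summary's edge count and average degree (2E/N) count each
(pair, decile) combination once, which is the convention under which
the released SA19k counts (19 041 nodes, 187 563 edges) reproduce the
printed average degree 19.7. Whether a "triplet" is counted once or
twice per undirected edge is fixed package-wide as: the triplet store
is mirrored, edge counts collapse mirrors.

Modularity is the Newman–Girvan score Q = Σ_c (e_c/m − (d_c/2m)²),
implemented directly from the formula; community detection itself is
delegated to the Louvain implementation in networkx.

## Link-prediction model

The scorer is a three-way Tucker factorization shared across relations:
φ(h,r,t) = W ×₁ e_h ×₂ w_r ×₃ e_t. Defaults follow the configuration
that performed best on the surname network: d_e = 200, d_r = 10 (one
dimension per decile relation), batch size 128, Adam at learning rate
0.005 with decay rate 1.0 (interpreted as no per-epoch decay), and
dropout rates (0.5, 0.2, 0.2) applied at three sites during training:
the head-entity input representation, the relation–core product
M_r = W ×₂ w_r, and the final query vector e_hᵀM_r before it is
multiplied against all candidate embeddings. Dropout is
inverted-scaled at train time and inactive at inference.

Although the graph is undirected, reciprocal relations are kept as
distinct embedding rows (r and r_inv), so symmetry of the learned
relation matrices M_r is an emergent diagnostic of fit rather than a
constraint. Training is 1:N: each batch row is a (head, relation) query
whose label vector marks all tails observed for it; the loss is the
candidate-averaged Bernoulli log-likelihood with probabilities clamped
to [1e-12, 1−1e-12]. Label smoothing (default 0) and batch
normalization (absent) are deliberately minimal: neither is part of the
core model, and the training loop converges without them at the
problem sizes used here. Gradients are derived analytically and
optimized with a hand-written Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).

Initialization draws E and R from N(0, 0.1²) and W from U(−1, 1),
seeded; small entity/relation scales keep initial scores near zero so
the sigmoid starts uninformative. Epoch count is a config knob; when a
validation set is supplied, the model with the best validation MRR
(filtered, evaluated every `eval_every` epochs) is returned. A
non-finite loss aborts with diagnostics. Identical config and seed give
bit-identical parameters.

## Evaluation protocol

Each evaluation triplet is ranked in both directions (tail via ⟨h,r,?⟩,
head via the reciprocal query ⟨t,r⁻¹,?⟩). Ranks are pessimistic: a
candidate scoring equal to the true entity counts as ranked above it.
The *filtered* protocol (default) removes other known-true candidates
from the comparison; both protocols are available, and every report
records which was used. Headline hits@n and MRR pool head and tail
ranks.

Because the triplet store is mirrored, sampling an evaluation triplet
would leave its mirror in the training set and leak the answer; the
splitter removes those mirrors from train by default, with a
`keep_mirrors` flag for the permissive protocol.

The random floor is the closed-form expectation under a uniformly
random permutation of m = n_entities − degree + 1 candidates:
E[hits@n] = min(1, n/m), E[MRR] = H_m/m.

## Shared-neighbor attribution

For each correctly predicted tie ⟨h, d, t⟩ three SNN fractions are
computed (|A∩B|/|A∪B|, query entities excluded, 0 on empty union):

- *same-decile*: graph neighborhoods restricted to relation d;
- *near-decile*: neighborhoods pooled over d and its `window` nearest
  deciles (default `window=2`, i.e. the two nearest — one per side,
  clipped at the boundary by taking the nearest two overall, so decile
  1 pools {1, 2, 3}; `window=4` gives two per side);
- *embedding*: each entity i is mapped to M_d·e_i and its neighborhood
  is its k nearest entities by Euclidean distance (default k = 50; ties
  at the k-th distance break by entity index; a flag switches to raw
  embedding rows).

A prediction is classified *grounded* when its same- or near-decile SNN
exceeds a threshold, default 0 — any shared graph neighbor grounds it.
This is the weakest grounded criterion, so the embedding-explained
fraction reported is conservative; the threshold is a config knob.

Micro-cluster bridging: a new tie's endpoints are located in the
connected components of the decile-restricted collapsed training graph
(a flag switches to the global graph); the analysis reports whether the
tie bridges two distinct components, both component sizes, and the
diameter of the union of the two components before (infinite when
disconnected) and after insertion.

## Synthetic registry generator

The generator emulates the summary structure of a real civil registry:

- **Surname frequencies** follow a Zipf law over ranks,
  w_r ∝ r^(−a) (default a = 1), giving the hub-dominated degree
  structure of real isonymy networks.
- **Latent strata** (default 10) drive generation; income deciles are
  assigned downstream from the empirical score distribution, keeping
  the generator independent of the analysis it feeds. Each surname
  belongs to one stratum, assigned by its noise-jittered frequency
  rank (Gaussian jitter, sd 0.1 in quantile units): common surnames
  sit in low strata, rare surnames in high strata. This mirrors the
  empirical pattern that surname diversity grows with socioeconomic
  level, and it is what makes significant edges concentrate in the top
  decile: very common surnames co-occur no more often than chance, so
  the significance filter removes their pairs, while rare high-stratum
  surnames pairing endogamously are strongly over-represented.
- **Endogamy**: with probability `endogamy` (default 0.9, the reference
  condition) the maternal surname is drawn from the paternal surname's
  stratum, otherwise from the marginal pool; draws where the two
  surnames coincide are redrawn from the same conditional law.
- **Blocks** (default 400) are assigned to strata round-robin; each
  block draws one raw score from a normal centered at its stratum
  ((s+0.5)·100/K, sd 60/K), shared by all its residents. An
  individual's block is drawn among the blocks of the paternal
  stratum.

Defaults (50 000 individuals, 500 surnames) are sized so that the bulk
of the surname pool clears the 20-occurrence filter, which at this
population is what a desk-scale registry requires.

What the generator does *not* emulate: real surname etymology and
ethnicity structure, geographic adjacency of blocks, household and
family-tree dependence between records, and the sheer scale of a
metropolitan registry (millions of individuals, tens of thousands of
surnames). Consequently the synthetic network reproduces the
*direction* of the empirical findings — top-decile edge
over-representation (more extreme here: the top three deciles carry
nearly all significant edges), high Louvain modularity (~0.82), ranking
performance far above the random floor, embedding-space SNN exceeding
grounded SNN — but its absolute metric values are not comparable to
those measured on the real network, and passing tests show
method correctness plus qualitative, not quantitative, transfer.

## Reference experiments and problem sizes

`experiments.full_pipeline` runs the whole analysis at the reference
condition (50 000 individuals, endogamy 0.9), holds out 300+300
triplets, trains a d_e = 32, d_r = 10 model for 200 epochs (these
reduced sizes suit the few-hundred-entity synthetic network; paper-scale
d_e = 200 remains the library default), evaluates per decile, and
attributes predictions with k = min(50, n_entities − 1). A test triplet
counts as correctly predicted when its better direction ranks within
10.

`experiments.planted_recovery` plants a ground-truth model over 50
entities in 5 latent clusters (cluster noise 0.15) and 3 relations,
emits its top 800 ordered triplets (symmetrized; enough for the
emitted set to cover essentially the whole entity set), retrains from
scratch (d_e = 24, 600 epochs, no dropout) on a split, and reports the
validation MRR against the random-ranking expectation together with the
planted-vs-non-planted AUC (Mann–Whitney rank statistic).

## Numerical choices and degenerate inputs

- Probability clamp 1e-12 in the Bernoulli loss; sigmoid computed in
  the numerically stable split form.
- Constant score vectors are rejected (zero min-max range); empty
  post-filter graphs raise with per-stage diagnostics.
- Tie-breaks are deterministic everywhere: decile ties go down, ranking
  ties go against the true entity, kNN ties break by entity index,
  planted-triplet score ties break by (head, tail, relation) index.
- One seeded RNG stream per generator operation; training derives its
  stream from the config seed. All text writers use fixed column order
  and float formatting, so equal inputs give byte-identical files.

## Known limitations

- The Tucker training loop is dense numpy; it is sized for graphs of
  up to a few thousand entities, not for GPU-scale corpora.
- Embedding kNN uses the full distance matrix (O(n_e²) memory), which
  is appropriate at desk scale only.
- The grounded/embedding dichotomy depends on the (documented) zero
  threshold; with it, any single shared neighbor grounds a prediction,
  so grounded fractions on dense synthetic networks run high.
- Per-decile metrics on the synthetic network are informative only for
  the deciles the significance filter leaves populated (the top three
  at the reference condition).
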