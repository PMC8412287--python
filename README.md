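# surname-affinity

Tools for building **surname affinity networks** from individual-level
registry data and predicting new affinity ties with a Tucker-decomposition
link-prediction model.

In countries where people carry both parents' surnames, the pair
(paternal, maternal) borne by one person records a marriage-derived
association between two surnames. Aggregated over a population, these
pairs form a multi-relational graph: nodes are surnames, and an edge
between two surnames in relation `d1`..`d10` counts the individuals
bearing that pair in each decile of the socioeconomic distribution. The
structure of such a graph — who connects to whom, and in which income
stratum — is a window on assortative mating and class segregation. This
package is aimed at computational social scientists and population
researchers who want to study that structure, and in particular to ask:
*how predictable is the formation of a new surname tie, and is a
predicted tie explained by neighbors the two surnames already share in
the observed network, or only by proximity in a learned embedding
space?*

Real registries cannot be redistributed, so the package ships a
synthetic registry generator that reproduces the statistical structure
the analysis relies on (Zipf-like surname frequencies, block-level
socioeconomic scores, tunable endogamy); every stage is exercised end to
end on generated data.

## The model

A knowledge graph G over entities V (surnames) and relations R (income
deciles) is a set of triplets ⟨h, r, t⟩. The scorer factorizes the
binary triplet tensor through a core tensor **W** ∈ ℝ^(d_e×d_r×d_e),
entity embeddings **E** ∈ ℝ^(n_e×d_e) and relation embeddings
**R** ∈ ℝ^(n_r×d_r):

    φ(h, r, t) = W ×₁ e_h ×₂ w_r ×₃ e_t
               = Σ_pqs W[p,q,s] · E[h,p] · R[r,q] · E[t,s]

where ×ₙ is the N-mode tensor–matrix product. A logistic sigmoid maps
φ to the probability that the triplet is observed. Training adds a
reciprocal relation r⁻¹ per relation (so head prediction ⟨?, r, t⟩
reduces to tail prediction ⟨t, r⁻¹, ?⟩) and uses 1:N scoring — each
(head, relation) query is scored against all candidate tails at once
under a multi-label Bernoulli log-likelihood loss, optimized with Adam.
The forward pass, analytic gradients and optimizer are plain numpy.

Evaluation ranks each held-out triplet's true entity among all
candidates (pessimistic ties, filtered protocol by default) and reports
hits@{1,3,10} and mean reciprocal rank, overall and per decile.
Correctly predicted ties are then attributed to three neighborhood
sources via the shared-nearest-neighbor fraction
SNN(A, B) = |A ∩ B| / |A ∪ B|: same-decile graph neighborhoods,
near-decile pooled neighborhoods, and k-nearest neighborhoods in the
decile-transformed embedding space (entity i ↦ M_d·e_i with
M_d = W ×₂ w_d).

## Worked example

```python
from surname_affinity import experiments

out = experiments.full_pipeline(seed=1)
print(out["summary"]["n_nodes"], out["summary"]["n_edges"])
print(round(out["summary"]["average_degree"], 2), round(out["modularity"], 3))
print({k: round(v, 3) for k, v in out["metrics"].items() if k.startswith("hits")})
print(round(out["snn"]["overall"]["mean_snn_same_decile"], 3),
      round(out["snn"]["overall"]["mean_snn_embedding"], 3))
```

prints (seed 1):

```
344 3586
20.85 0.823
{'hits@1': 0.05, 'hits@3': 0.105, 'hits@10': 0.287}
0.221 0.893
```

Reading: from a synthetic registry of 50 000 individuals with strong
socioeconomic endogamy (0.9), the construction pipeline (significance
threshold k = 20, minimum 20 occurrences per surname, 2-core pruning)
leaves a network of 344 surnames and 3 586 decile-stratified edges with
average degree 20.85. Louvain communities reach modularity 0.823 —
the network is strongly partitioned along socioeconomic lines — and
edges concentrate in the top decile. The trained model ranks 28.7% of
held-out ties into the top 10 of ~340 candidates (uniform chance:
2.9%), and the correctly predicted ties share far more neighbors in the
embedding space (mean SNN 0.89) than in the same-decile observed graph
(0.22): structural proximity, not only observed common neighbors,
carries the signal.

The same stages are scriptable from the shell:

```
surname-affinity generate --n-individuals 50000 --seed 1 --out data/
surname-affinity build --registry data/registry.tsv --k-security 20 --out kg/
surname-affinity split --triplets kg/triplets.tsv --n-valid 300 --n-test 300 --seed 1 --out splits/
surname-affinity train --triplets splits/train.tsv --valid splits/valid.tsv --seed 1 --out model/ckpt
surname-affinity evaluate --model model/ckpt --test splits/test.tsv --known splits/train.tsv --per-decile --out eval/
surname-affinity explain --model model/ckpt --kg splits/train.tsv --predictions splits/test.tsv --out snn/
```

All stages are seeded and write deterministic text outputs; a rerun with
the same arguments reproduces every file byte for byte.

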