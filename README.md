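# hypernull

Null models for hypergraphs, built by hyperedge swapping.

Many real systems — metabolic reaction networks, question–answer and review
communities, collaborations — are naturally **hypergraphs**: a hyperedge can
join any number of nodes, not just two. To decide whether a measured
statistic of such a network (its clustering, assortativity, entropy,
resilience, spreading capacity) is a genuine structural feature or just a
by-product of its degree sequences, one compares against **null models**:
randomized surrogates that preserve chosen properties and scramble
everything else.

`hypernull` implements a family of six null models generated by repeated
local swaps on the incidence matrix *C* (the *n × m* binary matrix with
*c<sub>ij</sub>* = 1 iff node *i* belongs to hyperedge *j*), preserving
progressively more structure:

| model   | preserved exactly (besides *n*, *m*, Σ*c<sub>ij</sub>*)            |
|---------|---------------------------------------------------------------------|
| H0k     | average hyperdegree only                                            |
| H1k-HD  | the hyperdegree vector (row sums of *C*)                            |
| H1k-HED | the hyperedge-degree vector (column sums of *C*)                    |
| HD-HED  | both degree vectors (checkerboard 2×2 swaps)                        |
| H2k     | + the joint hyperdegree signature of every hyperedge                |
| H2.25k  | + the mean clustering coefficient of the projection                 |

giving the containment hierarchy
H0k ⊆ H1k-HD / H1k-HED ⊆ H2k ⊆ H2.25k ⊆ H. No swap may ever empty a
hyperedge or strand a node outside every hyperedge.

On top of the generators the package provides:

- **randomness**: the hypergraph entropy
  I(H) = −Σᵢ pᵢ log pᵢ with pᵢ = dᵢᵗ / Σⱼ dⱼᵗ over the hyperdegrees
  d₁..d<sub>n</sub>, and entropy-vs-swaps trajectories;
- **statistics**: hyperdegrees, hyperedge degrees, clustering,
  co-average hyperdegree, average neighbor degree, strength, Newman
  assortativity on the projection, hypertriangle counts, and the
  significance ratio μ = (statistic on null) / (statistic on original);
- **dynamics**: hypergraph dismantling by nodes or hyperedges (GCC curves
  and GCC-AUC) and a threshold SIR contagion where a hyperedge becomes
  infectious once its infectious-member count passes θ and a susceptible
  node is infected with probability 1 − e^(−β·n_all);
- **I/O and synthesis**: hyperedge-list and nverts/simplices file formats,
  plus a seeded synthetic hypergraph generator.

## Worked example

```python
import numpy as np
from hypernull import (SyntheticSpec, generate_synthetic_hypergraph, NullModelConfig,
                       generate_null_model, hypergraph_entropy, mean_clustering,
                       significance_mu, hyperdegrees)

spec = SyntheticSpec(n=100, m=200, sizes={2: 0.3, 3: 0.4, 4: 0.2, 6: 0.1},
                     rng_seed=7, node_weight_exponent=1.0)
H = generate_synthetic_hypergraph(spec)
print(f"original: n={H.n}, m={H.m}, I(H)={hypergraph_entropy(H):.4f} nats, "
      f"C={mean_clustering(H):.4f}")

null, log = generate_null_model(H, NullModelConfig(model="H1k-HD", rng_seed=11))
print(f"H1k-HD : accepted {log.accepted} swaps ({log.attempted} attempts), "
      f"hyperdegrees preserved: "
      f"{np.array_equal(hyperdegrees(H), hyperdegrees(null))}")
print(f"         I(null)={hypergraph_entropy(null):.4f} nats, "
      f"C={mean_clustering(null):.4f}, "
      f"mu_C={significance_mu(mean_clustering(null), mean_clustering(H)):.3f}")
```

prints

```
original: n=100, m=200, I(H)=3.7408 nats, C=0.6935
H1k-HD : accepted 2000 swaps (2103 attempts), hyperdegrees preserved: True
         I(null)=3.7408 nats, C=0.6883, mu_C=0.993
```

The H1k-HD surrogate keeps every node's hyperdegree, so the entropy — a
function of the hyperdegree distribution alone — is bit-identical, while
the hyperedge composition is thoroughly scrambled (2000 accepted swaps,
10× the number of hyperedges). The clustering coefficient barely moves
(μ ≈ 0.99): in this network, clustering is almost entirely explained by
the hyperdegree sequence.

The same operations are available from the shell:

```sh
hypernull synth --n 100 --m 200 --size 3 --seed 7 -o net.txt
hypernull stats net.txt
hypernull nullmodel net.txt --model H2k --swaps 10m --seed 1 -o null.txt
hypernull entropy-curve net.txt --model H0k --reps 10 --seed 1 --csv curve.csv
hypernull dismantle net.txt --by nodes --target 0.01
hypernull sir net.txt --beta 0.1 --theta 5 --seeds 0.01 --strategy hyperdegree --runs 100 --seed 1
hypernull compare net.txt --dynamic sir --beta 0.1 --seed 1
```

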