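# Methods

## The hypergraph model

A hypergraph H = (V, E) is a set of n labelled nodes and m hyperedges, each
a non-empty subset of V whose union covers V. Internally nodes are 0-based
indices with a preserved label map, so the mathematics is decoupled from
dataset label conventions. Hyperedges have set semantics (a node appears at
most once per hyperedge — the incidence matrix is binary), but *duplicate
hyperedges are allowed*, both in inputs and as swap outcomes: the swap-based
construction never needs to forbid them, and forbidding them would bias the
randomization. Directed, weighted and multilayer hyperedges are out of
scope.

All pairwise notions (degree, clustering, neighbor statistics,
assortativity, connectivity) are defined on the **unweighted projection**:
the simple graph joining two nodes iff they share at least one hyperedge.
Where a quantity could also be read on a multiplicity-weighted projection,
the unweighted reading is the default because it keeps clustering in [0, 1]
and matches how such tables of global statistics are conventionally
reported; the assortativity routine accepts `endpoint_degree="hyperdegree"`
as the alternative endpoint convention, since either reading of "degree" is
defensible there.

## Swap-based null models

Every generator performs local swaps on the incidence matrix of a working
copy; the input hypergraph is never modified. The six models and their
exact invariants:

- **H0k** — swap a 1-entry of one column with a 0-entry of another: one
  membership migrates between hyperedges. Preserves n, m and Σc_ij (hence
  the average hyperdegree).
- **H1k-HD** — swap two differing entries of the same row: a node changes
  hyperedge. Preserves the hyperdegree vector.
- **H1k-HED** — swap two differing entries of the same column: a member is
  replaced by a non-member. Preserves the hyperedge-degree vector.
- **HD-HED** — checkerboard swap of a 2×2 submatrix [[1,0],[0,1]] ↔
  [[0,1],[1,0]]: preserves both degree vectors.
- **H2k** — exchange two equal-hyperdegree nodes between two hyperedges
  (neither node may sit in both): preserves the hyperdegree vector and
  every hyperedge's joint hyperdegree signature (the sorted tuple of its
  members' hyperdegrees).
- **H2.25k** — an H2k swap accepted only when the mean projection
  clustering coefficient is unchanged within `cc_tolerance`.

Two global rules hold for all models: no swap may leave a hyperedge empty,
and no swap may drop a node to hyperdegree 0 (which would shrink the node
set); violating proposals are rejected and the state is untouched.
Rejection is a normal outcome, logged by category in a `SwapLog`
(`rejected_membership` for ineligible selections, `rejected_empty` for the
two non-emptiness rules, `rejected_cc` for the clustering veto).

**Counting.** A generation run counts *accepted* swaps — the default is
10·m of them, the point at which entropy trajectories are comfortably in
their stationary phase on the fixtures used here — with an attempt budget
(default 100) per accepted swap. Exhausting a budget aborts the run with a
warning and a partial result; every preservation guarantee still holds on a
partial result, since it holds after each individual swap.

**Proposal sampling.** Candidate entries are drawn directly from the
eligible sets (for H1k-HD, rows in the two columns' symmetric difference;
for H0k and H1k-HED, a (1-entry, 0-entry) pair of the chosen column(s)
weighted to match the uniform-pair law). This is exactly the conditional
distribution of "draw arbitrary entries, reject equal values", so the Markov
chain over hypergraphs is unchanged — only the wasted proposals are gone.
H2k keeps the literal draw-then-check form because its eligibility (equal
hyperdegrees, no cross-membership) has no cheap direct parameterization.

**H2.25k acceptance.** The clustering check recomputes local clustering
only over the affected nodes (the swapped pair and the union of their
projection neighborhoods before and after), against a pair-multiplicity
index maintained incrementally, and compares the implied change of the
*mean* per swap against `cc_tolerance` (default 1e-12; a `cc_per_node` flag
strengthens this to per-node preservation). The tolerance is effectively an
exactness test: local clustering values are small-denominator rationals, so
genuinely different configurations differ by far more than 1e-12, and
accepted swaps change the mean by exactly 0.0 in practice — accumulated
drift over a run stays below the tolerance. On sparse random hypergraphs
exactly-clustering-preserving H2k swaps are rare, so H2.25k runs frequently
end on the attempt budget with few accepted swaps; that is a property of
the constraint, not of the sampler.

## Randomness measure

Hypergraph entropy is the Shannon entropy of the hyperdegree distribution:
I(H) = −Σ p_i log p_i with p_i = d_i^t / Σ_j d_j^t. The exponent t
(default 1) reweights the distribution; natural log is used because model
*orderings* — the quantity of interest — are base-invariant, and a `base`
argument rescales on request. Consequently 0 ≤ I ≤ log n, with equality on
hyperdegree-regular hypergraphs, and I is bit-invariant under any generator
that preserves the hyperdegree multiset (H1k-HD, HD-HED, H2k, H2.25k).
`entropy_trajectory` records I over 10 independent realizations (default)
at 50 evenly spaced accepted-swap checkpoints up to 10·m; realizations that
stall on the attempt budget are carried flat, which is the correct reading
of a stuck chain.

## Dynamics

**Dismantling** removes nodes in descending hyperdegree order, or
hyperedges in descending hyperedge-degree order (ties broken by index), the
ranking computed *once* on the intact network — adaptive re-ranking is out
of scope. After each removal the giant connected component of the surviving
projection is recorded as a fraction of the original n; removal stops once
the GCC drops below `target_fraction · n` (default 0.01). The GCC-AUC is
the plain sum of recorded fractions, no trapezoid correction. Isolated
surviving nodes count as components of size 1, so hyperedge removal cannot
push the GCC below one node; with a target below one node the routine
removes every hyperedge and warns. A target of 0.01·n is only meaningful
for n ≥ ~100.

**Threshold SIR.** Discrete synchronous dynamics with states S/I/R. Each
step, evaluated from the state at step start: (1) a hyperedge is
*infectious* if its infectious-member count strictly exceeds θ (default 5;
`theta_strict=False` switches to ≥, since "passes the threshold" is
genuinely ambiguous); (2) each susceptible node i is infected with
probability 1 − e^(−β·n_all), where n_all sums the infectious members of
i's infectious hyperedges *with multiplicity* (`nall_distinct=True`
switches to counting distinct infectious neighbors); (3) each node
infectious at step start recovers with probability γ (default 1) — a node
infected at step t cannot recover at t. The run ends when no infectious
node remains; the epidemic size is the recovered fraction. Defaults follow
the study conditions: seed fraction 0.01 of n (rounded, minimum one seed
with a warning), seed strategies `random` / `degree` (projection degree) /
`hyperdegree` (ranked seeds tie-break by index), 100 independent runs.

Note a consequence of the strict threshold: an epidemic can only ignite if
some hyperedge contains more than θ initially infectious members, so with
0.01·n seeds the dynamics need n of several hundred (and seeds concentrated
in shared hyperedges, e.g. hub-ranked seeds on a heterogeneous network)
before any spread is possible. Randomizing with H0k disperses exactly that
co-location, so at small scale the most random surrogate can show *less*
spread than the original under these defaults — the threshold, not the
randomness, is binding there.

## Synthetic generator

`generate_synthetic_hypergraph` emulates the shape of the empirical
datasets this kind of analysis targets: m hyperedges with sizes drawn from
a given distribution (constant or finite support), members drawn without
replacement, and every uncovered node patched into a uniformly chosen
hyperedge to restore ⋃e_j = V. The default member selection is uniform; a
`node_weight_exponent` a > 0 biases selection by weight (i+1)^−a, producing
the heavy-tailed hyperdegrees that entropy-trajectory and significance
experiments need (uniform selection yields near-binomial hyperdegrees whose
entropy is already near its plateau). What the generator does **not**
emulate: degree–degree correlations beyond those induced by the weights,
community structure, nested or simplicial hyperedge organization, and the
very large hyperedges of some social datasets. Tests passing on these
fixtures therefore establish the correctness of the machinery (exact
invariants, limit cases, oracles), not quantitative predictions for any
particular empirical network.

The suite's experiments use n = 100–800, m = 200–1000 with mixed hyperedge
sizes; preservation checks run on 20 independent fixtures of n = 100,
m = 200.

## Numerical and degenerate-input choices

- Assortativity uses Newman's edge-list formula on the projection; a
  regular projection (zero endpoint-degree variance) returns NaN with a
  warning, as does an edgeless projection.
- Statistics over neighbors (co-average hyperdegree, average neighbor
  degree) return 0 with a log entry for projection-isolated nodes; nodes
  with fewer than two neighbors contribute clustering 0 and are included in
  the mean.
- The significance ratio μ is undefined (NaN, warning) when the original
  statistic is 0.
- Hypertriangles are node triples whose three pairs are covered by three
  pairwise-distinct hyperedges, with triples lying entirely inside one
  hyperedge excluded; the search enumerates projection triangles and
  verifies a system of distinct representatives among the pair-covering
  hyperedge sets.
- Matrices are dense below 10⁶ cells and CSR-sparse above; all contracts
  are value-level.
- Every stochastic routine takes a single seed; per-run/realization streams
  are spawned from it, so results are reproducible and runs are
  independent.

## Known limitations

- H2.25k mixes slowly by construction (exact clustering preservation);
  expect partial runs on sparse random inputs.
- Swap-based sampling is MCMC-style: closeness to the uniform distribution
  over the constraint set after 10·m swaps is assessed empirically (entropy
  plateau), not proven.
- GCC recomputation during dismantling rebuilds the projection per step
  (O(steps · Σ|e|²)); adequate for the scales above, not tuned for
  n ≫ 10⁴.
- The simplex on-disk format stores 1-based indices, so arbitrary labels
  survive a round-trip only in the edgelist format.
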