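"""Six hyperedge-swapping null models of increasing order.

Each generator randomizes a hypergraph by repeated local swaps on its
incidence matrix, preserving progressively more structure:

========  =============================================================
model     preserved exactly (besides n, m and the total membership count)
========  =============================================================
H0k       nothing more (hence the *average* hyperdegree)
H1k-HD    the hyperdegree vector (incidence row sums)
H1k-HED   the hyperedge-degree vector (incidence column sums)
HD-HED    both degree vectors (checkerboard 2x2 swaps)
H2k       hyperdegree vector + per-hyperedge joint hyperdegree signature
H2.25k    H2k's set + the mean projection clustering coefficient
========  =============================================================

giving the containment hierarchy H0k ⊆ H1k-HD / H1k-HED ⊆ H2k ⊆ H2.25k ⊆ H.
Swaps that would create an empty hyperedge, or strand a node in no
hyperedge at all, are rejected and reverted — the node set and hyperedge
count never change.  Rejection is a normal outcome; generation counts
*accepted* swaps (default 10·m of them) and gives up with a partial result
when a per-swap attempt budget is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Hypergraph

MODEL_NAMES = ("H0k", "H1k-HD", "H1k-HED", "HD-HED", "H2k", "H2.25k")

# attempt outcome codes
_ACCEPT = "accepted"
_REJ_MEMBERSHIP = "rejected_membership"
_REJ_EMPTY = "rejected_empty"
_REJ_CC = "rejected_cc"


@dataclass
class NullModelConfig:
    """Configuration for one null-model generation run.

    Parameters
    ----------
    model
        One of ``H0k, H1k-HD, H1k-HED, HD-HED, H2k, H2.25k``.
    n_swaps
        Number of *accepted* swaps; ``None`` means 10·m.
    max_attempts_per_swap
        Attempt budget per accepted swap; exhausting it aborts the run
        with a partial result.
    rng_seed
        Seed for the single RNG driving all random choices.
    cc_tolerance
        H2.25k only: maximum allowed |Δ mean clustering| per swap.
    cc_per_node
        H2.25k only: if True, require every node's clustering value to be
        preserved within ``cc_tolerance`` (strict mode), not just the mean.
    """

    model: str
    n_swaps: int | None = None
    max_attempts_per_swap: int = 100
    rng_seed: int | None = None
    cc_tolerance: float = 1e-12
    cc_per_node: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(
                f"unknown null model {self.model!r}; valid names: {', '.join(MODEL_NAMES)}"
            )
        if self.n_swaps is not None and self.n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")
        if self.max_attempts_per_swap < 1:
            raise ValueError("max_attempts_per_swap must be >= 1")
        if self.cc_tolerance < 0:
            raise ValueError("cc_tolerance must be >= 0")


@dataclass
class SwapLog:
    """Diagnostics of one generation run.

    ``rejected_membership`` counts ineligible selections (equal incidence
    entries, a node common to both hyperedges, hyperdegree mismatch);
    ``rejected_empty`` counts swaps reverted because a hyperedge would
    become empty or a node would be left in no hyperedge; ``rejected_cc``
    counts H2.25k swaps reverted by the clustering-preservation check.
    """

    attempted: int = 0
    accepted: int = 0
    rejected_empty: int = 0
    rejected_membership: int = 0
    rejected_cc: int = 0
    budget_exhausted: bool = False

    def record(self, outcome: str) -> None:
        self.attempted += 1
        setattr(self, outcome, getattr(self, outcome) + 1)


class _SwapState:
    """Mutable working copy of a hypergraph used by the swap engine.

    Keeps hyperedges as sets plus the reverse node→hyperedge index, and —
    only when a model needs clustering — a shared-hyperedge pair counter
    for O(1) projection-adjacency queries.
    """

    __slots__ = ("n", "edges", "member_of", "pair_count")

    def __init__(self, H: Hypergraph) -> None:
        self.n = H.n
        self.edges: list[set[int]] = [set(e) for e in H.hyperedges]
        self.member_of: list[set[int]] = [set() for _ in range(H.n)]
        for j, e in enumerate(self.edges):
            for i in e:
                self.member_of[i].add(j)
        self.pair_count: dict[tuple[int, int], int] | None = None

    @property
    def m(self) -> int:
        return len(self.edges)

    def degree(self, i: int) -> int:
        return len(self.member_of[i])

    def hyperdegrees(self) -> np.ndarray:
        return np.array([len(s) for s in self.member_of], dtype=np.int64)

    def to_hypergraph(self, labels) -> Hypergraph:
        return Hypergraph(labels, [frozenset(e) for e in self.edges])

    # -- incidence edits (keep member_of and pair_count in sync) --------

    def remove(self, i: int, j: int) -> None:
        if self.pair_count is not None:
            for x in self.edges[j]:
                if x != i:
                    self._bump(i, x, -1)
        self.edges[j].discard(i)
        self.member_of[i].discard(j)

    def add(self, i: int, j: int) -> None:
        if self.pair_count is not None:
            for x in self.edges[j]:
                if x != i:
                    self._bump(i, x, +1)
        self.edges[j].add(i)
        self.member_of[i].add(j)

    # -- projection adjacency (clustering support) ----------------------

    def enable_pair_counts(self) -> None:
        if self.pair_count is not None:
            return
        pc: dict[tuple[int, int], int] = {}
        for e in self.edges:
            members = sorted(e)
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    key = (members[a], members[b])
                    pc[key] = pc.get(key, 0) + 1
        self.pair_count = pc

    def _bump(self, a: int, b: int, delta: int) -> None:
        key = (a, b) if a < b else (b, a)
        new = self.pair_count.get(key, 0) + delta
        if new:
            self.pair_count[key] = new
        else:
            self.pair_count.pop(key, None)

    def adjacent(self, a: int, b: int) -> bool:
        key = (a, b) if a < b else (b, a)
        return key in self.pair_count

    def neighbors(self, i: int) -> set[int]:
        nbrs: set[int] = set()
        for j in self.member_of[i]:
            nbrs.update(self.edges[j])
        nbrs.discard(i)
        return nbrs

    def local_clustering(self, i: int) -> float:
        nbrs = sorted(self.neighbors(i))
        k = len(nbrs)
        if k < 2:
            return 0.0
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if self.adjacent(nbrs[a], nbrs[b]):
                    links += 1
        return 2.0 * links / (k * (k - 1))


# -- single-swap attempts ------------------------------------------------


def _sample_nonmember(state: _SwapState, j: int, rng: np.random.Generator) -> int:
    # exact uniform draw over the column's 0-entries (rejection sampling)
    while True:
        r = int(rng.integers(state.n))
        if r not in state.edges[j]:
            return r


def _attempt_h0k(state: _SwapState, rng: np.random.Generator) -> str:
    """Swap a distinct-valued entry pair drawn from two random columns.

    The pair is drawn uniformly over the eligible (1-entry, 0-entry)
    combinations of the two columns — the same conditional law as drawing
    two arbitrary entries and rejecting equal values.  Moves one
    membership between hyperedges; preserves n, m and the total
    membership count (hence the average hyperdegree).
    """
    j1, j2 = (int(x) for x in rng.choice(state.m, size=2, replace=False))
    e1, e2 = state.edges[j1], state.edges[j2]
    k1 = len(e1) * (state.n - len(e2))  # membership leaves j1, lands in j2
    k2 = len(e2) * (state.n - len(e1))  # membership leaves j2, lands in j1
    if k1 + k2 == 0:
        return _REJ_MEMBERSHIP
    if rng.random() >= k1 / (k1 + k2):
        j1, j2 = j2, j1
        e1, e2 = e2, e1
    members = sorted(e1)
    r1 = members[int(rng.integers(len(members)))]
    r2 = _sample_nonmember(state, j2, rng)
    # same-row pair keeps r1's hyperdegree (it just changes hyperedge)
    if len(e1) == 1 or (state.degree(r1) == 1 and r1 != r2):
        return _REJ_EMPTY
    state.remove(r1, j1)
    state.add(r2, j2)
    return _ACCEPT


def _attempt_h1k_hd(state: _SwapState, rng: np.random.Generator) -> str:
    """Swap one row's entries across two columns: one node changes hyperedge.

    The row is drawn uniformly from those whose entries differ (the
    hyperedges' symmetric difference).  Row sums (hyperdegrees) are
    untouched; column sums may change.
    """
    j1, j2 = (int(x) for x in rng.choice(state.m, size=2, replace=False))
    diff = sorted(state.edges[j1] ^ state.edges[j2])
    if not diff:
        return _REJ_MEMBERSHIP
    r = diff[int(rng.integers(len(diff)))]
    src, dst = (j1, j2) if r in state.edges[j1] else (j2, j1)
    if len(state.edges[src]) == 1:
        return _REJ_EMPTY
    state.remove(r, src)
    state.add(r, dst)
    return _ACCEPT


def _attempt_h1k_hed(state: _SwapState, rng: np.random.Generator) -> str:
    """Swap two distinct-valued entries within one column: replace a member.

    Uniform over (member, non-member) pairs of the chosen column.  Column
    sums (hyperedge degrees) are untouched; the two nodes' hyperdegrees
    change by ±1.
    """
    j = int(rng.integers(state.m))
    e = state.edges[j]
    if len(e) == state.n:
        return _REJ_MEMBERSHIP  # no non-member to bring in
    members = sorted(e)
    leaving = members[int(rng.integers(len(members)))]
    entering = _sample_nonmember(state, j, rng)
    if state.degree(leaving) == 1:
        return _REJ_EMPTY
    state.remove(leaving, j)
    state.add(entering, j)
    return _ACCEPT


def _attempt_hd_hed(state: _SwapState, rng: np.random.Generator) -> str:
    """Checkerboard swap: a 2x2 incidence submatrix [[1,0],[0,1]] ↔ [[0,1],[1,0]].

    The two rows are drawn from those whose entries differ across the two
    chosen columns (each pair "from the same row while containing distinct
    entry values", i.e. the hyperedges' symmetric difference); the swap is
    rejected unless the two pairs have opposite orientation.  Both row and
    column sums are preserved exactly.
    """
    j1, j2 = rng.choice(state.m, size=2, replace=False)
    diff = sorted(state.edges[j1] ^ state.edges[j2])
    if len(diff) < 2:
        return _REJ_MEMBERSHIP
    i1, i2 = rng.choice(len(diff), size=2, replace=False)
    r1, r2 = diff[int(i1)], diff[int(i2)]
    a = r1 in state.edges[j1]
    c = r2 in state.edges[j1]
    if a == c:  # same orientation, e.g. [[1,0],[1,0]]
        return _REJ_MEMBERSHIP
    if a:  # pattern [[1,0],[0,1]] -> r1: j1->j2, r2: j2->j1
        state.remove(r1, j1)
        state.add(r1, j2)
        state.remove(r2, j2)
        state.add(r2, j1)
    else:  # mirrored pattern
        state.remove(r1, j2)
        state.add(r1, j1)
        state.remove(r2, j1)
        state.add(r2, j2)
    return _ACCEPT


def _pick_h2k_pair(state: _SwapState, rng: np.random.Generator):
    j1, j2 = rng.choice(state.m, size=2, replace=False)
    e1 = sorted(state.edges[j1])
    e2 = sorted(state.edges[j2])
    u = e1[int(rng.integers(len(e1)))]
    v = e2[int(rng.integers(len(e2)))]
    # a node common to both hyperedges cannot be selected, and neither node
    # may already sit in the receiving hyperedge (incidence stays binary)
    if u == v or u in state.edges[j2] or v in state.edges[j1]:
        return None
    if state.degree(u) != state.degree(v):
        return None
    return j1, j2, u, v


def _apply_h2k(state: _SwapState, j1: int, j2: int, u: int, v: int) -> None:
    state.remove(u, j1)
    state.remove(v, j2)
    state.add(v, j1)
    state.add(u, j2)


def _attempt_h2k(state: _SwapState, rng: np.random.Generator) -> str:
    """Exchange two equal-hyperdegree nodes between two hyperedges.

    Preserves the hyperdegree vector and every hyperedge's joint
    hyperdegree signature (the sorted tuple of its members' hyperdegrees).
    """
    picked = _pick_h2k_pair(state, rng)
    if picked is None:
        return _REJ_MEMBERSHIP
    _apply_h2k(state, *picked)
    return _ACCEPT


def _attempt_h2_25k(
    state: _SwapState,
    rng: np.random.Generator,
    cc_tolerance: float = 1e-12,
    cc_per_node: bool = False,
) -> str:
    """An H2k swap accepted only if the clustering coefficient is unchanged.

    The affected nodes are the swapped pair plus the union of their
    projection neighborhoods before and after the move; only their local
    clustering values can change, so the mean-clustering delta is computed
    over that set and the swap is reverted when |Δ| exceeds the tolerance.
    """
    picked = _pick_h2k_pair(state, rng)
    if picked is None:
        return _REJ_MEMBERSHIP
    state.enable_pair_counts()
    j1, j2, u, v = picked
    affected = {u, v} | state.neighbors(u) | state.neighbors(v)
    _apply_h2k(state, j1, j2, u, v)
    affected |= state.neighbors(u) | state.neighbors(v)
    order = sorted(affected)
    after = [state.local_clustering(w) for w in order]
    _apply_h2k(state, j1, j2, v, u)  # revert to measure the before values
    before = [state.local_clustering(w) for w in order]
    if cc_per_node:
        ok = all(abs(a - b) <= cc_tolerance for a, b in zip(after, before))
    else:
        delta_mean = (sum(after) - sum(before)) / state.n
        ok = abs(delta_mean) <= cc_tolerance
    if not ok:
        return _REJ_CC
    _apply_h2k(state, j1, j2, u, v)
    return _ACCEPT


def _dispatch(model: str, state: _SwapState, rng: np.random.Generator, config) -> str:
    if model == "H0k":
        return _attempt_h0k(state, rng)
    if model == "H1k-HD":
        return _attempt_h1k_hd(state, rng)
    if model == "H1k-HED":
        return _attempt_h1k_hed(state, rng)
    if model == "HD-HED":
        return _attempt_hd_hed(state, rng)
    if model == "H2k":
        return _attempt_h2k(state, rng)
    if model == "H2.25k":
        return _attempt_h2_25k(state, rng, config.cc_tolerance, config.cc_per_node)
    raise ValueError(
        f"unknown null model {model!r}; valid names: {', '.join(MODEL_NAMES)}"
    )


# -- public single-swap API (operate on a Hypergraph in place) -----------


def _attempt_on_hypergraph(model: str, H: Hypergraph, rng, **kw) -> bool:
    config = NullModelConfig(model=model, **kw)
    state = _SwapState(H)
    outcome = _dispatch(model, state, rng, config)
    if outcome == _ACCEPT:
        H.hyperedges[:] = [frozenset(e) for e in state.edges]
        return True
    return False


def attempt_swap_h0k(H: Hypergraph, rng: np.random.Generator) -> bool:
    """One H0k swap attempt applied in place; returns True iff accepted."""
    return _attempt_on_hypergraph("H0k", H, rng)


def attempt_swap_h1k_hd(H: Hypergraph, rng: np.random.Generator) -> bool:
    """One H1k-HD swap attempt applied in place; returns True iff accepted."""
    return _attempt_on_hypergraph("H1k-HD", H, rng)


def attempt_swap_h1k_hed(H: Hypergraph, rng: np.random.Generator) -> bool:
    """One H1k-HED swap attempt applied in place; returns True iff accepted."""
    return _attempt_on_hypergraph("H1k-HED", H, rng)


def attempt_swap_hd_hed(H: Hypergraph, rng: np.random.Generator) -> bool:
    """One HD-HED checkerboard swap attempt applied in place; returns True iff accepted."""
    return _attempt_on_hypergraph("HD-HED", H, rng)


def attempt_swap_h2k(H: Hypergraph, rng: np.random.Generator) -> bool:
    """One H2k swap attempt applied in place; returns True iff accepted."""
    return _attempt_on_hypergraph("H2k", H, rng)


def attempt_swap_h2_25k(
    H: Hypergraph, rng: np.random.Generator, cc_tolerance: float = 1e-12
) -> bool:
    """One H2.25k swap attempt applied in place; returns True iff accepted."""
    return _attempt_on_hypergraph("H2.25k", H, rng, cc_tolerance=cc_tolerance)


# -- generation ----------------------------------------------------------


def _run_swaps(state, config, rng, log, n_swaps, checkpoint_hook=None):
    """Drive the swap loop: n_swaps accepted swaps, each within the attempt budget."""
    for _ in range(n_swaps):
        for _attempt in range(config.max_attempts_per_swap):
            outcome = _dispatch(config.model, state, rng, config)
            log.record(outcome)
            if outcome == _ACCEPT:
                break
        else:
            log.budget_exhausted = True
            return
        if checkpoint_hook is not None:
            checkpoint_hook(log.accepted)


def generate_null_model(
    H: Hypergraph, config: NullModelConfig
) -> tuple[Hypergraph, SwapLog]:
    """Generate a null model of ``H`` by repeated swaps; ``H`` itself is untouched.

    Returns the randomized hypergraph and the :class:`SwapLog`.  If some
    swap exhausts the attempt budget before ``n_swaps`` swaps are accepted,
    a warning is emitted and the partial result is returned (all the
    model's preservation guarantees still hold on it).
    """
    if H.m < 1 or (config.model != "H1k-HED" and H.m < 2):
        raise ValueError(f"{config.model} needs at least 2 hyperedges")
    n_swaps = 10 * H.m if config.n_swaps is None else config.n_swaps
    rng = np.random.default_rng(config.rng_seed)
    state = _SwapState(H)
    log = SwapLog()
    _run_swaps(state, config, rng, log, n_swaps)
    if log.budget_exhausted:
        warnings.warn(
            f"{config.model}: attempt budget exhausted after {log.accepted} of "
            f"{n_swaps} accepted swaps; returning partial result"
        )
    return state.to_hypergraph(H.node_labels), log


# -- hierarchy verification ----------------------------------------------

_INVARIANT_MATRIX = {
    # model -> quantities it must preserve exactly
    "H0k": ("n", "m", "total_memberships"),
    "H1k-HD": ("n", "m", "total_memberships", "hyperdegree_vector"),
    "H1k-HED": ("n", "m", "total_memberships", "hyperedge_degree_vector"),
    "HD-HED": (
        "n", "m", "total_memberships",
        "hyperdegree_vector", "hyperedge_degree_vector",
    ),
    "H2k": (
        "n", "m", "total_memberships",
        "hyperdegree_vector", "hyperedge_degree_vector", "joint_signature",
    ),
    "H2.25k": (
        "n", "m", "total_memberships",
        "hyperdegree_vector", "hyperedge_degree_vector", "joint_signature",
        "mean_clustering",
    ),
}


def preserved_quantities(original: Hypergraph, null: Hypergraph,
                         cc_tolerance: float = 1e-12) -> dict[str, bool]:
    """Which candidate invariants a generated null model actually preserved."""
    from .stats import (
        hyperdegrees,
        hyperedge_degrees,
        joint_hyperdegree_signature,
        mean_clustering,
    )

    return {
        "n": original.n == null.n,
        "m": original.m == null.m,
        "total_memberships": sum(len(e) for e in original.hyperedges)
        == sum(len(e) for e in null.hyperedges),
        "hyperdegree_vector": np.array_equal(hyperdegrees(original), hyperdegrees(null)),
        "hyperedge_degree_vector": np.array_equal(
            hyperedge_degrees(original), hyperedge_degrees(null)
        ),
        "joint_signature": joint_hyperdegree_signature(original)
        == joint_hyperdegree_signature(null),
        "mean_clustering": abs(mean_clustering(original) - mean_clustering(null))
        <= cc_tolerance,
        "no_empty_hyperedge": all(len(e) > 0 for e in null.hyperedges),
    }


def hierarchy_check(H: Hypergraph, seed: int | None = None) -> dict[str, dict]:
    """Generate each model once and verify its preservation guarantees.

    Returns ``{model: {"preserved": {...}, "required": (...), "ok": bool}}``,
    where *required* lists the invariants the model's place in the
    containment hierarchy demands and *ok* says whether all of them (plus
    hyperedge non-emptiness) held on the generated instance.
    """
    report: dict[str, dict] = {}
    for k, model in enumerate(MODEL_NAMES):
        config = NullModelConfig(model=model, rng_seed=None if seed is None else seed + k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null, log = generate_null_model(H, config)
        preserved = preserved_quantities(H, null, config.cc_tolerance)
        required = _INVARIANT_MATRIX[model]
        report[model] = {
            "preserved": preserved,
            "required": required,
            "ok": all(preserved[q] for q in required) and preserved["no_empty_hyperedge"],
            "accepted_swaps": log.accepted,
        }
    return report
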