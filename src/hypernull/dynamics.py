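"""Dynamics on hypergraphs: dismantling and threshold SIR contagion.

Dismantling removes nodes (by descending hyperdegree) or hyperedges (by
descending hyperedge degree) one at a time, tracking the giant connected
component (GCC) of the projection until it falls below a target fraction of
the original node count; the cost summary is the GCC-AUC, the plain sum of
the recorded GCC fractions.

The contagion model is a discrete-time threshold SIR on the hypergraph:
a hyperedge becomes infectious once its infectious-member count passes the
threshold θ, and a susceptible node i is then infected with probability
β_i = 1 − exp(−β · n_all), where n_all totals the infectious members over
i's infectious hyperedges.  Infectious nodes recover independently with
probability γ per step; recovered nodes are immune.  The epidemic size is
the recovered fraction once no infectious node remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Hypergraph, giant_component_size
from .nullmodels import MODEL_NAMES, NullModelConfig, generate_null_model
from .stats import hyperdegrees, hyperedge_degrees


@dataclass
class DismantlingResult:
    """Removal order, GCC-fraction curve, stopping count and GCC-AUC."""

    removal_order: list[int]
    gcc_curve: list[float]
    n_removed: int
    auc: float


def _static_order(scores: np.ndarray) -> list[int]:
    # descending score, ties broken by ascending index
    return sorted(range(len(scores)), key=lambda i: (-scores[i], i))


def dismantle_by_nodes(H: Hypergraph, target_fraction: float = 0.01) -> DismantlingResult:
    """Remove nodes in descending-hyperdegree order until GCC < target_fraction · n.

    The ranking is computed once on the intact hypergraph (static
    strategy).  The GCC fraction after each removal is recorded; the AUC
    is the sum of those fractions.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    target = target_fraction * H.n
    order = _static_order(hyperdegrees(H))
    removed: set[int] = set()
    curve: list[float] = []
    taken: list[int] = []
    if giant_component_size(H) < target:
        return DismantlingResult(taken, curve, 0, 0.0)
    for i in order:
        removed.add(i)
        taken.append(i)
        gcc = giant_component_size(H, removed_nodes=removed)
        curve.append(gcc / H.n)
        if gcc < target:
            break
    return DismantlingResult(taken, curve, len(taken), float(sum(curve)))


def dismantle_by_hyperedges(
    H: Hypergraph, target_fraction: float = 0.01
) -> DismantlingResult:
    """Remove hyperedges in descending-degree order until GCC < target_fraction · n.

    Nodes losing all their hyperedges stay as isolated components of size
    1, so the GCC cannot drop below 1 and a warning is emitted when every
    hyperedge is gone without reaching the target.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    target = target_fraction * H.n
    order = _static_order(hyperedge_degrees(H))
    removed: set[int] = set()
    curve: list[float] = []
    taken: list[int] = []
    if giant_component_size(H) < target:
        return DismantlingResult(taken, curve, 0, 0.0)
    for j in order:
        removed.add(j)
        taken.append(j)
        gcc = giant_component_size(H, removed_hyperedges=removed)
        curve.append(gcc / H.n)
        if gcc < target:
            break
    else:
        warnings.warn(
            "all hyperedges removed without the GCC reaching the target size"
        )
    return DismantlingResult(taken, curve, len(taken), float(sum(curve)))


# -- threshold SIR -------------------------------------------------------

SEED_STRATEGIES = ("random", "degree", "hyperdegree")


@dataclass
class SIRConfig:
    """Parameters of the threshold SIR contagion experiment.

    ``theta_strict`` keeps the literal "exceeds θ" reading (count > θ);
    set it False for count ≥ θ.  ``nall_distinct`` switches n_all from
    summing infectious members over a node's infectious hyperedges with
    multiplicity (default) to counting distinct infectious neighbors.
    """

    beta: float
    gamma: float = 1.0
    theta: int = 5
    seed_fraction: float = 0.01
    seed_strategy: str = "random"
    n_runs: int = 100
    rng_seed: int | None = None
    theta_strict: bool = True
    nall_distinct: bool = False
    store_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if not 0 < self.seed_fraction <= 1:
            raise ValueError("seed_fraction must be in (0, 1]")
        if self.seed_strategy not in SEED_STRATEGIES:
            raise ValueError(
                f"unknown seed strategy {self.seed_strategy!r}; "
                f"valid: {', '.join(SEED_STRATEGIES)}"
            )


@dataclass
class SIRResult:
    """Recovered-fraction statistics over the independent runs."""

    recovered_fraction_mean: float
    recovered_fraction_sd: float
    per_run_fractions: np.ndarray
    trajectories: list[list[tuple[int, int, int]]] | None = None


def seed_selection(
    H: Hypergraph, strategy: str, count: int, rng: np.random.Generator
) -> set[int]:
    """Choose the initially infectious nodes.

    ``random``: uniform without replacement; ``degree``: top-count by
    projection degree; ``hyperdegree``: top-count by hyperdegree — ties
    broken by ascending node index.
    """
    if count > H.n:
        raise ValueError(f"cannot seed {count} nodes in a hypergraph of {H.n}")
    if strategy == "random":
        return set(rng.choice(H.n, size=count, replace=False).tolist())
    if strategy == "degree":
        from .core import projected_graph

        G = projected_graph(H)
        scores = np.array([G.degree(i) for i in range(H.n)])
    elif strategy == "hyperdegree":
        scores = hyperdegrees(H)
    else:
        raise ValueError(
            f"unknown seed strategy {strategy!r}; valid: {', '.join(SEED_STRATEGIES)}"
        )
    return set(_static_order(scores)[:count])


def _sir_single_run(H, config, seeds, rng, memberships):
    n = H.n
    S, I, R = 0, 1, 2
    state = np.zeros(n, dtype=np.int8)
    state[list(seeds)] = I
    traj = [] if config.store_trajectories else None
    while True:
        infectious = np.flatnonzero(state == I)
        if traj is not None:
            traj.append(
                (int((state == S).sum()), len(infectious), int((state == R).sum()))
            )
        if len(infectious) == 0:
            break
        inf_set = set(infectious.tolist())
        # infectious-member count per hyperedge; a hyperedge turns
        # infectious once that count passes the threshold
        counts = [len(e & inf_set) for e in H.hyperedges]
        if config.theta_strict:
            hot = [j for j, c in enumerate(counts) if c > config.theta]
        else:
            hot = [j for j, c in enumerate(counts) if c >= config.theta]
        hot_set = set(hot)
        newly_infected: list[int] = []
        if hot_set and config.beta > 0:
            for i in np.flatnonzero(state == S):
                mine = memberships[i] & hot_set
                if not mine:
                    continue
                if config.nall_distinct:
                    spreaders: set[int] = set()
                    for j in mine:
                        spreaders |= H.hyperedges[j] & inf_set
                    n_all = len(spreaders)
                else:
                    n_all = sum(counts[j] for j in mine)
                if rng.random() < 1.0 - np.exp(-config.beta * n_all):
                    newly_infected.append(i)
        # recovery is evaluated on the nodes infectious at step start;
        # a node infected this step cannot recover this step
        recovering = infectious[rng.random(len(infectious)) < config.gamma]
        state[recovering] = R
        state[newly_infected] = I
    return float((state == R).sum() / n), traj


def run_sir(H: Hypergraph, config: SIRConfig) -> SIRResult:
    """Run the threshold SIR contagion ``n_runs`` times and summarize.

    The number of seeds is ``max(1, round(seed_fraction · n))`` (with a
    warning when the fraction rounds below one node).  Each run draws its
    own RNG stream from ``rng_seed``; random seed sets are redrawn per
    run, ranked seed sets are fixed.
    """
    n_seeds = round(config.seed_fraction * H.n)
    if n_seeds < 1:
        warnings.warn("seed_fraction selects < 1 node; using a single seed")
        n_seeds = 1
    memberships = H.memberships()
    ss = np.random.SeedSequence(config.rng_seed)
    fractions = np.empty(config.n_runs)
    trajectories = [] if config.store_trajectories else None
    for run, child in enumerate(ss.spawn(config.n_runs)):
        rng = np.random.default_rng(child)
        seeds = seed_selection(H, config.seed_strategy, n_seeds, rng)
        frac, traj = _sir_single_run(H, config, seeds, rng, memberships)
        fractions[run] = frac
        if trajectories is not None:
            trajectories.append(traj)
    return SIRResult(
        recovered_fraction_mean=float(fractions.mean()),
        recovered_fraction_sd=float(fractions.std(ddof=0)),
        per_run_fractions=fractions,
        trajectories=trajectories,
    )


# -- orchestration -------------------------------------------------------


def compare_dynamics(
    H: Hypergraph,
    models: list[str],
    dynamic_spec: dict,
    rng_seed: int | None = None,
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """Run one dynamics experiment on the original network and/or its null models.

    ``models`` is a subset of the six model names plus ``"original"``;
    ``dynamic_spec`` is ``{"kind": "sir", "config": SIRConfig}`` or
    ``{"kind": "dismantle_nodes" | "dismantle_hyperedges",
    "target_fraction": float}``.  The same dynamics seed is used on every
    row so differences reflect the networks, not the noise.
    """
    valid = set(MODEL_NAMES) | {"original"}
    unknown = [m for m in models if m not in valid]
    if unknown:
        raise ValueError(f"unknown models: {unknown}; valid: {sorted(valid)}")
    kind = dynamic_spec["kind"]
    rows = []
    for k, name in enumerate(models):
        if name == "original":
            net = H
        else:
            config = NullModelConfig(
                model=name,
                n_swaps=n_swaps,
                rng_seed=None if rng_seed is None else rng_seed + 1 + k,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net, _ = generate_null_model(H, config)
        if kind == "sir":
            sir_config: SIRConfig = dynamic_spec["config"]
            if rng_seed is not None:
                sir_config = SIRConfig(**{**sir_config.__dict__, "rng_seed": rng_seed})
            res = run_sir(net, sir_config)
            rows.append(
                {
                    "network": name,
                    "recovered_fraction_mean": res.recovered_fraction_mean,
                    "recovered_fraction_sd": res.recovered_fraction_sd,
                }
            )
        elif kind in ("dismantle_nodes", "dismantle_hyperedges"):
            fn = dismantle_by_nodes if kind == "dismantle_nodes" else dismantle_by_hyperedges
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fn(net, dynamic_spec.get("target_fraction", 0.01))
            rows.append({"network": name, "n_removed": res.n_removed, "auc": res.auc})
        else:
            raise ValueError(f"unknown dynamic kind {kind!r}")
    return pd.DataFrame(rows).set_index("network")
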