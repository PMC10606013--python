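"""Hypergraph entropy and entropy-vs-swaps trajectories.

Randomness of a hypergraph is quantified through the Shannon entropy of its
hyperdegree distribution: with hyperdegrees d_1..d_n and an exponent t
(default 1),

    p_i = d_i^t / Σ_j d_j^t,     I(H) = −Σ_i p_i log p_i,

so 0 ≤ I(H) ≤ log n, with the maximum attained on hyperdegree-regular
hypergraphs.  Any generator that preserves the hyperdegree multiset
(H1k-HD, HD-HED, H2k, H2.25k) leaves I(H) unchanged; H0k and H1k-HED
redistribute memberships and drive I(H) toward a plateau as the number of
accepted swaps grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Hypergraph
from .nullmodels import MODEL_NAMES, NullModelConfig, SwapLog, _run_swaps, _SwapState


def hypergraph_entropy(H: Hypergraph, t: float = 1.0, base: float | None = None) -> float:
    """Shannon entropy of the (exponent-t) hyperdegree distribution, in nats.

    ``base`` switches the logarithm (e.g. 2 for bits); default natural log.
    """
    from .stats import hyperdegrees

    if H.n == 0:
        raise ValueError("entropy undefined for an empty hypergraph")
    return _entropy_of_degrees(hyperdegrees(H), t, base)


def _entropy_of_degrees(d: np.ndarray, t: float = 1.0, base: float | None = None) -> float:
    w = np.asarray(d, dtype=float) ** t
    p = w / w.sum()
    I = float(-(p * np.log(p)).sum())
    if base is not None:
        I /= math.log(base)
    return max(I, 0.0)


@dataclass
class EntropyCurve:
    """Mean/sd entropy across realizations at each swap-count checkpoint."""

    swap_counts: np.ndarray
    entropy_mean: np.ndarray
    entropy_sd: np.ndarray
    realizations: int

    def __post_init__(self) -> None:
        assert len(self.swap_counts) == len(self.entropy_mean) == len(self.entropy_sd)


def entropy_trajectory(
    H: Hypergraph,
    model: str,
    max_swaps: int | None = None,
    n_realizations: int = 10,
    checkpoints: np.ndarray | None = None,
    seed: int | None = None,
    t: float = 1.0,
) -> EntropyCurve:
    """Entropy of a null model as a function of the number of accepted swaps.

    Runs ``n_realizations`` independent generations of ``model`` and records
    I(H) at each checkpoint (default: 50 evenly spaced counts from 0 to
    ``max_swaps``, itself defaulting to 10·m).  If a realization's attempt
    budget runs out early, its entropy is carried flat to the remaining
    checkpoints (the chain is stuck, which is itself a plateau).
    """
    if model not in MODEL_NAMES:
        raise ValueError(
            f"unknown null model {model!r}; valid names: {', '.join(MODEL_NAMES)}"
        )
    if max_swaps is None:
        max_swaps = 10 * H.m
    if checkpoints is None:
        checkpoints = np.unique(np.linspace(0, max_swaps, 50).round().astype(int))
    else:
        checkpoints = np.asarray(checkpoints, dtype=int)
    ss = np.random.SeedSequence(seed)
    curves = np.empty((n_realizations, len(checkpoints)))
    for r, child in enumerate(ss.spawn(n_realizations)):
        rng = np.random.default_rng(child)
        config = NullModelConfig(model=model, n_swaps=max_swaps)
        state = _SwapState(H)
        entropies = {0: _entropy_of_degrees(state.hyperdegrees(), t)}
        targets = set(checkpoints.tolist())

        def hook(accepted: int, state=state, entropies=entropies, targets=targets):
            if accepted in targets:
                entropies[accepted] = _entropy_of_degrees(state.hyperdegrees(), t)

        _run_swaps(state, config, rng, SwapLog(), max_swaps, checkpoint_hook=hook)
        # fill checkpoints (flat-fill past an early stop)
        last = entropies[0]
        row = []
        for c in checkpoints:
            last = entropies.get(int(c), last)
            row.append(last)
        curves[r] = row
    return EntropyCurve(
        swap_counts=checkpoints,
        entropy_mean=curves.mean(axis=0),
        entropy_sd=curves.std(axis=0, ddof=0),
        realizations=n_realizations,
    )
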