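"""File formats and synthetic hypergraph generation.

Two on-disk formats are supported:

* **edgelist** — one hyperedge per line, node labels separated by
  whitespace or commas; ``#`` starts a comment.  Labels are kept as
  strings and round-trip verbatim.
* **simplex** — the two-file convention of the public hypergraph dataset
  repositories: ``<name>-nverts.txt`` holds each hyperedge's size, one per
  line, and ``<name>-simplices.txt`` the concatenated 1-based node ids.

The synthetic generator produces random hypergraphs with a chosen node
count, hyperedge count and hyperedge-size distribution; it stands in for
empirical datasets in tests and experiments.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Hypergraph, build_hypergraph

logger = logging.getLogger(__name__)

FORMATS = ("edgelist", "simplex")

_INT_RE = re.compile(r"[+-]?\d+")


def _simplex_paths(path: Path) -> tuple[Path, Path]:
    """Resolve the nverts/simplices pair from a prefix or either filename."""
    s = str(path)
    for suffix in ("-nverts.txt", "-simplices.txt"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
            break
    return Path(s + "-nverts.txt"), Path(s + "-simplices.txt")


def read_hypergraph(path: str | Path, format: str = "edgelist") -> Hypergraph:
    """Read a hypergraph from disk.

    ``format='edgelist'`` expects one hyperedge per line; ``'simplex'``
    accepts the dataset prefix or either of the two files of the pair.
    """
    path = Path(path)
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "simplex":
        return _read_simplex(path)
    raise ValueError(f"unknown format {format!r}; valid: {', '.join(FORMATS)}")


def _read_edgelist(path: Path) -> Hypergraph:
    raw: list[list] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "," in line:
                labels = [t.strip() for t in line.split(",") if t.strip()]
            else:
                labels = line.split()
            if not labels:
                raise ValueError(f"{path}:{lineno}: empty hyperedge")
            raw.append(labels)
    if not raw:
        raise ValueError(f"{path}: no hyperedges found")
    if all(_INT_RE.fullmatch(lab) for e in raw for lab in e):
        raw = [[int(lab) for lab in e] for e in raw]
    return build_hypergraph(raw)


def _read_simplex(path: Path) -> Hypergraph:
    nverts_path, simplices_path = _simplex_paths(path)
    nverts = [int(x) for x in nverts_path.read_text().split()]
    ids = [int(x) for x in simplices_path.read_text().split()]
    if sum(nverts) != len(ids):
        raise ValueError(
            f"inconsistent simplex files: sizes sum to {sum(nverts)} "
            f"but {len(ids)} node ids are given"
        )
    if not nverts:
        raise ValueError(f"{nverts_path}: no hyperedges found")
    raw, pos = [], 0
    for lineno, size in enumerate(nverts, start=1):
        if size < 1:
            raise ValueError(f"{nverts_path}:{lineno}: empty hyperedge")
        raw.append(ids[pos : pos + size])
        pos += size
    return build_hypergraph(raw)


def write_hypergraph(H: Hypergraph, path: str | Path, format: str = "edgelist") -> None:
    """Write a hypergraph; ``read_hypergraph(write_hypergraph(H))`` round-trips
    up to hyperedge order.

    Edgelist output is space-delimited unless some label contains
    whitespace, in which case commas are used; integer labels are parsed
    back as integers.  Simplex output writes
    1-based node indices (labels themselves are not representable in that
    format and survive only when they already are 1-based integers).
    """
    path = Path(path)
    if format == "edgelist":
        labels = [str(lab) for lab in H.node_labels]
        sep = ", " if any(" " in lab or "\t" in lab for lab in labels) else " "
        with open(path, "w") as fh:
            for e in H.hyperedges:
                fh.write(sep.join(labels[i] for i in sorted(e)) + "\n")
    elif format == "simplex":
        nverts_path, simplices_path = _simplex_paths(path)
        with open(nverts_path, "w") as nf, open(simplices_path, "w") as sf:
            for e in H.hyperedges:
                nf.write(f"{len(e)}\n")
                for i in sorted(e):
                    sf.write(f"{i + 1}\n")
    else:
        raise ValueError(f"unknown format {format!r}; valid: {', '.join(FORMATS)}")


# -- synthetic generation --------------------------------------------------


@dataclass
class SyntheticSpec:
    """Recipe for a random hypergraph.

    ``sizes`` is either an int (every hyperedge has that size) or a
    ``{size: probability}`` mapping.  ``node_weight_exponent`` biases
    member selection toward low-index nodes with weight ``(i+1)^-a``,
    producing heterogeneous (heavy-tailed) hyperdegrees for ``a > 0``;
    the default 0 keeps selection uniform.
    """

    n: int
    m: int
    sizes: int | dict[int, float] = 3
    rng_seed: int | None = None
    node_weight_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        if isinstance(self.sizes, int):
            if not 1 <= self.sizes <= self.n:
                raise ValueError("constant hyperedge size must lie in [1, n]")
        else:
            if not self.sizes or any(s < 1 for s in self.sizes):
                raise ValueError("size distribution must cover sizes >= 1")
            total = sum(self.sizes.values())
            if not np.isclose(total, 1.0):
                raise ValueError("size probabilities must sum to 1")


def generate_synthetic_hypergraph(spec: SyntheticSpec) -> Hypergraph:
    """Sample a random hypergraph: m hyperedges of sampled size, members
    drawn without replacement; uncovered nodes are appended to a random
    hyperedge so every node belongs somewhere.

    Sampled sizes exceeding n are resampled (capped at n after 100 tries,
    with a warning).  Node labels are ``0..n-1``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, m = spec.n, spec.m
    if isinstance(spec.sizes, int):
        sizes = np.full(m, spec.sizes, dtype=int)
    else:
        support = np.array(sorted(spec.sizes), dtype=int)
        probs = np.array([spec.sizes[s] for s in support], dtype=float)
        sizes = rng.choice(support, size=m, p=probs)
        for k in range(m):
            tries = 0
            while sizes[k] > n:
                if tries >= 100:
                    warnings.warn(f"sampled hyperedge size capped at n={n}")
                    sizes[k] = n
                    break
                sizes[k] = rng.choice(support, p=probs)
                tries += 1
    if spec.node_weight_exponent:
        w = (np.arange(1, n + 1, dtype=float)) ** (-spec.node_weight_exponent)
        p = w / w.sum()
    else:
        p = None
    edges = [
        set(rng.choice(n, size=int(s), replace=False, p=p).tolist()) for s in sizes
    ]
    covered = set().union(*edges)
    for i in range(n):
        if i not in covered:
            edges[int(rng.integers(m))].add(i)
    return Hypergraph(list(range(n)), edges)


def generate_path_hypergraph(n: int) -> Hypergraph:
    """Deterministic connected fixture: n-1 dyadic hyperedges wired as a path."""
    if n < 2:
        raise ValueError("a path needs at least 2 nodes")
    return Hypergraph(list(range(n)), [{i, i + 1} for i in range(n - 1)])


def toy_figure1_hypergraph() -> Hypergraph:
    """The 5-node, 4-hyperedge worked example used throughout the docs.

    A reconstruction satisfying every stated constraint of the original
    illustration (the full incidence matrix is not published): v1, v2, v3
    share e4; the triple (v1, v2, v5) forms a hypertriangle through the
    three distinct hyperedges e2, e3, e4; all hyperedges are non-empty and
    all five nodes are covered.  Not ground truth beyond those constraints.
    """
    return build_hypergraph(
        [
            ["v3", "v4"],        # e1
            ["v1", "v5"],        # e2
            ["v2", "v5"],        # e3
            ["v1", "v2", "v3"],  # e4
        ]
    )
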