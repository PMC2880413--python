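"""Random probabilistic networks and simulated quantized time series.

The simulator provides the ground truth for benchmarking: each gene in a
random directed network draws 1-3 parents, its dynamics are a conditional
probability table whose rows put a dominant mass (``determinism``) on one
level, and a trajectory is sampled from the induced Markov chain.  The
``determinism`` knob sets the signal-to-noise ratio of the data: 1.0 gives
a deterministic Boolean-style network, 1/q gives pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .mdl import LookupTable
from .preprocess import QuantizedMatrix

__all__ = ["SimConfig", "GeneNetwork", "generate_network", "simulate_timeseries"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings for random ground-truth networks.

    n genes, m time points; each gene draws between ``parents_min`` and
    ``parents_max`` distinct parents uniformly at random; every CPT row
    places probability ``determinism`` on one uniformly chosen level and
    splits the remainder evenly over the other q-1 levels.
    """

    n: int
    m: int = 50
    q: int = 2
    parents_min: int = 1
    parents_max: int = 3
    determinism: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 genes")
        if self.m < 2:
            raise ValueError("need at least 2 time points")
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if not 0 <= self.parents_min <= self.parents_max:
            raise ValueError("need 0 <= parents_min <= parents_max")
        if self.parents_max >= self.n:
            raise ValueError("parents_max must be smaller than n")
        if not (1.0 / self.q) < self.determinism <= 1.0:
            raise ValueError("determinism must lie in (1/q, 1]")


@dataclass
class GeneNetwork:
    """Ground-truth directed network with per-gene CPT dynamics."""

    n: int
    q: int
    cpts: list[LookupTable]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cpts) != self.n:
            raise ValueError("need one CPT per gene")
        if not self.gene_ids:
            self.gene_ids = [f"g{j + 1}" for j in range(self.n)]
        for j, cpt in enumerate(self.cpts):
            if j in cpt.parents:
                raise ValueError(f"self-loop on gene {j}")

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Directed (regulator, target) pairs."""
        return [(int(p), j) for j, cpt in enumerate(self.cpts) for p in cpt.parents]

    def connectivity(self) -> np.ndarray:
        conn = np.zeros((self.n, self.n), dtype=np.int8)
        for i, j in self.edges:
            conn[i, j] = 1
        return conn

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(
            (self.gene_ids[i], self.gene_ids[j]) for i, j in self.edges
        )
        return g


def generate_network(cfg: SimConfig) -> GeneNetwork:
    """Draw a random network: parent sets and CPTs, fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    q = cfg.q
    off = (1.0 - cfg.determinism) / (q - 1)
    cpts = []
    for j in range(cfg.n):
        k = int(rng.integers(cfg.parents_min, cfg.parents_max + 1))
        others = np.delete(np.arange(cfg.n), j)
        parents = tuple(sorted(int(p) for p in rng.choice(others, k, replace=False)))
        table = np.full((q**k, q), off)
        dominant = rng.integers(q, size=q**k)
        table[np.arange(q**k), dominant] = cfg.determinism
        cpts.append(LookupTable(gene=j, parents=parents, q=q, table=table))
    return GeneNetwork(n=cfg.n, q=q, cpts=cpts)


def simulate_timeseries(
    net: GeneNetwork, m: int, seed: int = 0
) -> QuantizedMatrix:
    """Sample one m-point trajectory of the network's Markov chain.

    The initial state is uniform over {0..q-1}^n; each later state is drawn
    gene-wise from the CPT rows selected by the previous state.
    """
    if m < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    q, n = net.q, net.n
    X = np.zeros((n, m), dtype=np.int64)
    X[:, 0] = rng.integers(q, size=n)
    cum = [np.cumsum(cpt.table, axis=1) for cpt in net.cpts]
    for t in range(1, m):
        prev = X[:, t - 1]
        u = rng.random(n)
        for j, cpt in enumerate(net.cpts):
            idx = 0
            for p in cpt.parents:
                idx = idx * q + prev[p]
            # clamp guards against cumulative sums a hair below 1.0
            X[j, t] = min(
                int(np.searchsorted(cum[j][idx], u[j], side="right")), q - 1
            )
    return QuantizedMatrix(X, q=q, gene_ids=list(net.gene_ids))
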