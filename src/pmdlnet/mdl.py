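"""Conditional probability tables and the predictive description length.

A candidate network assigns each gene a set of parents; its dynamics are the
factorized Markov chain p(X_{t+1} | X_t) = prod_i p(x_{i,t+1} | parents_i(t)),
with each per-gene conditional read from a look-up table estimated by
maximum likelihood from the observed transitions.  The predictive
description length of the data under a candidate is the accumulated code
length sum_t -log2 p(X_{t+1} | X_t) over the m-1 observed transitions; the
cost of the initial state is identical for all candidates and is omitted.
No model-coding term is added: candidates are compared by data length alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import QuantizedMatrix

__all__ = [
    "LookupTable",
    "CandidateModel",
    "DescriptionLength",
    "estimate_cpt",
    "transition_probability",
    "description_length",
]


@dataclass
class LookupTable:
    """Per-gene conditional probability table p(child value | parent state).

    Dense form (``states is None``): ``table`` has q^k rows (k = number of
    parents, row index encodes the parent state tuple with the first parent
    most significant) and q columns; rows whose parent state was never
    observed are NaN rather than fabricated.

    Sparse form: ``states`` lists the observed parent-state tuples and
    ``table`` holds one row per listed state.  This is how tables with huge
    q^k are represented — only the at most m-1 observed states ever carry
    probability mass, so nothing is lost.
    """

    gene: int
    parents: tuple[int, ...]
    q: int
    table: np.ndarray
    states: list[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent indices")
        t = np.asarray(self.table, dtype=float)
        k = len(self.parents)
        if self.states is None:
            if t.shape != (self.q**k, self.q):
                raise ValueError(
                    f"table shape {t.shape} != ({self.q**k}, {self.q})"
                )
        else:
            self.states = [tuple(int(s) for s in st) for st in self.states]
            if t.shape != (len(self.states), self.q):
                raise ValueError("sparse table needs one row per listed state")
            if any(len(st) != k for st in self.states):
                raise ValueError("state tuples must match the parent count")
            self._state_rows = {st: r for r, st in enumerate(self.states)}
            if len(self._state_rows) != len(self.states):
                raise ValueError("duplicate parent states")
        observed = ~np.isnan(t).any(axis=1)
        if np.any(t[observed] < 0) or np.any(t[observed] > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = t[observed].sum(axis=1)
        if observed.any() and np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("observed CPT rows must sum to 1")
        self.table = t

    def row_index(self, parent_state: Sequence[int]) -> int:
        """Dense row index of a parent state (first parent most significant)."""
        if len(parent_state) != len(self.parents):
            raise ValueError("parent_state length mismatch")
        idx = 0
        for s in parent_state:
            if not 0 <= s < self.q:
                raise ValueError(f"state symbol {s} outside alphabet")
            idx = idx * self.q + int(s)
        return idx

    def row(self, parent_state: Sequence[int]) -> np.ndarray:
        """The probability row of a parent state; errors if unobserved."""
        if self.states is None:
            row = self.table[self.row_index(parent_state)]
            if np.isnan(row).any():
                raise ValueError(
                    f"parent state {tuple(parent_state)} of gene {self.gene} "
                    "was never observed"
                )
            return row
        key = tuple(int(s) for s in parent_state)
        r = self._state_rows.get(key)
        if r is None:
            raise ValueError(
                f"parent state {key} of gene {self.gene} was never observed"
            )
        return self.table[r]

    def prob(self, parent_state: Sequence[int], value: int) -> float:
        """p(child = value | parents = parent_state); errors if unobserved."""
        return float(self.row(parent_state)[int(value)])


@dataclass
class CandidateModel:
    """A candidate network: binary connectivity plus one CPT per gene.

    ``connectivity[i, j] = 1`` means gene i regulates gene j; the parents
    recorded in each gene's CPT must match the corresponding column.
    ``mi_threshold`` records the MI cutoff that induced the structure, when
    there is one.
    """

    connectivity: np.ndarray
    cpts: list[LookupTable]
    mi_threshold: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.connectivity)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("connectivity must be square")
        if not np.isin(c, (0, 1)).all():
            raise ValueError("connectivity entries must be 0 or 1")
        if len(self.cpts) != c.shape[0]:
            raise ValueError("need one CPT per gene")
        for j, cpt in enumerate(self.cpts):
            expected = tuple(int(i) for i in np.nonzero(c[:, j])[0])
            if tuple(sorted(cpt.parents)) != expected:
                raise ValueError(
                    f"CPT parents {cpt.parents} of gene {j} do not match "
                    f"connectivity column {expected}"
                )
        self.connectivity = c.astype(np.int8)

    @property
    def n(self) -> int:
        return self.connectivity.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        return [
            (int(i), int(j)) for i, j in np.argwhere(self.connectivity == 1)
        ]


@dataclass(frozen=True)
class DescriptionLength:
    """Predictive description length in bits, with its per-gene split."""

    total: float
    per_gene: np.ndarray

    def __post_init__(self) -> None:
        pg = np.asarray(self.per_gene, dtype=float)
        object.__setattr__(self, "per_gene", pg)
        if abs(self.total - pg.sum()) > 1e-6:
            raise ValueError("total must equal the sum of per-gene terms")


def _parent_state_indices(
    data: np.ndarray, parents: tuple[int, ...], q: int
) -> np.ndarray:
    """Row index into the CPT for the parent state at each time 0..m-2."""
    m = data.shape[1]
    idx = np.zeros(m - 1, dtype=np.int64)
    for p in parents:
        idx = idx * q + data[p, : m - 1]
    return idx


# dense tables beyond this many rows switch to the sparse observed-state form
_DENSE_MAX_ROWS = 4096


def estimate_cpt(
    data: QuantizedMatrix,
    gene: int,
    parents: Sequence[int],
    *,
    max_cells: int | None = None,
) -> LookupTable:
    """Maximum-likelihood CPT of one gene given a parent set.

    Row (parent state s) and column (child value v) hold
    #{t : parents at t in state s, gene at t+1 equals v} / #{t : parents at
    t in state s} over the m-1 transitions; with no parents this is the
    marginal of the gene's values at times 2..m.  Unobserved parent states
    yield NaN rows in the dense form; large parent sets fall back to the
    sparse observed-state form.  ``max_cells`` refuses tables larger than
    the given cell budget instead of silently truncating.
    """
    parents = tuple(int(p) for p in parents)
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parent indices")
    X, q, m = data.values, data.q, data.m
    if m < 2:
        raise ValueError("need at least 2 time points to observe a transition")
    k = len(parents)
    n_rows = q**k
    if max_cells is not None and n_rows * q > max_cells:
        raise ValueError(
            f"CPT for gene {gene} needs {n_rows * q} cells, "
            f"exceeding the budget of {max_cells}"
        )
    child = X[gene, 1:]
    if n_rows <= _DENSE_MAX_ROWS:
        rows = _parent_state_indices(X, parents, q)
        counts = np.bincount(rows * q + child, minlength=n_rows * q).reshape(
            n_rows, q
        )
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            table = counts / row_tot
        table[row_tot[:, 0] == 0] = np.nan
        return LookupTable(gene=gene, parents=parents, q=q, table=table)
    # sparse path: count transitions keyed by the observed parent tuples
    P = X[list(parents), : m - 1]
    counts_by_state: dict[tuple[int, ...], np.ndarray] = {}
    for t in range(m - 1):
        key = tuple(int(s) for s in P[:, t])
        row = counts_by_state.setdefault(key, np.zeros(q))
        row[child[t]] += 1
    states = sorted(counts_by_state)
    table = np.vstack([counts_by_state[st] for st in states])
    table /= table.sum(axis=1, keepdims=True)
    return LookupTable(gene=gene, parents=parents, q=q, table=table, states=states)


def transition_probability(
    model: CandidateModel, state_t: Sequence[int], state_t1: Sequence[int]
) -> float:
    """One-step Markov transition probability p(X_{t+1} | X_t).

    The factorized product over genes of each CPT entry, parents read from
    ``state_t`` and child values from ``state_t1``.
    """
    state_t = np.asarray(state_t, dtype=int)
    state_t1 = np.asarray(state_t1, dtype=int)
    if state_t.shape != (model.n,) or state_t1.shape != (model.n,):
        raise ValueError("states must be n-vectors")
    prob = 1.0
    for j, cpt in enumerate(model.cpts):
        prob *= cpt.prob(state_t[list(cpt.parents)], state_t1[j])
    return prob


def description_length(
    data: QuantizedMatrix, model: CandidateModel
) -> DescriptionLength:
    """Predictive description length of the data under a candidate model.

    total = sum_{t=1}^{m-1} -log2 p(X_{t+1} | X_t), factorized per gene so
    the per-gene decomposition comes for free.  The model's CPTs must have
    been estimated from this same data, which guarantees every queried
    entry is positive (each observed transition contributes to its own
    count).
    """
    X, q, m = data.values, data.q, data.m
    per_gene = np.zeros(model.n)
    for j, cpt in enumerate(model.cpts):
        if cpt.states is None:
            rows = _parent_state_indices(X, cpt.parents, q)
            probs = cpt.table[rows, X[j, 1:]]
        else:
            P = X[list(cpt.parents), : m - 1]
            probs = np.array(
                [
                    cpt.prob(P[:, t], X[j, t + 1])
                    for t in range(m - 1)
                ]
            )
        assert not np.isnan(probs).any() and (probs > 0).all(), (
            "CPTs must be estimated from the scored data"
        )
        per_gene[j] = float(-np.log2(probs).sum())
    return DescriptionLength(total=float(per_gene.sum()), per_gene=per_gene)
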