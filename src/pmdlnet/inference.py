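"""Network inference: MI matrix, description-length threshold scan, CMI pruning.

The pipeline has three stages:

1. ``mi_matrix`` scores every ordered gene pair (i, j) by the time-lagged
   mutual information I(x_i(t); x_j(t+lag)).
2. ``select_threshold`` tries every distinct off-diagonal MI value as a
   cutoff delta; each cutoff induces a candidate network with edge set
   {(i, j) : M[i, j] >= delta}, whose CPTs are fitted by maximum likelihood
   and whose predictive description length is computed.  The cutoff with
   the shortest description length wins; ties (within 1e-9 bits) go to the
   largest cutoff, i.e. the sparsest of the equally short models.
3. ``cmi_prune`` removes edges that a third gene explains away: an edge
   x -> y is deleted when the minimum over conditioning genes z of the
   lagged conditional mutual information I(x_t; y_{t+1} | z_t) falls below
   the user threshold Th.

The scan is the expensive stage.  Because the candidate edge sets are
nested along the sorted cutoffs, each gene's parent set along the scan is a
prefix of its potential parents ordered by decreasing MI; the per-gene
description length is therefore computed once per distinct prefix and
reused across candidates, and the per-gene term itself is accumulated from
transition counts without materializing the (potentially huge) dense CPT.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mdl import CandidateModel, estimate_cpt
from .preprocess import QuantizedMatrix

__all__ = [
    "InferenceConfig",
    "InferenceReport",
    "mi_matrix",
    "threshold_candidates",
    "select_threshold",
    "cmi_prune",
    "edge_min_cmi",
    "apply_cmi_threshold",
    "infer_network",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


@dataclass
class InferenceConfig:
    """Tunable knobs of the inference pipeline.

    cmi_threshold
        Th, the pruning cutoff in bits; edges whose minimum conditional MI
        falls below it are deleted.  0.1-0.2 is the useful range for binary
        data.
    lag
        Time lag (in sampling steps) pairing regulators with targets.
    q
        Alphabet size of the quantized data.
    max_parents, max_table_cells
        Optional space-control caps: candidate cutoffs whose induced model
        gives some gene more than ``max_parents`` parents, or a CPT larger
        than ``max_table_cells`` cells, are skipped with a warning.
    include_empty_model
        Append one extra candidate above the largest MI value so the scan
        may also return the edgeless network.
    prune_conditioning
        "all" conditions each edge on every other gene; "parents" only on
        the other inferred regulators of the target.
    """

    cmi_threshold: float = 0.1
    lag: int = 1
    q: int = 2
    max_parents: int | None = None
    max_table_cells: int | None = None
    include_empty_model: bool = False
    prune_conditioning: str = "all"

    def __post_init__(self) -> None:
        if self.cmi_threshold < 0:
            raise ValueError("cmi_threshold must be >= 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.prune_conditioning not in ("all", "parents"):
            raise ValueError("prune_conditioning must be 'all' or 'parents'")


@dataclass
class InferenceReport:
    """Audit trail of one inference run."""

    selected_delta: float
    candidate_deltas: np.ndarray
    candidate_dls: np.ndarray
    skipped_candidates: int
    edges_before_pruning: list[tuple[int, int]]
    pruned_edges: list[tuple[int, int]]
    edge_stats: dict[tuple[int, int], dict]
    runtime_seconds: float = 0.0

    def to_dict(self) -> dict:
        return {
            "selected_delta": self.selected_delta,
            "candidate_deltas": [float(d) for d in self.candidate_deltas],
            "candidate_dls": [float(d) for d in self.candidate_dls],
            "skipped_candidates": self.skipped_candidates,
            "edges_before_pruning": [list(e) for e in self.edges_before_pruning],
            "pruned_edges": [list(e) for e in self.pruned_edges],
            "edge_stats": {
                f"{i}->{j}": stats for (i, j), stats in self.edge_stats.items()
            },
            "runtime_seconds": self.runtime_seconds,
        }


# ---------------------------------------------------------------------------
# stage 1: the MI matrix


def _entropy_from_codes(codes: np.ndarray, size: int) -> float:
    counts = np.bincount(codes, minlength=size)
    p = counts[counts > 0] / codes.size
    return float(-(p * np.log2(p)).sum())


def mi_matrix(data: QuantizedMatrix, lag: int = 1) -> np.ndarray:
    """n x n matrix of lagged MI values; entry (i, j) scores gene i -> j."""
    X, q, n, m = data.values, data.q, data.n, data.m
    if m <= lag:
        raise ValueError(f"need more than lag={lag} time points, got {m}")
    src = X[:, : m - lag] if lag else X
    tgt = X[:, lag:] if lag else X
    h_src = np.array([_entropy_from_codes(row, q) for row in src])
    h_tgt = np.array([_entropy_from_codes(row, q) for row in tgt])
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            h_joint = _entropy_from_codes(src[i] * q + tgt[j], q * q)
            M[i, j] = max(h_src[i] + h_tgt[j] - h_joint, 0.0)
    return M


def threshold_candidates(M: np.ndarray) -> np.ndarray:
    """Sorted unique off-diagonal MI values, ascending.

    Each value delta induces the candidate network with edges
    {(i, j) : i != j, M[i, j] >= delta}.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n == 1:
        return np.empty(0)
    off = M[~np.eye(n, dtype=bool)]
    return np.unique(off)


# ---------------------------------------------------------------------------
# stage 2: description-length scan


def _prefix_dl(child_next: np.ndarray, parent_block: np.ndarray, q: int) -> float:
    """Description length of one gene given a parent block (k x (m-1)).

    Equals sum over observed (parent state s, child value v) of
    -N(s, v) log2(N(s, v) / N(s)); works from transition counts keyed by
    the observed parent states only, so arbitrarily large parent sets cost
    O(m) space.
    """
    m1 = child_next.size
    if parent_block.shape[0] == 0:
        state_ids = np.zeros(m1, dtype=np.int64)
        n_states = 1
    else:
        _, state_ids = np.unique(parent_block.T, axis=0, return_inverse=True)
        state_ids = state_ids.astype(np.int64).ravel()
        n_states = int(state_ids.max()) + 1
    counts = np.bincount(state_ids * q + child_next, minlength=n_states * q)
    counts = counts.reshape(n_states, q)
    row_tot = counts.sum(axis=1)
    nz = counts > 0
    ratio = counts[nz] / np.repeat(row_tot, q).reshape(n_states, q)[nz]
    return float(-(counts[nz] * np.log2(ratio)).sum())


def select_threshold(
    data: QuantizedMatrix, M: np.ndarray, cfg: InferenceConfig | None = None
) -> tuple[float, CandidateModel]:
    """Pick the MI cutoff whose induced model has the shortest description length.

    Every distinct off-diagonal MI value is tried as cutoff delta; the
    induced model's CPTs are fitted from the data and scored by predictive
    description length.  Returns the winning delta and its fitted model.
    Ties within 1e-9 bits resolve to the largest delta (sparsest model).
    """
    cfg = cfg or InferenceConfig()
    X, q, n, m = data.values, data.q, data.n, data.m
    cands = threshold_candidates(M)
    if cfg.include_empty_model and cands.size:
        cands = np.append(cands, cands[-1] + 1.0)
    if cands.size == 0:
        # single gene: only the empty model exists
        model = CandidateModel(
            connectivity=np.zeros((n, n), dtype=np.int8),
            cpts=[estimate_cpt(data, j, ()) for j in range(n)],
            mi_threshold=0.0,
        )
        return 0.0, model

    child = X[:, 1:]
    totals = np.zeros(cands.size)
    valid = np.ones(cands.size, dtype=bool)
    for j in range(n):
        col = np.delete(M[:, j], j)
        others = np.delete(np.arange(n), j)
        order = others[np.argsort(-col, kind="stable")]
        col_sorted = np.sort(col)  # ascending
        # number of parents of gene j at each candidate cutoff
        r = col.size - np.searchsorted(col_sorted, cands, side="left")
        if cfg.max_parents is not None:
            valid &= r <= cfg.max_parents
        if cfg.max_table_cells is not None:
            budget = math.log(cfg.max_table_cells) / math.log(q) - 1
            valid &= r <= budget
        dl_by_r: dict[int, float] = {}
        for rv in np.unique(r):
            dl_by_r[int(rv)] = _prefix_dl(child[j], X[order[:rv], : m - 1], q)
        totals += np.array([dl_by_r[int(rv)] for rv in r])

    skipped = int((~valid).sum())
    if skipped:
        logger.warning(
            "%d candidate cutoffs skipped (parent/table budget)", skipped
        )
    if not valid.any():
        raise ValueError("every candidate cutoff exceeded the size budgets")
    totals_masked = np.where(valid, totals, np.inf)
    best = totals_masked.min()
    # ties within tolerance -> largest delta = sparsest model
    idx = int(np.nonzero(totals_masked <= best + _TIE_TOL)[0][-1])
    delta = float(cands[idx])

    conn = ((M >= delta) & ~np.eye(n, dtype=bool)).astype(np.int8)
    cpts = [
        estimate_cpt(
            data,
            j,
            tuple(np.nonzero(conn[:, j])[0]),
            max_cells=cfg.max_table_cells,
        )
        for j in range(n)
    ]
    model = CandidateModel(connectivity=conn, cpts=cpts, mi_threshold=delta)
    model._scan_deltas = cands  # type: ignore[attr-defined]
    model._scan_dls = totals_masked  # type: ignore[attr-defined]
    model._scan_skipped = skipped  # type: ignore[attr-defined]
    return delta, model


# ---------------------------------------------------------------------------
# stage 3: CMI pruning


def _lagged_cmi_fast(
    xs: np.ndarray, yt: np.ndarray, zs: np.ndarray, q: int
) -> float:
    """I(x_t; y_{t+lag} | z_t) from pre-lagged symbol arrays, in bits."""
    h_z = _entropy_from_codes(zs, q)
    h_xz = _entropy_from_codes(xs * q + zs, q * q)
    h_yz = _entropy_from_codes(yt * q + zs, q * q)
    h_xyz = _entropy_from_codes((xs * q + yt) * q + zs, q * q * q)
    return max(h_xz + h_yz - h_z - h_xyz, 0.0)


def edge_min_cmi(
    data: QuantizedMatrix,
    connectivity: np.ndarray,
    cfg: InferenceConfig | None = None,
) -> dict[tuple[int, int], float | None]:
    """Minimum lagged CMI over conditioning genes, for every edge.

    Returns ``None`` for edges with no eligible conditioning gene (e.g. in
    a 2-gene network, or "parents" mode with a single regulator).
    """
    cfg = cfg or InferenceConfig()
    X, q, m = data.values, data.q, data.m
    lag = cfg.lag
    src = X[:, : m - lag] if lag else X
    tgt = X[:, lag:] if lag else X
    out: dict[tuple[int, int], float | None] = {}
    for i, j in np.argwhere(np.asarray(connectivity) == 1):
        i, j = int(i), int(j)
        if cfg.prune_conditioning == "parents":
            zs = [int(z) for z in np.nonzero(connectivity[:, j])[0]]
        else:
            zs = list(range(X.shape[0]))
        zs = [z for z in zs if z not in (i, j)]
        if not zs:
            out[(i, j)] = None
            continue
        out[(i, j)] = min(
            _lagged_cmi_fast(src[i], tgt[j], src[z], q) for z in zs
        )
    return out


def apply_cmi_threshold(
    connectivity: np.ndarray,
    min_cmi: dict[tuple[int, int], float | None],
    threshold: float,
) -> np.ndarray:
    """Delete edges whose minimum CMI is below the threshold.

    Edges with no eligible conditioning gene are kept.  One pass against
    the pre-pruning connectivity, so the result is order-independent.
    """
    pruned = np.asarray(connectivity).astype(np.int8).copy()
    for (i, j), value in min_cmi.items():
        if value is not None and value < threshold:
            pruned[i, j] = 0
    return pruned


def cmi_prune(
    data: QuantizedMatrix,
    model: CandidateModel,
    cfg: InferenceConfig | None = None,
) -> np.ndarray:
    """Remove indirect edges by thresholding the minimum lagged CMI.

    For each edge x -> y, I(x_t; y_{t+lag} | z_t) is evaluated for every
    eligible conditioning gene z; the edge is deleted when the minimum is
    below ``cfg.cmi_threshold``.  Never adds edges.
    """
    cfg = cfg or InferenceConfig()
    min_cmi = edge_min_cmi(data, model.connectivity, cfg)
    return apply_cmi_threshold(model.connectivity, min_cmi, cfg.cmi_threshold)


# ---------------------------------------------------------------------------
# the full pipeline


def infer_network(
    data: QuantizedMatrix, cfg: InferenceConfig | None = None
) -> tuple[np.ndarray, InferenceReport]:
    """Run the full pipeline: MI matrix -> cutoff scan -> CMI pruning.

    Returns the inferred binary connectivity matrix (entry (i, j) = 1 means
    gene i regulates gene j; no self-loops) and a report carrying the
    selected cutoff, the per-candidate description lengths, per-edge MI and
    minimum-CMI statistics, and the pruned edges.
    """
    cfg = cfg or InferenceConfig()
    t0 = time.perf_counter()
    M = mi_matrix(data, lag=cfg.lag)
    delta, model = select_threshold(data, M, cfg)
    min_cmi = edge_min_cmi(data, model.connectivity, cfg)
    pruned_conn = apply_cmi_threshold(
        model.connectivity, min_cmi, cfg.cmi_threshold
    )
    before = model.edges()
    after = {tuple(e) for e in np.argwhere(pruned_conn == 1)}
    pruned_edges = [e for e in before if e not in after]
    stats = {
        (i, j): {
            "mi": float(M[i, j]),
            "min_cmi": None if min_cmi[(i, j)] is None else float(min_cmi[(i, j)]),
            "kept": (i, j) in after,
        }
        for (i, j) in before
    }
    report = InferenceReport(
        selected_delta=delta,
        candidate_deltas=getattr(model, "_scan_deltas", np.empty(0)),
        candidate_dls=getattr(model, "_scan_dls", np.empty(0)),
        skipped_candidates=getattr(model, "_scan_skipped", 0),
        edges_before_pruning=before,
        pruned_edges=pruned_edges,
        edge_stats=stats,
        runtime_seconds=time.perf_counter() - t0,
    )
    return pruned_conn, report
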