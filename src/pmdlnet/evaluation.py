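"""Precision/recall scoring and the synthetic benchmarking experiments.

Scoring is exact set arithmetic on directed edges: Ce edges present in both
truth and inference, Me edges missed, Fe edges invented; precision is
Ce/(Ce+Fe) and recall Ce/(Ce+Me).  A reversed edge counts once as missed
and once as false.  Degenerate denominators yield ``None`` (reported as NaN
in tables and excluded from averages) rather than a silent zero.

Two experiment drivers reproduce the standard benchmarks:

* ``pr_curve_experiment`` — random networks of several sizes, inferred at
  several CMI thresholds, averaged over seeded replicates.  The MI-cutoff
  scan does not depend on the CMI threshold, so each replicate is inferred
  once and re-pruned per threshold.
* ``data_size_experiment`` — one network, one long trajectory, inference on
  growing prefixes to chart how performance scales with the number of time
  points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import (
    InferenceConfig,
    apply_cmi_threshold,
    edge_min_cmi,
    mi_matrix,
    select_threshold,
)
from .netsim import GeneNetwork, SimConfig, generate_network, simulate_timeseries
from .preprocess import QuantizedMatrix

__all__ = [
    "PRScore",
    "score",
    "pr_curve_experiment",
    "data_size_experiment",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRScore:
    """Directed-edge confusion counts with derived precision and recall."""

    ce: int  # edges in both truth and inference
    me: int  # edges only in truth (missed)
    fe: int  # edges only in inference (false)

    @property
    def precision(self) -> float | None:
        return None if self.ce + self.fe == 0 else self.ce / (self.ce + self.fe)

    @property
    def recall(self) -> float | None:
        return None if self.ce + self.me == 0 else self.ce / (self.ce + self.me)


def _edge_set(obj) -> tuple[int, set[tuple[int, int]]]:
    if isinstance(obj, GeneNetwork):
        return obj.n, set(obj.edges)
    conn = np.asarray(obj)
    if conn.ndim != 2 or conn.shape[0] != conn.shape[1]:
        raise ValueError("connectivity must be a square matrix")
    return conn.shape[0], {tuple(map(int, e)) for e in np.argwhere(conn == 1)}


def score(truth, inferred) -> PRScore:
    """Score an inferred connectivity against the ground-truth network."""
    n_t, true_edges = _edge_set(truth)
    n_i, inf_edges = _edge_set(inferred)
    if n_t != n_i:
        raise ValueError(f"gene sets differ: {n_t} vs {n_i} genes")
    ce = len(true_edges & inf_edges)
    return PRScore(
        ce=ce, me=len(true_edges) - ce, fe=len(inf_edges) - ce
    )


def _replicate_seeds(base_seed: int, *context: int) -> tuple[int, int]:
    """Two independent sub-seeds (network, trajectory), each below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, context)])
    net_seed, data_seed = ss.generate_state(2) % (2**31)
    return int(net_seed), int(data_seed)


def _infer_once(data: QuantizedMatrix, cfg: InferenceConfig):
    """Shared inference stages: MI matrix, cutoff scan, per-edge min CMI."""
    M = mi_matrix(data, lag=cfg.lag)
    _, model = select_threshold(data, M, cfg)
    min_cmi = edge_min_cmi(data, model.connectivity, cfg)
    return model, min_cmi


def pr_curve_experiment(
    sizes: Sequence[int] = (20, 30, 40, 50),
    thresholds: Sequence[float] = (0.1, 0.15, 0.2),
    replicates: int = 10,
    m: int = 50,
    base_seed: int = 0,
    sim_overrides: dict | None = None,
    inference_cfg: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Precision/recall over network sizes and CMI thresholds.

    For every (size, replicate) a fresh network and trajectory are drawn
    from seeds derived from ``base_seed``; the same replicate is scored at
    every threshold, so threshold comparisons are paired.  Returns a tidy
    frame with one row per (n, Th, replicate).
    """
    sim_overrides = sim_overrides or {}
    cfg = inference_cfg or InferenceConfig()
    rows = []
    for n in sizes:
        for rep in range(replicates):
            net_seed, data_seed = _replicate_seeds(base_seed, n, rep)
            sim = SimConfig(n=n, m=m, seed=net_seed, **sim_overrides)
            net = generate_network(sim)
            data = simulate_timeseries(net, m, seed=data_seed)
            model, min_cmi = _infer_once(data, cfg)
            for th in thresholds:
                conn = apply_cmi_threshold(model.connectivity, min_cmi, th)
                s = score(net, conn)
                rows.append(
                    {
                        "n": n,
                        "m": m,
                        "Th": th,
                        "replicate": rep,
                        "seed": net_seed,
                        "Ce": s.ce,
                        "Me": s.me,
                        "Fe": s.fe,
                        "precision": np.nan if s.precision is None else s.precision,
                        "recall": np.nan if s.recall is None else s.recall,
                    }
                )
    return pd.DataFrame(rows)


def data_size_experiment(
    max_m: int = 75,
    start: int = 15,
    step: int = 5,
    n: int = 20,
    base_seed: int = 0,
    sim_overrides: dict | None = None,
    inference_cfg: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Performance vs data size on growing prefixes of one trajectory.

    One network and one ``max_m``-point trajectory are generated; inference
    runs on the first ``start``, ``start + step``, ... time points (13 runs
    at the defaults).  The recall/precision ratio is reported per run.
    """
    if max_m < start:
        raise ValueError("max_m must be >= start")
    sim_overrides = sim_overrides or {}
    cfg = inference_cfg or InferenceConfig()
    net_seed, data_seed = _replicate_seeds(base_seed, n, max_m)
    sim = SimConfig(n=n, m=max_m, seed=net_seed, **sim_overrides)
    net = generate_network(sim)
    data = simulate_timeseries(net, max_m, seed=data_seed)
    rows = []
    for mp in range(start, max_m + 1, step):
        prefix = QuantizedMatrix(
            data.values[:, :mp], q=data.q, gene_ids=list(data.gene_ids)
        )
        model, min_cmi = _infer_once(prefix, cfg)
        conn = apply_cmi_threshold(model.connectivity, min_cmi, cfg.cmi_threshold)
        s = score(net, conn)
        p = np.nan if s.precision is None else s.precision
        r = np.nan if s.recall is None else s.recall
        rows.append(
            {
                "n": n,
                "m": mp,
                "Th": cfg.cmi_threshold,
                "seed": net_seed,
                "Ce": s.ce,
                "Me": s.me,
                "Fe": s.fe,
                "precision": p,
                "recall": r,
                "recall_precision_ratio": r / p if p and p > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, by: Iterable[str] = ("n", "Th")) -> pd.DataFrame:
    """Mean precision/recall per group, NaN (degenerate) replicates excluded."""
    degenerate = int(results[["precision", "recall"]].isna().any(axis=1).sum())
    if degenerate:
        logger.info("%d replicates had a degenerate precision or recall", degenerate)
    return (
        results.groupby(list(by))[["precision", "recall"]]
        .mean()
        .reset_index()
        .rename(columns={"precision": "mean_precision", "recall": "mean_recall"})
    )
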