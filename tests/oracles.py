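"""Independent brute-force oracles used to cross-check the estimators.

These deliberately avoid the code paths they verify: probabilities come
from explicit counting over symbol tuples and sums run over the full
alphabet product.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def joint_counts(seqs, q: int) -> dict[tuple, int]:
    counts: dict[tuple, int] = {}
    for tup in zip(*seqs):
        key = tuple(int(v) for v in tup)
        counts[key] = counts.get(key, 0) + 1
    return counts


def entropy_bruteforce(seqs, q: int) -> float:
    m = len(seqs[0])
    h = 0.0
    for c in joint_counts(seqs, q).values():
        p = c / m
        h -= p * math.log2(p)
    return h


def mi_bruteforce(x, y, q: int) -> float:
    """Direct double sum over the alphabet: sum p(x,y) log p(x,y)/(p(x)p(y))."""
    m = len(x)
    jc = joint_counts([x, y], q)
    px = joint_counts([x], q)
    py = joint_counts([y], q)
    total = 0.0
    for (a, b), c in jc.items():
        pxy = c / m
        total += pxy * math.log2(pxy / ((px[(a,)] / m) * (py[(b,)] / m)))
    return total


def cmi_bruteforce(x, y, z, q: int) -> float:
    """Triple sum: sum p(x,y,z) log [p(z) p(x,y,z) / (p(x,z) p(y,z))]."""
    m = len(x)
    jxyz = joint_counts([x, y, z], q)
    jxz = joint_counts([x, z], q)
    jyz = joint_counts([y, z], q)
    jz = joint_counts([z], q)
    total = 0.0
    for (a, b, c), cnt in jxyz.items():
        pxyz = cnt / m
        pz = jz[(c,)] / m
        pxz = jxz[(a, c)] / m
        pyz = jyz[(b, c)] / m
        total += pxyz * math.log2(pz * pxyz / (pxz * pyz))
    return total


def transition_prob_bruteforce(data: np.ndarray, parents, q: int, t: int, j: int) -> float:
    """p(x_j at t+1 | parent state at t) by explicit transition counting."""
    m = data.shape[1]
    state = tuple(data[list(parents), t])
    num = den = 0
    for s in range(m - 1):
        if tuple(data[list(parents), s]) == state:
            den += 1
            if data[j, s + 1] == data[j, t + 1]:
                num += 1
    return num / den


def description_length_bruteforce(data: np.ndarray, parents_per_gene, q: int) -> float:
    """Sum over transitions of -log2 p(X_{t+1}|X_t), with the per-gene
    factorized transition probabilities recounted from scratch."""
    n, m = data.shape
    total = 0.0
    for t in range(m - 1):
        p = 1.0
        for j in range(n):
            p *= transition_prob_bruteforce(data, parents_per_gene[j], q, t, j)
        total -= math.log2(p)
    return total
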