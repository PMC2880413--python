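"""Plug-in information-theoretic estimators on discrete sequences.

All quantities are computed in bits (log base 2) from empirical frequency
(maximum-likelihood) probability mass functions, with no smoothing.  The
time-lagged variants pair regulator values at time ``t`` with target values
at ``t + lag`` to give mutual information a direction, which is how edge
orientation enters the network-inference pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pmf",
    "LagPairing",
    "estimate_pmf",
    "entropy",
    "mutual_information",
    "lagged_mi",
    "cmi",
    "lagged_cmi",
]

# Tiny negative residue from floating-point cancellation is clamped to zero;
# anything more negative indicates a programming error and is let through.
_NEG_TOL = 1e-12


@dataclass(frozen=True)
class Pmf:
    """Empirical probability mass function over tuples from alphabet {0..q-1}.

    ``probabilities`` has one axis per variable (1 to 3 axes), each of
    length ``q``.
    """

    probabilities: np.ndarray
    q: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim < 1 or p.ndim > 3:
            raise ValueError("Pmf supports 1- to 3-variable joints")
        if any(s != self.q for s in p.shape):
            raise ValueError(f"Pmf axes must all have length q={self.q}")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        total = float(p.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")

    @property
    def n_variables(self) -> int:
        return self.probabilities.ndim


@dataclass(frozen=True)
class LagPairing:
    """Pairing rule for lagged estimators: source at t vs target at t+lag."""

    lag: int = 1

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


def _as_symbols(seq, q: int) -> np.ndarray:
    a = np.asarray(seq)
    if a.ndim != 1:
        raise ValueError("sequences must be one-dimensional")
    a = a.astype(np.intp)
    if a.size and (a.min() < 0 or a.max() >= q):
        raise ValueError(f"symbols must lie in {{0..{q - 1}}}")
    return a


def estimate_pmf(*sequences, q: int) -> Pmf:
    """Empirical joint PMF of one to three aligned discrete sequences.

    Each cell holds (number of positions with that symbol tuple) / length.
    """
    if not 1 <= len(sequences) <= 3:
        raise ValueError("estimate_pmf takes one to three sequences")
    arrs = [_as_symbols(s, q) for s in sequences]
    m = arrs[0].size
    if m == 0:
        raise ValueError("sequences must be non-empty")
    if any(a.size != m for a in arrs):
        raise ValueError("sequences must have equal length")
    code = arrs[0]
    for a in arrs[1:]:
        code = code * q + a
    k = len(arrs)
    counts = np.bincount(code, minlength=q**k).reshape((q,) * k)
    return Pmf(counts / m, q=q)


def entropy(p: Pmf) -> float:
    """Shannon entropy H = -sum p log2 p in bits, with 0 log 0 := 0."""
    probs = p.probabilities[p.probabilities > 0]
    return float(-(probs * np.log2(probs)).sum())


def _clamp(value: float) -> float:
    if abs(value) < _NEG_TOL:
        return 0.0
    if value < 0:
        raise AssertionError(f"plug-in estimate unexpectedly negative: {value}")
    return value


def _seq_entropy(*sequences, q: int) -> float:
    return entropy(estimate_pmf(*sequences, q=q))


def mutual_information(x, y, q: int) -> float:
    """Plug-in mutual information I(X;Y) = H(X) + H(Y) - H(X,Y) in bits."""
    x = _as_symbols(x, q)
    y = _as_symbols(y, q)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    return _clamp(
        _seq_entropy(x, q=q) + _seq_entropy(y, q=q) - _seq_entropy(x, y, q=q)
    )


def _lag_of(lag) -> int:
    return lag.lag if isinstance(lag, LagPairing) else int(lag)


def lagged_mi(x, y, lag=1, *, q: int) -> float:
    """Time-lagged MI: I(X_t; Y_{t+lag}).  Scores the directed edge x -> y."""
    ell = _lag_of(lag)
    x = _as_symbols(x, q)
    y = _as_symbols(y, q)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size <= ell:
        raise ValueError(f"need length > lag ({ell}), got {x.size}")
    if ell == 0:
        return mutual_information(x, y, q)
    return mutual_information(x[:-ell], y[ell:], q)


def cmi(x, y, z, q: int) -> float:
    """Conditional mutual information I(X;Y|Z) from joint entropies.

    Computed as H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z); non-negative for any
    empirical joint.
    """
    x = _as_symbols(x, q)
    y = _as_symbols(y, q)
    z = _as_symbols(z, q)
    if not (x.size == y.size == z.size):
        raise ValueError("sequences must have equal length")
    return _clamp(
        _seq_entropy(x, z, q=q)
        + _seq_entropy(y, z, q=q)
        - _seq_entropy(z, q=q)
        - _seq_entropy(x, y, z, q=q)
    )


def lagged_cmi(x, y, z, lag=1, *, q: int) -> float:
    """Time-lagged CMI: I(X_t; Y_{t+lag} | Z_t).

    Near-zero values for an edge x -> y, minimized over candidate
    confounders z, flag the edge as indirect.
    """
    ell = _lag_of(lag)
    x = _as_symbols(x, q)
    y = _as_symbols(y, q)
    z = _as_symbols(z, q)
    if not (x.size == y.size == z.size):
        raise ValueError("sequences must have equal length")
    if x.size <= ell:
        raise ValueError(f"need length > lag ({ell}), got {x.size}")
    if ell == 0:
        return cmi(x, y, z, q)
    return cmi(x[:-ell], y[ell:], z[:-ell], q)
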