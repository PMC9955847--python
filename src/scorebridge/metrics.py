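"""Wasserstein-1 distances between empirical distributions.

The Euclidean-cost optimal-transport distance is computed exactly: by the
sorted-sample closed form in one dimension, by an optimal assignment for
equal-size uniformly weighted samples, and by the transport linear program
for the general weighted / unequal-size case.  An optional size cap keeps
the LP tractable on large sample sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance as _w1_1d

__all__ = ["EmpiricalDistribution", "wasserstein1", "mode_coverage"]


@dataclass
class EmpiricalDistribution:
    """Samples ``[N, D]`` with optional weights summing to one."""

    samples: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if s.size == 0:
            raise ValueError("empty distribution")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        self.samples = s
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (s.shape[0],) or np.any(w < 0):
                raise ValueError("weights must be nonnegative, one per sample")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")
            self.weights = w

    @property
    def n(self):
        return self.samples.shape[0]

    @property
    def dim(self):
        return self.samples.shape[1]

    def effective_weights(self):
        if self.weights is not None:
            return self.weights
        return np.full(self.n, 1.0 / self.n)


def _as_dist(x):
    return x if isinstance(x, EmpiricalDistribution) else EmpiricalDistribution(np.asarray(x))


def _w1_lp(X, Y, wx, wy):
    """Exact transport LP: min <C, P> s.t. row/col marginals."""
    n, m = X.shape[0], Y.shape[0]
    C = cdist(X, Y).ravel()
    A_rows = sparse.csr_matrix(
        (np.ones(n * m), (np.repeat(np.arange(n), m), np.arange(n * m))),
        shape=(n, n * m))
    cols_idx = np.tile(np.arange(m), n)
    A_cols = sparse.csr_matrix((np.ones(n * m), (cols_idx, np.arange(n * m))),
                               shape=(m, n * m))
    # drop one redundant constraint for numerical stability
    A_eq = sparse.vstack([A_rows, A_cols[:-1]])
    b_eq = np.concatenate([wx, wy[:-1]])
    res = linprog(C, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP should always be feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def wasserstein1(a, b, max_points=2000, rng_seed=0):
    """Exact W1 (earth mover's distance) between two empirical measures.

    Parameters
    ----------
    a, b : arrays ``[N, D]`` or :class:`EmpiricalDistribution`
    max_points : int
        Uniformly weighted inputs larger than this are subsampled (seeded)
        before solving, bounding the LP/assignment cost.
    """
    da, db = _as_dist(a), _as_dist(b)
    if da.dim != db.dim:
        raise ValueError(f"dimension mismatch: {da.dim} vs {db.dim}")

    rng = np.random.default_rng(rng_seed)
    Xa, Xb = da.samples, db.samples
    if da.weights is None and da.n > max_points:
        Xa = Xa[rng.choice(da.n, size=max_points, replace=False)]
    if db.weights is None and db.n > max_points:
        Xb = Xb[rng.choice(db.n, size=max_points, replace=False)]

    if da.dim == 1:
        return float(_w1_1d(Xa[:, 0], Xb[:, 0],
                            da.weights, db.weights))
    if da.weights is None and db.weights is None and Xa.shape[0] == Xb.shape[0]:
        C = cdist(Xa, Xb)
        r, c = linear_sum_assignment(C)
        return float(C[r, c].mean())
    return _w1_lp(Xa, Xb, da.effective_weights(), db.effective_weights())


def mode_coverage(samples, mode_centers):
    """Fraction of samples nearest (Euclidean) to each mode centre."""
    s = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    c = np.atleast_2d(np.asarray(mode_centers, dtype=np.float64))
    nearest = cdist(s, c).argmin(axis=1)
    counts = np.bincount(nearest, minlength=c.shape[0])
    return counts / s.shape[0]
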