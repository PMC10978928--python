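"""Non-metric multidimensional scaling (Kruskal) of a dissimilarity matrix.

The embedding of the phylobetadiversity turnover matrix provides the
continuous "biogeographic isolation" coordinate system: cells that share
little evolutionary history sit far apart.  Configuration quality is
measured by Kruskal's stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 )

over unordered pairs, where dhat are least-squares monotone (isotonic)
fits of the configuration distances on the dissimilarity order.  Tied
dissimilarities are averaged within tie blocks before the pool-adjacent-
violators pass.

Each start alternates a monotone-regression step with a Guttman (SMACOF
majorization) update; the recorded stress trace is non-increasing within a
start because an update that would raise stress terminates the start at the
previous configuration.  The first start is the classical (metric) scaling
of the input; the remaining starts are seeded random configurations.  The
best solution is centered and rotated to principal axes with deterministic
signs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix

__all__ = ["OrdinationResult", "monotone_regression", "stress1", "nmds"]


def monotone_regression(dissimilarities: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit of ``distances`` in the order of
    ``dissimilarities``; ties in dissimilarity are averaged within blocks."""
    diss = np.asarray(dissimilarities, dtype=float)
    dist = np.asarray(distances, dtype=float)
    if diss.size == 0:
        raise ValueError("empty input")
    if diss.shape != dist.shape:
        raise ValueError("length mismatch")
    uniq, inverse, counts = np.unique(diss, return_inverse=True, return_counts=True)
    block_means = np.bincount(inverse, weights=dist) / counts
    fitted_blocks = isotonic_regression(block_means, weights=counts.astype(float)).x
    return fitted_blocks[inverse]


def _stress_from(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom <= 0:
        raise ValueError("all configuration distances are zero")
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def stress1(coords: np.ndarray, d: DistanceMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(d):
        raise ValueError("coordinate rows must match matrix items")
    diss = d.condensed()
    dist = pdist(coords)
    return _stress_from(dist, monotone_regression(diss, dist))


@dataclass
class OrdinationResult:
    """NMDS solution: centered coordinates on principal axes plus run record."""

    ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_starts: int
    best_start: int
    converged: bool
    seed: int
    stress_trace: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.coordinates, index=self.ids,
                            columns=[f"axis{i+1}" for i in range(self.coordinates.shape[1])])


def _classical_start(d: DistanceMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    X = np.zeros((n, k))
    for j in range(k):
        if j < len(vals) and vals[j] > 1e-12:
            X[:, j] = vecs[:, j] * np.sqrt(vals[j])
        else:
            X[:, j] = rng.normal(scale=1e-3, size=n)
    return X


def _one_start(diss: np.ndarray, X: np.ndarray, max_iter: int, tol: float,
               ) -> tuple[np.ndarray, float, list[float], bool]:
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    dist = pdist(X)
    dhat = monotone_regression(diss, dist)
    stress = _stress_from(dist, dhat)
    trace = [stress]
    converged = False
    n_pairs = len(dist)
    for _ in range(max_iter):
        # Guttman transform toward the current disparities; the disparities
        # are rescaled to a fixed norm (sum dhat^2 = number of pairs, as in
        # standard SMACOF) so the configuration scale cannot drift to zero
        scale = np.sqrt(n_pairs / np.sum(dhat ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, scale * dhat / dist, 0.0)
        R = squareform(ratio)
        Bmat = -R
        np.fill_diagonal(Bmat, R.sum(axis=1))
        X_new = (Bmat @ X) / n
        dist_new = pdist(X_new)
        dhat_new = monotone_regression(diss, dist_new)
        stress_new = _stress_from(dist_new, dhat_new)
        if stress_new > stress:        # keep the trace non-increasing
            converged = True
            break
        X, dist, dhat = X_new, dist_new, dhat_new
        improvement = stress - stress_new
        stress = stress_new
        trace.append(stress)
        if improvement < tol:
            converged = True
            break
    return X, stress, trace, converged


def nmds(d: DistanceMatrix, k: int = 3, n_starts: int = 20, max_iter: int = 500,
         tol: float = 1e-7, seed: int = 0) -> OrdinationResult:
    """Kruskal NMDS of ``d`` into ``k`` axes, best of ``n_starts`` starts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    diss = d.condensed()
    n = len(d)
    best = None
    for s in range(n_starts):
        if s == 0:
            X0 = _classical_start(d, k, rng)
        else:
            X0 = rng.uniform(-1.0, 1.0, size=(n, k))
        X, stress, trace, conv = _one_start(diss, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, trace, conv, s)
    X, stress, trace, conv, s = best
    # center and rotate to principal axes; deterministic signs
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for j in range(k):
        i = np.argmax(np.abs(X[:, j]))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return OrdinationResult(list(d.ids), X, stress, n_starts, s, conv, seed, trace)
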