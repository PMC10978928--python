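"""Phylogenetic signal statistics for traits on a rooted tree.

Blomberg's K (continuous traits) compares the observed ratio of the
phylogenetically uncorrected to the corrected mean squared error with its
expectation under Brownian motion; K = 1 under Brownian evolution, K -> 0
as signal disappears.

Fritz & Purvis' D (binary traits) locates the observed sum of sister-clade
differences between two simulated reference distributions: tip-shuffled
(phylogenetically random; D = 1) and threshold-Brownian (D = 0).  Because
K and D run in opposite directions, D is additionally reported rescaled as
1 - D so that larger always means stronger signal.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .phylo_metrics import Phylogeny

__all__ = ["SignalResult", "blomberg_k", "fritz_purvis_d"]


@dataclass(frozen=True)
class SignalResult:
    statistic: float
    name: str                     # "K" or "D"
    n_simulations: int = 0
    seed: int | None = None
    rescaled: float | None = None  # 1 - D, reported for D only


def _aligned_trait(tree: Phylogeny, trait: Mapping[str, float]) -> np.ndarray:
    missing = [t for t in tree.tip_labels if t not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing[:5]}")
    return np.array([float(trait[t]) for t in tree.tip_labels])


def blomberg_k(tree: Phylogeny, trait: Mapping[str, float]) -> SignalResult:
    """Blomberg's K for a continuous trait.

    With C the Brownian tip variance-covariance matrix,
    a_hat = (1' C^-1 x) / (1' C^-1 1), the statistic is

        K = (MSE0 / MSE)_observed / (MSE0 / MSE)_expected

    where MSE0 = sum (x - a_hat)^2 / (n - 1), MSE = (x - a_hat)' C^-1
    (x - a_hat) / (n - 1) and the Brownian expectation of the ratio is
    (tr C - n / (1' C^-1 1)) / (n - 1).
    """
    x = _aligned_trait(tree, trait)
    if np.var(x) == 0:
        raise ValueError("constant trait")
    C = tree.vcv()
    n = len(x)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    ones = np.ones(n)
    denom1 = ones @ Cinv @ ones
    ahat = (ones @ Cinv @ x) / denom1
    dev = x - ahat
    mse0 = dev @ dev / (n - 1)
    mse = dev @ Cinv @ dev / (n - 1)
    expected = (np.trace(C) - n / denom1) / (n - 1)
    k = (mse0 / mse) / expected
    return SignalResult(float(k), "K")


def _d_value(tree: Phylogeny, values: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of absolute sister differences in nodal
    values obtained by averaging tip states down the tree.

    ``values`` is (n_tips,) or (n_tips, n_sims); vectorized over columns.
    """
    vals = np.atleast_2d(values.T).T.astype(float)  # (n_tips, n_sims)
    n_sims = vals.shape[1]
    node_vals = np.zeros((tree.n_nodes, n_sims))
    node_vals[: tree.n_tips] = vals
    d = np.zeros(n_sims)
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        kid_vals = node_vals[kids]              # (n_kids, n_sims)
        mean = kid_vals.mean(axis=0)
        node_vals[v] = mean
        d += np.abs(kid_vals - mean).sum(axis=0)
    return d


def fritz_purvis_d(tree: Phylogeny, trait: Mapping[str, int], n_sims: int = 1000,
                   seed: int = 0) -> SignalResult:
    """Fritz & Purvis' D for a binary trait, with the 1 - D rescaling.

    The random reference shuffles tip labels; the Brownian reference
    simulates a Brownian trait on the tree and thresholds it so the number
    of 1-tips matches the observed prevalence.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    x = _aligned_trait(tree, trait)
    if not set(np.unique(x)).issubset({0.0, 1.0}):
        raise ValueError("trait must be binary 0/1")
    k1 = int(x.sum())
    n = len(x)
    if k1 == 0 or k1 == n:
        raise ValueError("monomorphic trait: both states must be present")
    rng = np.random.default_rng(seed)
    d_obs = float(_d_value(tree, x)[0])

    # random reference: tip shuffles
    perms = np.empty((n, n_sims))
    for s in range(n_sims):
        perms[:, s] = rng.permutation(x)
    d_rand = _d_value(tree, perms)

    # Brownian threshold reference
    C = tree.vcv()
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
    z = L @ rng.standard_normal((n, n_sims))
    # threshold each column at its k1-th largest value
    order = np.argsort(-z, axis=0)
    bm = np.zeros_like(z)
    np.put_along_axis(bm, order[:k1], 1.0, axis=0)
    d_bm = _d_value(tree, bm)

    denom = d_rand.mean() - d_bm.mean()
    if denom == 0:
        raise ValueError("degenerate reference distributions")
    d_stat = (d_obs - d_bm.mean()) / denom
    return SignalResult(float(d_stat), "D", n_simulations=n_sims, seed=seed,
                        rescaled=float(1.0 - d_stat))
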