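"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's internal representations: trees are
walked through dendropy directly, branch sets are python sets of edge ids,
and volumes are estimated by rejection sampling.  They exist to cross-check
the production implementations, never to stand in for them.
"""
from __future__ import annotations

import dendropy
import numpy as np


def branch_sets_from_newick(newick: str) -> tuple[dict[str, set[int]], dict[int, float]]:
    """Per-tip root-to-tip edge-id sets plus edge lengths, via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    edge_ids: dict[int, int] = {}
    lengths: dict[int, float] = {}
    for k, edge in enumerate(tree.preorder_edge_iter()):
        edge_ids[id(edge)] = k
        lengths[k] = edge.length or 0.0
    tip_sets: dict[str, set[int]] = {}
    for leaf in tree.leaf_node_iter():
        path = set()
        node = leaf
        while node.parent_node is not None:
            path.add(edge_ids[id(node.edge)])
            node = node.parent_node
        tip_sets[leaf.taxon.label] = path
    return tip_sets, lengths


def phylobeta_oracle(newick: str, set_a: set[str], set_b: set[str]):
    """(sim, sor, nes) by explicit edge-set algebra."""
    tip_sets, lengths = branch_sets_from_newick(newick)
    edges_a = set().union(*(tip_sets[t] for t in set_a))
    edges_b = set().union(*(tip_sets[t] for t in set_b))
    a = sum(lengths[e] for e in edges_a & edges_b)
    b = sum(lengths[e] for e in edges_a - edges_b)
    c = sum(lengths[e] for e in edges_b - edges_a)
    mn = min(b, c)
    sim = mn / (a + mn) if a + mn > 0 else 0.0
    sor = (b + c) / (2 * a + b + c) if (2 * a + b + c) > 0 else 0.0
    return sim, sor, sor - sim


def pd_oracle(newick: str, species: set[str]) -> float:
    tip_sets, lengths = branch_sets_from_newick(newick)
    edges = set().union(*(tip_sets[t] for t in species))
    return sum(lengths[e] for e in edges)


def monte_carlo_intersection_volume(points_a: np.ndarray, points_b: np.ndarray,
                                    n_samples: int, seed: int) -> float:
    """Rejection-sampling estimate of the hulls' intersection volume."""
    from scipy.spatial import ConvexHull

    eq_a = ConvexHull(points_a).equations
    eq_b = ConvexHull(points_b).equations
    lo = points_a.min(axis=0)
    hi = points_a.max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, points_a.shape[1]))
    inside_a = (pts @ eq_a[:, :-1].T + eq_a[:, -1] <= 1e-12).all(axis=1)
    inside_b = (pts @ eq_b[:, :-1].T + eq_b[:, -1] <= 1e-12).all(axis=1)
    frac = np.mean(inside_a & inside_b)
    return float(np.prod(hi - lo) * frac)
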