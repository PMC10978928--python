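"""Branch-length-based alpha and beta diversity on a rooted phylogeny.

Faith's phylogenetic diversity (PD) is the summed length of all branches on
the union of root-to-tip paths of an assemblage.  Phylogenetic beta diversity
is computed on branch lengths rather than species: with

    a = shared branch length, b / c = branch length unique to each assemblage,

the Sorensen-family partition is

    pbeta_sim = min(b, c) / (a + min(b, c))        (turnover, Simpson family)
    pbeta_sor = (b + c) / (2a + b + c)             (total dissimilarity)
    pbeta_nes = pbeta_sor - pbeta_sim              (nestedness-resultant)

The turnover component is insensitive to richness differences, which is what
makes it usable as a continuous measure of biogeographic distance.

Branch sets follow the *rooted* convention: paths run all the way to the tree
root (not to the subset's MRCA), so PD of the full species pool equals the
total tree length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .containers import DistanceMatrix, OccurrenceMatrix

__all__ = [
    "Phylogeny",
    "BranchSet",
    "PhyloBetaPair",
    "NewickParseError",
    "read_newick",
    "assemblage_branch_set",
    "faith_pd",
    "phylobeta_pair",
    "phylobeta_matrix",
]


class NewickParseError(ValueError):
    """Raised for malformed newick input (position included when known)."""


class Phylogeny:
    """Array-backed rooted phylogeny.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1, in newick
    order).  ``edge_length[i]`` is the length of the edge *above* node ``i``
    (0 for the root).  All edge lengths are non-negative; tip labels are
    unique.  Ultrametricity is accepted but not required (use
    :meth:`is_ultrametric` to check).
    """

    def __init__(self, parent: np.ndarray, edge_length: np.ndarray,
                 tip_labels: Sequence[str]) -> None:
        parent = np.asarray(parent, dtype=int)
        edge_length = np.asarray(edge_length, dtype=float)
        n_nodes = len(parent)
        if len(edge_length) != n_nodes:
            raise ValueError("parent/edge_length length mismatch")
        roots = np.flatnonzero(parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if np.any(edge_length < 0):
            raise ValueError("negative edge length")
        labels = [str(t) for t in tip_labels]
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.parent = parent
        self.edge_length = edge_length
        self.tip_labels = labels
        self.n_tips = len(labels)
        self.n_nodes = n_nodes
        self.root = int(roots[0])
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        # children lists and a postorder node sequence
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for i, p in enumerate(parent):
            if p >= 0:
                children[p].append(i)
        self.children = children
        # verify all tips reachable / acyclic via iterative DFS
        order: list[int] = []
        stack = [self.root]
        seen = np.zeros(n_nodes, dtype=bool)
        while stack:
            v = stack.pop()
            if seen[v]:
                raise ValueError("cycle in parent pointers")
            seen[v] = True
            order.append(v)
            stack.extend(children[v])
        if not seen.all():
            raise ValueError("nodes unreachable from root")
        self.preorder = np.array(order)
        self.postorder = self.preorder[::-1].copy()

    # ------------------------------------------------------------------
    @property
    def total_length(self) -> float:
        """Sum of all edge lengths."""
        return float(self.edge_length.sum())

    def tip_indices(self, labels: Iterable[str]) -> np.ndarray:
        idx = []
        for lab in labels:
            if lab not in self._tip_index:
                raise KeyError(f"unknown tip label {lab!r}")
            idx.append(self._tip_index[lab])
        return np.array(sorted(idx), dtype=int)

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.edge_length[v]
        return d

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        td = self.depths()[: self.n_tips]
        span = td.max() - td.min()
        return bool(span <= rel_tol * max(td.max(), 1e-300))

    def branch_indicator(self, tips: Iterable[str]) -> np.ndarray:
        """Boolean mask over nodes whose *above* edge lies on a root-to-tip
        path of the given tips (root excluded)."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        for i in self.tip_indices(tips):
            v = i
            while v != self.root and not mask[v]:
                mask[v] = True
                v = self.parent[v]
        return mask

    def vcv(self) -> np.ndarray:
        """Tip variance-covariance matrix under Brownian motion: C[i, j] is
        the shared root-to-MRCA path length; diagonal is tip depth."""
        d = self.depths()
        n = self.n_tips
        C = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if not self.children[v]:
                tipsets[v] = np.array([v]) if v < n else np.array([], dtype=int)
                continue
            kids = self.children[v]
            for ai in range(len(kids)):
                for bi in range(ai + 1, len(kids)):
                    ta, tb = tipsets[kids[ai]], tipsets[kids[bi]]
                    C[np.ix_(ta, tb)] = d[v]
                    C[np.ix_(tb, ta)] = d[v]
            tipsets[v] = np.concatenate([tipsets[k] for k in kids])
        np.fill_diagonal(C, d[:n])
        return C

    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        def emit(v: int) -> str:
            if not self.children[v]:
                s = _quote(self.tip_labels[v]) if v < self.n_tips else ""
            else:
                s = "(" + ",".join(emit(c) for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{self.edge_length[v]:.10g}"
            return s

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return emit(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, total_length={self.total_length:.4g})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Branch lengths are required on all non-root edges; a missing root edge
    length is treated as 0.  Malformed input, duplicate tip labels and
    missing lengths raise :class:`NewickParseError`.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
    if any(lab is None for lab in labels):
        raise NewickParseError("unlabeled tip in newick input")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate tip labels: {dupes}")

    index: dict[int, int] = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    nxt = len(leaves)
    for nd in tree.preorder_node_iter():
        if id(nd) not in index:
            index[id(nd)] = nxt
            nxt += 1
    n_nodes = nxt
    parent = np.full(n_nodes, -1, dtype=int)
    lengths = np.zeros(n_nodes)
    root = tree.seed_node
    for nd in tree.preorder_node_iter():
        i = index[id(nd)]
        if nd is root:
            lengths[i] = nd.edge.length or 0.0
            continue
        parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is None:
            raise NewickParseError(
                f"missing branch length on edge above "
                f"{nd.taxon.label if nd.taxon else 'internal node'}")
        lengths[i] = nd.edge.length
    lengths[index[id(root)]] = 0.0  # root stub excluded from branch sets
    return Phylogeny(parent, lengths, labels)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BranchSet:
    """A set of edges (by child-node id) and their total length."""

    edges: frozenset[int]
    total_length: float


@dataclass(frozen=True)
class PhyloBetaPair:
    """Baselga-family partition of pairwise phylogenetic dissimilarity."""

    sim: float
    sor: float
    nes: float


def assemblage_branch_set(tree: Phylogeny, species: Iterable[str]) -> BranchSet:
    """Edges on the union of root-to-tip paths of ``species`` (rooted
    convention; the root's stub edge is excluded)."""
    species = list(species)
    if not species:
        raise ValueError("empty assemblage")
    mask = tree.branch_indicator(species)
    edges = frozenset(int(i) for i in np.flatnonzero(mask))
    return BranchSet(edges, float(tree.edge_length[mask].sum()))


def faith_pd(tree: Phylogeny, species: Iterable[str]) -> float:
    """Faith's phylogenetic diversity: total branch length spanning the
    assemblage (to the root)."""
    return assemblage_branch_set(tree, species).total_length


def _partition(a: float, b: float, c: float) -> PhyloBetaPair:
    tot = a + b + c
    if tot <= 0.0:
        warnings.warn("all relevant edges have zero length; returning 0 dissimilarity")
        return PhyloBetaPair(0.0, 0.0, 0.0)
    mn = min(b, c)
    sim = mn / (a + mn) if (a + mn) > 0 else 0.0
    sor = (b + c) / (2 * a + b + c)
    return PhyloBetaPair(sim, sor, sor - sim)


def phylobeta_pair(tree: Phylogeny, species_a: Iterable[str],
                   species_b: Iterable[str]) -> PhyloBetaPair:
    """Pairwise phylogenetic beta diversity between two assemblages."""
    ma = tree.branch_indicator(list(species_a) or _raise_empty())
    mb = tree.branch_indicator(list(species_b) or _raise_empty())
    w = tree.edge_length
    a = float(w[ma & mb].sum())
    b = float(w[ma & ~mb].sum())
    c = float(w[mb & ~ma].sum())
    return _partition(a, b, c)


def _raise_empty():
    raise ValueError("empty assemblage")


def phylobeta_matrix(tree: Phylogeny, occ: OccurrenceMatrix,
                     drop_empty: bool = False,
                     ) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """Full pairwise phylobetadiversity matrices (sim, sor, nes).

    Branch sets are computed once per cell (as a cells x edges indicator
    matrix) and all pairs evaluated with weighted boolean algebra.

    Parameters
    ----------
    drop_empty : bool
        If True, cells with no species are dropped with a warning; otherwise
        an empty cell raises ``ValueError``.
    """
    empty = [c for c, r in zip(occ.cells, occ.values.sum(axis=1)) if r == 0]
    if empty:
        if not drop_empty:
            raise ValueError(f"empty cells: {empty}")
        warnings.warn(f"dropping {len(empty)} empty cells: {empty}")
        occ = occ.drop_cells(empty)
    cells = occ.cells
    n = len(cells)
    B = np.zeros((n, tree.n_nodes), dtype=bool)
    for i, cell in enumerate(cells):
        B[i] = tree.branch_indicator(occ.species_in(cell))
    w = tree.edge_length
    Bw = B * w
    shared = Bw @ B.T                      # a for every pair
    tot = B @ w
    bmat = tot[:, None] - shared           # unique to row cell
    cmat = tot[None, :] - shared           # unique to column cell
    mn = np.minimum(bmat, cmat)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(shared + mn > 0, mn / (shared + mn), 0.0)
        denom = 2 * shared + bmat + cmat
        sor = np.where(denom > 0, (bmat + cmat) / denom, 0.0)
    sim = np.clip(0.5 * (sim + sim.T), 0.0, 1.0)
    sor = np.clip(0.5 * (sor + sor.T), 0.0, 1.0)
    np.fill_diagonal(sim, 0.0)
    np.fill_diagonal(sor, 0.0)
    nes = np.maximum(sor - sim, 0.0)  # guard tiny negative round-off
    return (DistanceMatrix(cells, sim), DistanceMatrix(cells, sor),
            DistanceMatrix(cells, nes))
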