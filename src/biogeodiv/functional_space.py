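"""Trait space construction and convex-hull functional diversity.

The trait space is built in two steps: a Gower dissimilarity over a
mixed-type trait table (continuous, percentage and categorical columns),
followed by principal coordinates analysis (PCoA) retaining the first ``m``
positive-eigenvalue axes.  Functional richness (FRic) of an assemblage is
the volume of the convex hull of its species in that space, expressed as a
proportion of the species pool's hull volume.  Functional beta diversity
compares two assemblages through the exact volume of the intersection of
their hulls:

    a = V_shared,  b = V_A - V_shared,  c = V_B - V_shared
    sor      = (b + c) / (2a + b + c)
    turnover = min(b, c) / (a + min(b, c))
    nestedness = sor - turnover

Turnover is 0 when one hull is nested in (or identical to) the other and 1
when the hulls are disjoint.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .containers import DistanceMatrix, OccurrenceMatrix

__all__ = [
    "TraitTable",
    "FunctionalSpace",
    "FuncBetaPair",
    "DegenerateHull",
    "gower_matrix",
    "pcoa",
    "build_functional_space",
    "functional_richness",
    "hull_volume",
    "hull_intersection_volume",
    "functional_beta_pair",
    "mean_functional_turnover",
]

_KINDS = ("continuous", "percentage", "categorical")


@dataclass
class TraitColumn:
    kind: str
    weight: float = 1.0
    transform: str | None = None  # "log" | "sqrt" | None, continuous only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.transform not in (None, "log", "sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.weight < 0:
            raise ValueError("negative trait weight")


class TraitTable:
    """Species x trait table with a per-column type/weight/transform schema."""

    def __init__(self, data: pd.DataFrame, schema: Mapping[str, TraitColumn | dict]) -> None:
        cols = {}
        for name, decl in schema.items():
            cols[name] = decl if isinstance(decl, TraitColumn) else TraitColumn(**decl)
        missing = set(data.columns) - set(cols)
        if missing:
            raise ValueError(f"columns without schema declaration: {sorted(missing)}")
        extra = set(cols) - set(data.columns)
        if extra:
            raise ValueError(f"schema declares absent columns: {sorted(extra)}")
        for name, col in cols.items():
            if col.kind == "percentage":
                v = data[name].to_numpy(dtype=float)
                if np.any(v < 0) or np.any(v > 100):
                    raise ValueError(f"percentage column {name!r} outside [0, 100]")
        if data.isna().all(axis=1).any():
            raise ValueError("species with all traits missing")
        self.data = data
        self.schema = cols
        self.species = [str(s) for s in data.index]

    def to_csv(self, path, schema_path) -> None:
        self.data.to_csv(path, float_format="%.10g")
        with open(schema_path, "w") as fh:
            json.dump({k: {"kind": c.kind, "weight": c.weight, "transform": c.transform}
                       for k, c in self.schema.items()}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path, schema_path) -> "TraitTable":
        data = pd.read_csv(path, index_col=0)
        with open(schema_path) as fh:
            schema = json.load(fh)
        return cls(data, schema)


def gower_matrix(traits: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity over mixed trait types, entries in [0, 1].

    Continuous columns are optionally log/sqrt transformed, then
    range-scaled; percentage columns are divided by 100 and treated as
    continuous; categorical columns use 0/1 simple matching.  Zero-range
    columns are dropped with a warning.
    """
    n = len(traits.species)
    if n < 2:
        raise ValueError("need at least two species")
    num = np.zeros((n, n))
    wsum = 0.0
    used = 0
    for name, col in traits.schema.items():
        if col.weight == 0:
            continue
        if col.kind == "categorical":
            v = traits.data[name].to_numpy()
            if len(np.unique(v)) < 2:
                warnings.warn(f"dropping constant trait {name!r}")
                continue
            diff = (v[:, None] != v[None, :]).astype(float)
        else:
            v = traits.data[name].to_numpy(dtype=float)
            if col.kind == "percentage":
                v = v / 100.0
            if col.transform == "log":
                if np.any(v <= 0):
                    raise ValueError(f"log transform of non-positive values in {name!r}")
                v = np.log(v)
            elif col.transform == "sqrt":
                if np.any(v < 0):
                    raise ValueError(f"sqrt transform of negative values in {name!r}")
                v = np.sqrt(v)
            rng = v.max() - v.min()
            if rng == 0:
                warnings.warn(f"dropping zero-range trait {name!r}")
                continue
            diff = np.abs(v[:, None] - v[None, :]) / rng
        num += col.weight * diff
        wsum += col.weight
        used += 1
    if used == 0:
        raise ValueError("no varying traits: all columns constant or zero-weight")
    d = num / wsum
    return DistanceMatrix(traits.species, d)


@dataclass
class FunctionalSpace:
    """Species coordinates on the retained PCoA axes plus pool hull volume."""

    species: list[str]
    coordinates: np.ndarray          # (n_species, m)
    eigenvalues: np.ndarray          # m retained, descending, positive
    pool_volume: float
    m: int
    n_negative_eigenvalues: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 axes")
        if np.any(self.eigenvalues <= 0):
            raise ValueError("retained eigenvalues must be positive")
        if self.pool_volume <= 0:
            raise ValueError("pool hull volume must be positive")
        self._index = {s: i for i, s in enumerate(self.species)}

    def points(self, species: Iterable[str]) -> np.ndarray:
        return self.coordinates[[self._index[s] for s in species]]

    def to_files(self, coords_path, meta_path) -> None:
        df = pd.DataFrame(self.coordinates, index=self.species,
                          columns=[f"axis{i+1}" for i in range(self.m)])
        df.to_csv(coords_path, float_format="%.12g")
        with open(meta_path, "w") as fh:
            json.dump({"m": self.m,
                       "eigenvalues": [float(e) for e in self.eigenvalues],
                       "pool_volume": self.pool_volume,
                       "n_negative_eigenvalues": self.n_negative_eigenvalues},
                      fh, indent=1, sort_keys=True)


def pcoa(d: DistanceMatrix, m: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Principal coordinates of a dissimilarity matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and returns the first ``m``
    positive-eigenvalue axes scaled by sqrt(eigenvalue).  Negative
    eigenvalues are truncated (their count is returned, not corrected).

    Returns
    -------
    coordinates : (n, m) ndarray
    eigenvalues : (m,) ndarray, descending
    n_negative : int
    """
    if m < 2:
        raise ValueError("need at least 2 axes")
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    G = 0.5 * (G + G.T)
    vals, vecs = eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12
    n_pos = int(np.sum(vals > tol))
    n_neg = int(np.sum(vals < -tol))
    if n_pos < m:
        raise ValueError(
            f"only {n_pos} positive eigenvalues; reduce m from {m} to <= {n_pos}")
    coords = vecs[:, :m] * np.sqrt(vals[:m])
    # deterministic signs: largest-magnitude coordinate positive per axis
    for j in range(m):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, vals[:m], n_neg


def build_functional_space(traits: TraitTable, m: int = 4) -> FunctionalSpace:
    """Gower -> PCoA -> pool convex hull, in one step."""
    d = gower_matrix(traits)
    coords, vals, n_neg = pcoa(d, m)
    vol = hull_volume(coords)
    return FunctionalSpace(list(d.ids), coords, vals, vol, m, n_neg)


class DegenerateHull(Exception):
    """Point set does not span an m-volume."""

    def __init__(self, reason: str) -> None:
        super().__init__(reason)
        self.reason = reason


def hull_volume(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    m = points.shape[1]
    if points.shape[0] < m + 1:
        raise DegenerateHull("too_few_species")
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise DegenerateHull("degenerate") from exc


def functional_richness(space: FunctionalSpace, species: Iterable[str]) -> float:
    """Hull volume of the assemblage divided by the pool hull volume.

    Raises :class:`DegenerateHull` (reason ``too_few_species`` or
    ``degenerate``) when no m-volume exists; callers treat that as a
    missing value and exclude the cell downstream.
    """
    pts = space.points(list(species))
    return hull_volume(pts) / space.pool_volume


def _interior_point(halfspaces: np.ndarray) -> np.ndarray | None:
    """Chebyshev center of the polytope Ax + b <= 0; None if empty/flat."""
    A, b = halfspaces[:, :-1], halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    m = A.shape[1]
    # maximize r subject to A x + r*||a|| <= -b
    res = linprog(c=np.r_[np.zeros(m), -1.0],
                  A_ub=np.hstack([A, norms]), b_ub=-b,
                  bounds=[(None, None)] * m + [(0, None)],
                  method="highs")
    if not res.success or res.x[-1] <= 1e-12:
        return None
    return res.x[:-1]


def hull_intersection_volume(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Exact volume of the intersection of two convex hulls.

    The half-space representations of both hulls are stacked, an interior
    point located by linear programming (Chebyshev center), and the
    intersection polytope's vertices enumerated with Qhull.  Returns 0 when
    the interiors do not meet.
    """
    eq_a = _hull_equations(points_a)
    eq_b = _hull_equations(points_b)
    return _intersection_volume_from_equations(eq_a, eq_b)


def _hull_equations(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    m = points.shape[1]
    if points.shape[0] < m + 1:
        raise DegenerateHull("too_few_species")
    try:
        return ConvexHull(points).equations
    except QhullError as exc:
        raise DegenerateHull("degenerate") from exc


def _intersection_volume_from_equations(eq_a: np.ndarray, eq_b: np.ndarray) -> float:
    halfspaces = np.vstack([eq_a, eq_b])
    center = _interior_point(halfspaces)
    if center is None:
        return 0.0
    try:
        hs = HalfspaceIntersection(halfspaces, center)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


@dataclass(frozen=True)
class FuncBetaPair:
    """Hull-overlap partition of pairwise functional dissimilarity."""

    sor: float
    turnover: float
    nestedness: float
    volume_a: float
    volume_b: float
    volume_shared: float


def functional_beta_pair(space: FunctionalSpace, species_a: Iterable[str],
                         species_b: Iterable[str]) -> FuncBetaPair:
    """Pairwise functional beta diversity from exact hull overlap."""
    pa = space.points(list(species_a))
    pb = space.points(list(species_b))
    return _func_beta_from_points(pa, pb)


def _func_beta_from_points(pa: np.ndarray, pb: np.ndarray) -> FuncBetaPair:
    va = hull_volume(pa)
    vb = hull_volume(pb)
    vs = min(hull_intersection_volume(pa, pb), va, vb)
    return _func_beta_from_volumes(va, vb, vs)


def _func_beta_from_volumes(va: float, vb: float, vs: float) -> FuncBetaPair:
    a = vs
    b = va - vs
    c = vb - vs
    tot = 2 * a + b + c
    sor = (b + c) / tot if tot > 0 else 0.0
    mn = min(b, c)
    turn = mn / (a + mn) if (a + mn) > 0 else 0.0
    return FuncBetaPair(sor, turn, max(sor - turn, 0.0), va, vb, vs)


def mean_functional_turnover(occ: OccurrenceMatrix, space: FunctionalSpace,
                             ) -> tuple[pd.Series, dict[str, str]]:
    """Per-cell mean of pairwise functional turnover against all other cells.

    Cells whose species cannot form an m-volume hull (too few species or a
    degenerate point set) are excluded from both focal and partner roles.

    Returns
    -------
    means : pandas.Series indexed by valid cell id
    excluded : dict cell id -> reason code
    """
    valid: list[str] = []
    eqs: dict[str, np.ndarray] = {}
    vols: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for cell in occ.cells:
        pts = space.points(sorted(occ.species_in(cell)))
        try:
            eqs[cell] = _hull_equations(pts)
            vols[cell] = hull_volume(pts)
            valid.append(cell)
        except DegenerateHull as exc:
            excluded[cell] = exc.reason
    if len(valid) < 2:
        raise ValueError("fewer than 2 cells with a valid functional hull")
    n = len(valid)
    turn = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vs = _intersection_volume_from_equations(eqs[valid[i]], eqs[valid[j]])
            vs = min(vs, vols[valid[i]], vols[valid[j]])
            pair = _func_beta_from_volumes(vols[valid[i]], vols[valid[j]], vs)
            turn[i, j] = turn[j, i] = pair.turnover
    means = turn.sum(axis=1) / (n - 1)
    return pd.Series(means, index=valid, name="mean_functional_turnover"), excluded
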