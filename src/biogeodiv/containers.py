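"""Shared in-memory containers: pairwise distance matrices and occurrence matrices.

Both are thin, validated wrappers around numpy arrays with ordered string
identifiers, plus round-trippable CSV serialization (square CSV with a header
row/column of ids for distances; cells x species 0/1 table for occurrences).
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "OccurrenceMatrix"]

_SYM_TOL = 1e-12


class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal.

    Parameters
    ----------
    ids : sequence of str
        Ordered item identifiers (grid cells, species, ...).
    values : (n, n) array_like
        Dissimilarities; must be finite, non-negative, symmetric to 1e-12
        and have a zero diagonal.
    """

    def __init__(self, ids: Sequence[str], values) -> None:
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in DistanceMatrix")
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} does not match {n} ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite entries in DistanceMatrix")
        if np.any(values < 0):
            raise ValueError("negative entries in DistanceMatrix")
        if np.max(np.abs(values - values.T), initial=0.0) > _SYM_TOL:
            raise ValueError("matrix not symmetric to 1e-12")
        if np.max(np.abs(np.diagonal(values)), initial=0.0) > _SYM_TOL:
            raise ValueError("non-zero diagonal in DistanceMatrix")
        # exact symmetry / zero diagonal after validation
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        self.ids: list[str] = ids
        self.values: np.ndarray = values

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, keep: Iterable[str]) -> "DistanceMatrix":
        keep = list(keep)
        idx = [self.ids.index(k) for k in keep]
        return DistanceMatrix(keep, self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DistanceMatrix(n={len(self.ids)})"


class OccurrenceMatrix:
    """Binary cells x species presence/absence matrix.

    Empty cells (all-zero rows) are retained by the container; metric
    operations decide whether to reject or drop them.
    """

    def __init__(self, cells: Sequence[str], species: Sequence[str], values) -> None:
        cells = [str(c) for c in cells]
        species = [str(s) for s in species]
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate cell ids")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species ids")
        values = np.asarray(values)
        if values.shape != (len(cells), len(species)):
            raise ValueError("occurrence shape mismatch")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("occurrence entries must be 0 or 1")
        self.cells = cells
        self.species = species
        self.values = values.astype(np.uint8)
        self._cell_index = {c: i for i, c in enumerate(cells)}

    @property
    def richness(self) -> pd.Series:
        """Species count per cell."""
        return pd.Series(self.values.sum(axis=1).astype(int), index=self.cells, name="richness")

    def species_in(self, cell: str) -> set[str]:
        row = self.values[self._cell_index[cell]]
        return {self.species[j] for j in np.flatnonzero(row)}

    def drop_cells(self, cells: Iterable[str]) -> "OccurrenceMatrix":
        drop = set(cells)
        keep = [i for i, c in enumerate(self.cells) if c not in drop]
        return OccurrenceMatrix([self.cells[i] for i in keep], self.species, self.values[keep])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"OccurrenceMatrix(cells={len(self.cells)}, species={len(self.species)})"
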