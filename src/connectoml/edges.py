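"""Canonical edge indexing for symmetric connectivity matrices.

An *edge* is an unordered pair of brain regions. With ``R`` regions there are
``R(R-1)/2`` edges; :class:`EdgeIndex` fixes a deterministic bijection between
region pairs ``(i, j)`` with ``i < j`` (0-based, lexicographic — i.e. the
upper triangle read row by row) and edge columns, so every module in the
pipeline agrees on feature order.
"""

from __future__ import annotations

import numpy as np

from .aal90 import AAL90_REGIONS

__all__ = ["edge_count", "EdgeIndex", "aal90_index", "vectorize_matrix", "devectorize"]

_SYM_TOL = 1e-9  # symmetry / diagonal tolerance for matrix input


def edge_count(n_regions: int) -> int:
    """Number of unordered region pairs: ``n_regions * (n_regions - 1) / 2``.

    >>> edge_count(90)
    4005
    """
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    return n_regions * (n_regions - 1) // 2


class EdgeIndex:
    """Bijection between region pairs ``(i, j)``, ``i < j``, and edge columns.

    Parameters
    ----------
    region_names
        Unique, non-empty labels, one per region; their order defines the
        edge order.
    """

    def __init__(self, region_names) -> None:
        names = tuple(str(n) for n in region_names)
        if len(names) < 2:
            raise ValueError("an edge index needs at least 2 regions")
        if any(not n for n in names):
            raise ValueError("region names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        self.region_names = names
        r = len(names)
        iu, ju = np.triu_indices(r, k=1)
        self._pairs = np.column_stack([iu, ju])  # (E, 2), lexicographic
        self._pair_to_id = {(int(i), int(j)): e for e, (i, j) in enumerate(self._pairs)}
        self._name_to_region = {n: i for i, n in enumerate(names)}

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_edges(self) -> int:
        return len(self._pairs)

    def __len__(self) -> int:
        return self.n_edges

    @property
    def pairs(self) -> np.ndarray:
        """``(n_edges, 2)`` array of region indices, ``i < j``."""
        return self._pairs.copy()

    def edge_id(self, i: int, j: int) -> int:
        """Edge column for the unordered region pair ``{i, j}``."""
        if i == j:
            raise ValueError("self-pairs are not edges")
        key = (min(i, j), max(i, j))
        try:
            return self._pair_to_id[key]
        except KeyError:
            raise IndexError(f"region pair {key} out of range for {self.n_regions} regions")

    def edge_id_by_name(self, name_a: str, name_b: str) -> int:
        try:
            i, j = self._name_to_region[name_a], self._name_to_region[name_b]
        except KeyError as err:
            raise KeyError(f"unknown region name: {err.args[0]!r}")
        return self.edge_id(i, j)

    def edge_regions(self, edge: int) -> tuple[int, int]:
        self._check_edge(edge)
        i, j = self._pairs[edge]
        return int(i), int(j)

    def edge_label(self, edge: int, sep: str = "–") -> str:
        """Human-readable label ``"RegionA–RegionB"`` in index order."""
        i, j = self.edge_regions(edge)
        return f"{self.region_names[i]}{sep}{self.region_names[j]}"

    def _check_edge(self, edge: int) -> None:
        if not 0 <= edge < self.n_edges:
            raise IndexError(f"edge id {edge} out of range [0, {self.n_edges})")

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgeIndex) and other.region_names == self.region_names

    def __repr__(self) -> str:
        return f"EdgeIndex(n_regions={self.n_regions}, n_edges={self.n_edges})"


def aal90_index() -> EdgeIndex:
    """The packaged AAL-90 atlas edge index (90 regions, 4005 edges)."""
    return EdgeIndex(AAL90_REGIONS)


def vectorize_matrix(matrix, edge_index: EdgeIndex) -> np.ndarray:
    """Flatten a symmetric zero-diagonal matrix into edge-index order.

    The matrix must be symmetric within 1e-9, have a (near-)zero diagonal and
    no NaNs; violations raise with the offending cells named rather than being
    silently repaired.
    """
    m = np.asarray(matrix, dtype=float)
    r = edge_index.n_regions
    if m.shape != (r, r):
        raise ValueError(f"matrix shape {m.shape} does not match {r} regions")
    if np.isnan(m).any():
        cells = list(zip(*np.nonzero(np.isnan(m))))[:5]
        raise ValueError(f"matrix contains NaN at cells {cells}")
    asym = np.abs(m - m.T)
    if asym.max() > _SYM_TOL:
        i, j = np.unravel_index(np.argmax(asym), m.shape)
        raise ValueError(
            f"matrix not symmetric: cell ({i},{j})={m[i, j]!r} vs ({j},{i})={m[j, i]!r}"
        )
    diag = np.abs(np.diag(m))
    if diag.max() > _SYM_TOL:
        k = int(np.argmax(diag))
        raise ValueError(f"nonzero diagonal at ({k},{k}): {m[k, k]!r}")
    iu, ju = np.triu_indices(r, k=1)
    return m[iu, ju]


def devectorize(edge_values, edge_index: EdgeIndex) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix`: rebuild the symmetric matrix."""
    v = np.asarray(edge_values, dtype=float)
    if v.shape != (edge_index.n_edges,):
        raise ValueError(f"expected {edge_index.n_edges} edge values, got shape {v.shape}")
    r = edge_index.n_regions
    m = np.zeros((r, r))
    iu, ju = np.triu_indices(r, k=1)
    m[iu, ju] = v
    m[ju, iu] = v
    return m
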