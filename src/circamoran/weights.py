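"""Spatial weight matrices defining "local" versus "global" coherence.

Moran's I compares neighbourhood-weighted covariance against total variance,
so the notion of *neighbourhood* is supplied explicitly as a sparse,
non-negative weight matrix ``w_ij`` with zero diagonal.  Three constructions
are provided:

* von Neumann lattice neighbourhoods of range ``r`` (binary weights on a
  regular grid, Manhattan metric),
* inverse Euclidean distance weights ``w_ij = ||Z_i - Z_j||^(-alpha)`` for
  freely located units,
* binary distance bands ``d_lo < ||Z_i - Z_j|| <= d_hi`` for correlograms.

Masked (no-tissue) grid cells are removed from the index space entirely, not
zero-weighted, so the unit count N seen by downstream statistics covers only
valid units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Locations",
    "WeightMatrix",
    "NoUsableUnitsError",
    "DegenerateDistanceError",
    "EmptyBandError",
    "grid_locations",
    "grid_von_neumann_weights",
    "inverse_distance_weights",
    "distance_band_weights",
    "write_edgelist",
    "read_edgelist",
]


class NoUsableUnitsError(ValueError):
    """Raised when a mask (or empty grid) leaves no spatial units."""


class DegenerateDistanceError(ValueError):
    """Raised when two locations coincide and inverse distance is undefined."""


class EmptyBandError(ValueError):
    """Raised when a distance band contains no pair of units."""


@dataclass(frozen=True)
class Locations:
    """2-D locations Z_i of the spatial units.

    ``frame`` is ``"grid"`` for integer (row, col) lattice coordinates (unit
    cell spacing) or ``"free"`` for real-valued planar coordinates.
    """

    coords: np.ndarray
    frame: str = "free"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (N, 2), got shape {coords.shape}")
        object.__setattr__(self, "coords", coords)
        if self.frame not in ("grid", "free"):
            raise ValueError(f"frame must be 'grid' or 'free', got {self.frame!r}")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class WeightMatrix:
    """Sparse non-negative spatial weights with zero diagonal.

    ``meta`` records the construction (kind and parameters) for provenance.
    """

    matrix: sp.csr_array
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = sp.csr_array(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("weight matrix must be square")
        if m.diagonal().any():
            raise ValueError("weight matrix diagonal must be zero")
        if (m.data < 0).any():
            raise ValueError("weights must be non-negative")
        m.sort_indices()
        self.matrix = m

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Total weight S0 = sum_ij w_ij."""
        return float(self.matrix.sum())

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def is_symmetric(self, tol: float = 0.0) -> bool:
        diff = self.matrix - self.matrix.T
        return bool(abs(diff).max() <= tol) if diff.nnz else True


def grid_locations(rows: int, cols: int, mask: np.ndarray | None = None) -> Locations:
    """Row-major (row, col) locations of the unmasked cells of a grid."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise ValueError(f"mask shape {mask.shape} != grid shape {(rows, cols)}")
        coords = coords[mask.ravel()]
    if coords.shape[0] == 0:
        raise NoUsableUnitsError("mask excludes all grid cells")
    return Locations(coords, frame="grid")


def grid_von_neumann_weights(
    rows: int,
    cols: int,
    range_r: int = 1,
    mask: np.ndarray | None = None,
) -> WeightMatrix:
    """Binary weights for the von Neumann neighbourhood of range ``r``.

    ``w_ij = 1`` iff ``0 < |x_i - x_j| + |y_i - y_j| <= r`` (Manhattan metric,
    open boundaries) and both cells are unmasked.  Masked cells are dropped
    from the index space, so the resulting matrix is ``n_valid x n_valid``
    with units ordered row-major over the unmasked cells.
    """
    if rows < 1 or cols < 1:
        raise NoUsableUnitsError("grid must have at least one cell")
    if range_r < 1:
        raise ValueError("range_r must be >= 1")
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise ValueError(f"mask shape {mask.shape} != grid shape {(rows, cols)}")
    if not mask.any():
        raise NoUsableUnitsError("mask excludes all grid cells")

    # compact index for valid cells, row-major
    index = -np.ones((rows, cols), dtype=int)
    index[mask] = np.arange(int(mask.sum()))

    offsets = [
        (dr, dc)
        for dr in range(-range_r, range_r + 1)
        for dc in range(-range_r + abs(dr), range_r - abs(dr) + 1)
        if (dr, dc) != (0, 0)
    ]
    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    rr, cc = np.nonzero(mask)
    for dr, dc in offsets:
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
        ok[ok] &= mask[r2[ok], c2[ok]]
        rows_idx.append(index[rr[ok], cc[ok]])
        cols_idx.append(index[r2[ok], c2[ok]])
    i = np.concatenate(rows_idx)
    j = np.concatenate(cols_idx)
    n = int(mask.sum())
    m = sp.csr_array((np.ones(i.size), (i, j)), shape=(n, n))
    return WeightMatrix(
        m,
        meta={
            "kind": "von_neumann",
            "rows": rows,
            "cols": cols,
            "range_r": range_r,
            "masked": bool((~mask).any()),
        },
    )


def _pairwise_distances(locs: Locations) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(locs.coords))


def inverse_distance_weights(locs: Locations, alpha: float) -> WeightMatrix:
    """Inverse-distance weights ``w_ij = ||Z_i - Z_j||^(-alpha)``, zero diagonal.

    ``alpha`` sets the interaction range: large alpha makes the weights
    effectively nearest-neighbour, alpha = 0 gives uniform (all-ones) weights.
    Coincident points make the weight undefined and raise
    :class:`DegenerateDistanceError`.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n = len(locs)
    if n < 2:
        raise NoUsableUnitsError("need at least two locations")
    d = _pairwise_distances(locs)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        i, j = np.argwhere((d == 0.0) & off)[0]
        raise DegenerateDistanceError(
            f"locations {int(i)} and {int(j)} coincide; inverse distance undefined"
        )
    w = np.zeros_like(d)
    w[off] = d[off] ** (-alpha)
    return WeightMatrix(sp.csr_array(w), meta={"kind": "inverse_distance", "alpha": alpha})


def distance_band_weights(locs: Locations, d_lo: float, d_hi: float) -> WeightMatrix:
    """Binary weights for the half-open distance band ``(d_lo, d_hi]``."""
    if not (d_hi > d_lo >= 0):
        raise ValueError("need d_hi > d_lo >= 0")
    n = len(locs)
    if n < 2:
        raise NoUsableUnitsError("need at least two locations")
    d = _pairwise_distances(locs)
    w = ((d > d_lo) & (d <= d_hi)).astype(float)
    np.fill_diagonal(w, 0.0)
    if not w.any():
        raise EmptyBandError(f"no pair of units at distance in ({d_lo}, {d_hi}]")
    return WeightMatrix(
        sp.csr_array(w), meta={"kind": "distance_band", "d_lo": d_lo, "d_hi": d_hi}
    )


def write_edgelist(W: WeightMatrix, path) -> None:
    """Write ``W`` as a 3-column (i, j, w) edge list with a JSON header line."""
    coo = W.matrix.tocoo()
    header = {"n_units": W.n_units, **W.meta}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("i\tj\tw\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{w:.12g}\n")


def read_edgelist(path) -> WeightMatrix:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        data = np.loadtxt(fh, skiprows=1, ndmin=2)
    n = int(meta.pop("n_units"))
    if data.size == 0:
        raise EmptyBandError("edge list contains no entries")
    i, j, w = data[:, 0].astype(int), data[:, 1].astype(int), data[:, 2]
    return WeightMatrix(sp.csr_array((w, (i, j)), shape=(n, n)), meta=meta)
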