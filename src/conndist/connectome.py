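"""Subject-level functional connectivity matrices and shared edge indexing.

A connectome here is the matrix of pairwise Pearson correlations between
regional BOLD time courses, Fisher z-transformed (``z = atanh(r)``) for
approximate normality.  All downstream stages (edge-wise GLM, NBS,
prediction) operate on the flattened upper triangle, so the edge ordering
is fixed once, lexicographically by 0-based region pair ``(i, j)``, ``i < j``.
For the 136-region parcellation used by default this gives 9180 edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

NETWORK_NAMES = ("DMN", "CEN", "VAN", "DAN", "AFN", "SMN", "VN")


def edge_count(n_regions: int) -> int:
    """Number of undirected edges (upper-triangle entries) for ``n_regions``.

    >>> edge_count(136)
    9180
    """
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    return n_regions * (n_regions - 1) // 2


@dataclass(frozen=True)
class RegionSet:
    """Region labels and their network partition.

    Parameters
    ----------
    labels : sequence of str
        Unique region labels, index position = region id (0-based).
    networks : sequence of str
        Network name per region (e.g. one of the seven canonical
        resting-state networks DMN/CEN/VAN/DAN/AFN/SMN/VN).
    """

    labels: tuple = ()
    networks: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "networks", tuple(self.networks))
        if len(self.labels) != len(self.networks):
            raise ValueError("labels and networks must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def network_names(self) -> tuple:
        seen = []
        for net in self.networks:
            if net not in seen:
                seen.append(net)
        return tuple(seen)

    def partition_sizes(self) -> dict:
        sizes: dict = {}
        for net in self.networks:
            sizes[net] = sizes.get(net, 0) + 1
        return sizes

    @classmethod
    def from_partition_sizes(cls, sizes: Sequence[int], network_names: Sequence[str] = NETWORK_NAMES) -> "RegionSet":
        """Build a RegionSet with contiguous blocks of regions per network."""
        if len(sizes) > len(network_names):
            raise ValueError("more partition blocks than network names")
        labels, networks = [], []
        for net, k in zip(network_names, sizes):
            for j in range(k):
                labels.append(f"{net}_{j:03d}")
                networks.append(net)
        return cls(tuple(labels), tuple(networks))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions),
                "region_name": self.labels,
                "network_label": self.networks,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        df = df.sort_values("region_id")
        return cls(tuple(df["region_name"]), tuple(df["network_label"]))


class EdgeIndex:
    """Bidirectional map between region pairs ``(i, j)`` and flat edge indices.

    Edges are the strict upper triangle in lexicographic order by ``(i, j)``,
    0-based, length ``R(R-1)/2``.
    """

    def __init__(self, n_regions: int):
        if n_regions < 2:
            raise ValueError("need at least 2 regions")
        self.n_regions = n_regions
        iu = np.triu_indices(n_regions, k=1)
        self._rows = iu[0]
        self._cols = iu[1]
        # flat index of pair (i, j): offset of row i plus (j - i - 1)
        self._row_offsets = np.concatenate(
            ([0], np.cumsum(n_regions - 1 - np.arange(n_regions - 1)))
        )

    def __len__(self) -> int:
        return self._rows.size

    @property
    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of region pairs in flat order."""
        return np.column_stack([self._rows, self._cols])

    def to_flat(self, i, j):
        """Flat index of edge (i, j); accepts scalars or arrays, any order."""
        i = np.asarray(i)
        j = np.asarray(j)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        if np.any(lo == hi):
            raise ValueError("self-pairs have no edge index")
        if np.any((lo < 0) | (hi >= self.n_regions)):
            raise ValueError("region index out of range")
        flat = self._row_offsets[lo] + (hi - lo - 1)
        return int(flat) if flat.ndim == 0 else flat

    def to_pair(self, flat):
        """Region pair (i, j), i < j, of a flat edge index."""
        flat = np.asarray(flat)
        if np.any((flat < 0) | (flat >= len(self))):
            raise ValueError("edge index out of range")
        i, j = self._rows[flat], self._cols[flat]
        if flat.ndim == 0:
            return int(i), int(j)
        return np.column_stack([i, j])


@dataclass
class ConnectivityMatrix:
    """A symmetric R x R Fisher-z connectivity matrix with zero diagonal."""

    subject_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        offdiag = v[~np.eye(v.shape[0], dtype=bool)]
        if not np.all(np.isfinite(offdiag)):
            raise ValueError("non-finite off-diagonal connectivity values")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def build_connectome(
    series: np.ndarray,
    subject_id: str = "",
    scrub_mask: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Fisher-z connectivity from a timepoints x R time-series array.

    Pearson correlations between all region pairs are computed on retained
    timepoints (``scrub_mask`` True = keep) and Fisher transformed,
    ``z = atanh(r)``.  The diagonal is set to 0; self-connections are never
    analyzed.

    Raises
    ------
    ValueError
        If fewer than 3 retained timepoints remain, a region's retained
        series is constant (undefined correlation), or any off-diagonal
        ``|r| = 1`` (atanh diverges; on real data this signals duplicated
        regions and is reported rather than clamped).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be timepoints x regions")
    if scrub_mask is not None:
        scrub_mask = np.asarray(scrub_mask, dtype=bool)
        if scrub_mask.shape[0] != series.shape[0]:
            raise ValueError("scrub_mask length must match timepoints")
        series = series[scrub_mask]
    if series.shape[0] < 3:
        raise ValueError(
            f"need >= 3 retained timepoints, got {series.shape[0]}"
        )
    sd = series.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant time series for region(s) {constant.tolist()}; "
            "correlation undefined"
        )
    r = np.corrcoef(series, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-15):
        bad = np.argwhere(np.triu(np.abs(r) >= 1.0 - 1e-15, k=1))
        raise ValueError(
            f"perfect correlation |r|=1 between region pairs {bad.tolist()}; "
            "Fisher transform diverges (duplicated regions?)"
        )
    np.fill_diagonal(r, 0.0)  # diagonal defined as 0, never atanh(1)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetries
    return ConnectivityMatrix(subject_id=subject_id, values=z)


def vectorize(matrix: ConnectivityMatrix | np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Upper-triangle edge values of a matrix in EdgeIndex order."""
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if v.shape[0] != index.n_regions:
        raise ValueError(
            f"matrix has {v.shape[0]} regions but index expects {index.n_regions}"
        )
    return v[index._rows, index._cols].copy()


def devectorize(edge_vector: np.ndarray, index: EdgeIndex, subject_id: str = "") -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`; rebuilds the symmetric matrix, diag 0."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    if edge_vector.shape[0] != len(index):
        raise ValueError(
            f"edge vector length {edge_vector.shape[0]} != {len(index)}"
        )
    R = index.n_regions
    m = np.zeros((R, R))
    m[index._rows, index._cols] = edge_vector
    m += m.T
    return ConnectivityMatrix(subject_id=subject_id, values=m)


def read_timeseries(path) -> np.ndarray:
    """Read a per-subject time-series table (CSV/TSV, header = region labels)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return df.to_numpy(dtype=float)


def cohort_edge_table(matrices: Sequence[ConnectivityMatrix], index: EdgeIndex) -> np.ndarray:
    """Stack per-subject edge vectors into a subjects x edges array."""
    return np.vstack([vectorize(m, index) for m in matrices])
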