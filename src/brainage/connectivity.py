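"""ROI-ROI connectivity features in a fixed canonical edge order.

All modules share one edge convention: for a set of ROI ids the feature
vector enumerates pairs (i, j) with i < j in row-major order, i.e.
(0,1), (0,2), ..., (0,n-1), (1,2), ... — ``C(n, 2)`` edges total.
Connectivity values are Fisher z-transformed Pearson correlations.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: correlations are clipped to this magnitude before arctanh so that
#: degenerate (perfectly correlated) inputs stay finite
R_CLIP = 1.0 - 1e-7

NETWORKS7 = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")


class EdgeClass(NamedTuple):
    """Classification of one edge from its two ROIs' metadata."""

    network_relation: str  # "within" | "between"
    hemisphere_relation: str  # "LL" | "RR" | "inter"


def fisher_z(r):
    """Fisher z-transform (arctanh) of correlation(s), clipped at ±(1 - 1e-7).

    Raises ``ValueError`` if any ``|r| > 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return out if out.ndim else float(out)


def fc_from_timeseries(ts: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix from a T x R time-series matrix.

    Pearson correlation per ROI pair, arctanh-transformed, zero diagonal.
    Requires T >= 3 and no constant column (a constant ROI has undefined
    correlation and is reported by index).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a T x R matrix with T >= 3")
    constant = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    if constant.size:
        raise ValueError(f"constant time series for ROI index(es) {constant.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    # numerical excursions beyond |1| are rounding error, not invalid input
    z = fisher_z(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(z, 0.0)
    return z


def canonical_edges(roi_ids: Sequence[int]) -> np.ndarray:
    """(M, 2) array of edges (i, j), i < j by ROI id, row-major order."""
    ids = np.sort(np.asarray(roi_ids, dtype=int))
    if ids.size < 2:
        return np.empty((0, 2), dtype=int)
    iu, ju = np.triu_indices(ids.size, k=1)
    return np.column_stack([ids[iu], ids[ju]])


def n_edges(n_roi: int) -> int:
    return n_roi * (n_roi - 1) // 2


def vectorize_upper(matrix: np.ndarray, roi_ids: Sequence[int]) -> np.ndarray:
    """Upper-triangle vector of a symmetric square matrix in canonical order.

    The matrix rows/columns follow ``sorted(roi_ids)``. Asymmetry beyond
    1e-8 is an error.
    """
    matrix = np.asarray(matrix, dtype=float)
    ids = np.sort(np.asarray(roi_ids, dtype=int))
    n = ids.size
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} ROIs")
    if n and np.max(np.abs(matrix - matrix.T)) > 1e-8:
        raise ValueError("matrix is not symmetric (tolerance 1e-8)")
    iu, ju = np.triu_indices(n, k=1)
    return matrix[iu, ju].copy()


def matrix_from_vector(values: np.ndarray, roi_ids: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; zero diagonal."""
    ids = np.sort(np.asarray(roi_ids, dtype=int))
    n = ids.size
    values = np.asarray(values, dtype=float)
    if values.size != n_edges(n):
        raise ValueError("value count does not match C(n, 2)")
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = values
    out[ju, iu] = values
    return out


def edge_subset_mask(edges: np.ndarray, roi_subset: Sequence[int],
                     valid_ids: Sequence[int] | None = None) -> np.ndarray:
    """Boolean mask over ``edges`` keeping those with both endpoints in the subset."""
    subset = np.asarray(sorted(set(int(r) for r in roi_subset)), dtype=int)
    if valid_ids is not None:
        unknown = set(subset.tolist()) - set(int(r) for r in valid_ids)
        if unknown:
            raise ValueError(f"unknown ROI id(s) in subset: {sorted(unknown)}")
    keep = np.isin(edges[:, 0], subset) & np.isin(edges[:, 1], subset)
    return keep


def subset_edges(values: np.ndarray, roi_ids: Sequence[int],
                 roi_subset: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Restrict an edge vector to edges within ``roi_subset``.

    Returns ``(sub_values, sub_edges)``; canonical order is preserved
    (a contiguous re-enumeration of the surviving pairs).
    """
    edges = canonical_edges(roi_ids)
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != edges.shape[0]:
        raise ValueError("values length does not match edge order")
    keep = edge_subset_mask(edges, roi_subset, valid_ids=roi_ids)
    return values[..., keep], edges[keep]


def classify_edge(roi_i: int, roi_j: int, parcellation: pd.DataFrame) -> EdgeClass:
    """Within/between-network and LL/RR/inter-hemisphere class of one edge."""
    if roi_i == roi_j:
        raise ValueError("an edge joins two distinct ROIs")
    meta = parcellation.set_index("roi") if "roi" in parcellation.columns else parcellation
    net_i, net_j = meta.loc[roi_i, "network"], meta.loc[roi_j, "network"]
    hem_i, hem_j = meta.loc[roi_i, "hemisphere"], meta.loc[roi_j, "hemisphere"]
    network_relation = "within" if net_i == net_j else "between"
    if hem_i == hem_j:
        hemisphere_relation = "LL" if hem_i == "L" else "RR"
    else:
        hemisphere_relation = "inter"
    return EdgeClass(network_relation, hemisphere_relation)


def classify_edges(edges: np.ndarray, parcellation: pd.DataFrame) -> pd.DataFrame:
    """Vectorized edge classification: one row per edge with both relations."""
    meta = parcellation.set_index("roi") if "roi" in parcellation.columns else parcellation
    net = meta["network"]
    hem = meta["hemisphere"]
    net_i = net.loc[edges[:, 0]].to_numpy()
    net_j = net.loc[edges[:, 1]].to_numpy()
    hem_i = hem.loc[edges[:, 0]].to_numpy()
    hem_j = hem.loc[edges[:, 1]].to_numpy()
    network_relation = np.where(net_i == net_j, "within", "between")
    hemisphere_relation = np.where(
        hem_i != hem_j, "inter", np.where(hem_i == "L", "LL", "RR")
    )
    return pd.DataFrame(
        {
            "roi_i": edges[:, 0],
            "roi_j": edges[:, 1],
            "network_relation": network_relation,
            "hemisphere_relation": hemisphere_relation,
        }
    )
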