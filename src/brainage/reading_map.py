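"""Map meta-analysis coordinates to parent ROIs and derive ROI cutoff sets.

A coordinate's parent ROI is, in synthetic mode, the nearest centroid
within a radius (default 12 mm); coordinates farther than the radius
from every centroid are out-of-range (e.g. non-cortical foci). Nested
ROI sets are then defined by minimum hit counts, producing the
whole-brain / reading-network ladder used by the prediction models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_RADIUS_MM = 12.0
OUT_OF_RANGE = -1


@dataclass
class CoordinateHitTable:
    """Per-ROI coordinate tallies with conservation totals."""

    counts: pd.Series  # indexed by ROI id, covering every parcellation ROI
    n_coords: int
    n_out_of_range: int
    #: per-coordinate parent ROI (OUT_OF_RANGE for unmapped)
    assignments: np.ndarray
    #: coordinates equidistant from >= 2 centroids (tie broken by lowest id)
    tie_flags: np.ndarray

    @property
    def n_mapped(self) -> int:
        return self.n_coords - self.n_out_of_range


def _coord_array(coords) -> np.ndarray:
    if isinstance(coords, pd.DataFrame):
        coords = coords[["x", "y", "z"]].to_numpy()
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 3 or not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite (x, y, z) triples")
    return coords


def map_coordinate_to_roi(coord, parcellation: pd.DataFrame,
                          radius: float = DEFAULT_RADIUS_MM) -> int:
    """Parent ROI of one coordinate, or ``OUT_OF_RANGE`` (-1).

    Nearest centroid wins if within ``radius`` mm; exact distance ties go
    to the lowest ROI id.
    """
    if len(parcellation) == 0:
        raise ValueError("empty parcellation")
    coord = _coord_array(coord)[0]
    cent = parcellation[["x", "y", "z"]].to_numpy()
    d = np.linalg.norm(cent - coord, axis=1)
    k = int(np.argmin(d))  # argmin takes the first minimum: lowest id on ties
    if d[k] > radius:
        return OUT_OF_RANGE
    return int(parcellation["roi"].iloc[k])


def count_hits(coords, parcellation: pd.DataFrame,
               radius: float = DEFAULT_RADIUS_MM) -> CoordinateHitTable:
    """Tally parent-ROI hits for a coordinate list.

    Conservation holds by construction: in-range + out-of-range = total.
    """
    coords = _coord_array(coords)
    if coords.shape[0] == 0:
        raise ValueError("coords must be nonempty")
    cent = parcellation[["x", "y", "z"]].to_numpy()
    ids = parcellation["roi"].to_numpy()
    d = np.linalg.norm(coords[:, None, :] - cent[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    dmin = d[np.arange(len(coords)), nearest]
    ties = (d <= dmin[:, None]).sum(axis=1) > 1
    assign = np.where(dmin <= radius, ids[nearest], OUT_OF_RANGE)
    mapped = assign[assign != OUT_OF_RANGE]
    counts = pd.Series(0, index=pd.Index(ids, name="roi"), dtype=int)
    vals, n = np.unique(mapped, return_counts=True)
    counts.loc[vals] = n
    return CoordinateHitTable(
        counts=counts,
        n_coords=len(coords),
        n_out_of_range=int((assign == OUT_OF_RANGE).sum()),
        assignments=assign,
        tie_flags=ties & (assign != OUT_OF_RANGE),
    )


def apply_cutoff(hits: CoordinateHitTable, k: int) -> np.ndarray:
    """Sorted ids of ROIs with at least ``k`` mapped coordinates.

    ``k=0`` returns every parcellation ROI (the whole-brain model).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return np.sort(hits.counts.index.to_numpy())
    return np.sort(hits.counts.index[hits.counts >= k].to_numpy())
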