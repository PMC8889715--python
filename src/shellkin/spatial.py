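"""Territory coordinates, pairwise distances and neighbourhood density.

Territories are points in a Cartesian plane measured in centimetres
(arbitrary origin). Neighbourhood density is the number of *other*
territories within a radius of the focal one; the boundary is inclusive
(a territory exactly at the radius counts), a documented convention that
is measure-zero for surveyed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["TerritoryMap", "DEFAULT_RADII", "neighbourhood_density", "pairwise_distances"]

DEFAULT_RADII = (50.0, 100.0, 150.0, 200.0)

_MAX_EXTENT_CM = 1e6  # reject maps whose extent suggests a unit error


@dataclass
class TerritoryMap:
    """Territory (group) centroid coordinates in cm."""

    group_ids: list[str]
    coords: np.ndarray  # (n, 2) cm
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.group_ids), 2):
            raise ValueError("coords must be (n_groups, 2)")
        if len(set(self.group_ids)) != len(self.group_ids):
            raise ValueError("duplicate group_id in territory map")
        if len(self.group_ids) == 0:
            raise ValueError("empty territory map")
        extent = self.coords.max(initial=0) - self.coords.min(initial=0)
        if extent > _MAX_EXTENT_CM:
            raise ValueError(
                f"map extent {extent:.3g} cm exceeds {_MAX_EXTENT_CM:.0e}; "
                "coordinates must be centimetres"
            )
        self._index = {g: i for i, g in enumerate(self.group_ids)}

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "TerritoryMap":
        df = pd.read_csv(path, dtype={"group_id": str})
        return cls(list(df["group_id"]), df[["x_cm", "y_cm"]].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "group_id": self.group_ids,
            "x_cm": np.round(self.coords[:, 0], 3),
            "y_cm": np.round(self.coords[:, 1], 3),
        }).to_csv(path, index=False)

    # -- geometry --------------------------------------------------------
    def distances(self) -> np.ndarray:
        """Full symmetric Euclidean distance matrix (cm)."""
        return cdist(self.coords, self.coords)

    def distance_between(self, group_a: str, group_b: str) -> float:
        d = self.coords[self._index[group_a]] - self.coords[self._index[group_b]]
        return float(np.hypot(*d))

    def distance_between_arrays(self, groups_a, groups_b) -> np.ndarray:
        ia = np.array([self._index[g] for g in groups_a])
        ib = np.array([self._index[g] for g in groups_b])
        d = self.coords[ia] - self.coords[ib]
        return np.hypot(d[:, 0], d[:, 1])

    def nearest_neighbour_distances(self) -> np.ndarray:
        d = self.distances()
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)


def pairwise_distances(territory_map: TerritoryMap) -> np.ndarray:
    """Symmetric matrix of inter-territory Euclidean distances (cm)."""
    return territory_map.distances()


def neighbourhood_density(territory_map: TerritoryMap,
                          radii=DEFAULT_RADII) -> pd.DataFrame:
    """Per-territory neighbour counts at each radius (inclusive boundary).

    Returns a DataFrame ``group_id, n_<r>...`` with one column per radius,
    e.g. ``n_50`` for 50 cm. Counts exclude the focal territory and are
    non-decreasing in the radius.
    """
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    d = territory_map.distances()
    np.fill_diagonal(d, np.inf)
    out = {"group_id": territory_map.group_ids}
    for r in radii:
        out[f"n_{r:g}"] = (d <= r).sum(axis=1)
    return pd.DataFrame(out)
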