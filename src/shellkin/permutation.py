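"""Permutation tests of within-group relatedness against neighbourhood density.

The question: do groups with more neighbouring territories within reach hold
less-related same-sex adults (because dispersal opportunities dilute kin
structure)? For each radius (50/100/150/200 cm) and category (FF, MM) the
observed statistic is the ordinary least-squares slope of mean within-group
same-sex relatedness on the neighbour count. The null distribution comes
from permuting the response across groups without replacement (10,000
permutations by default); the one-sided P-value is the proportion of null
slopes *strictly more negative* than the observed slope. Because that
literal definition can return P = 0, the add-one corrected estimate
``(count + 1) / (n_perm + 1)`` is reported alongside.

Each (category, radius) cell draws from its own seed stream derived from
the master seed, so any cell can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_for
from .spatial import DEFAULT_RADII

__all__ = ["slope", "permutation_slope_test", "PermutationResult",
           "DensityPermutationTest", "run_density_tests"]


def slope(response, predictor) -> float:
    """OLS slope of ``response`` on ``predictor`` (cov/var closed form)."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) != len(x):
        raise ValueError("response and predictor lengths differ")
    if len(y) < 3:
        raise ValueError("need >= 3 groups for a slope")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        raise ValueError("constant predictor: slope undefined")
    return float(xc @ y / ssx)


@dataclass
class PermutationResult:
    """One permutation-test cell (category x radius)."""

    radius_cm: float
    category: str
    observed_slope: float
    null_slopes: np.ndarray
    p_value: float           # strict "more negative" proportion
    p_value_plus_one: float  # (count + 1) / (n_perm + 1)
    seed: int
    n_perm: int

    def to_dict(self) -> dict:
        return dict(radius_cm=self.radius_cm, category=self.category,
                    observed_slope=round(self.observed_slope, 8),
                    p_value=round(self.p_value, 6),
                    p_value_plus_one=round(self.p_value_plus_one, 6),
                    n_perm=self.n_perm, seed=self.seed)


def permutation_slope_test(response, predictor, n_perm: int = 10_000,
                           seed: int = 0, category: str = "",
                           radius_cm: float = float("nan")) -> PermutationResult:
    """One-sided permutation test for a negative slope.

    The response is shuffled without replacement ``n_perm`` times; the
    slope is recomputed for each shuffle (vectorised: the slope is linear
    in the response, so every permuted slope is one dot product with the
    centred predictor).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    obs = slope(y, x)
    xc = x - x.mean()
    ssx = float(xc @ xc)
    rng = rng_for(seed, "perm", category, f"{radius_cm:g}")
    perm = np.tile(y, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    null = perm @ xc / ssx
    # strict "more negative" with a round-off guard so exact ties (e.g. a
    # constant response, where every slope is the same up to float noise)
    # never count as more extreme
    tol = 1e-12 * max(1.0, float(np.abs(null).max(initial=0.0)))
    count = int((null < obs - tol).sum())
    return PermutationResult(
        radius_cm=float(radius_cm), category=category,
        observed_slope=obs, null_slopes=null,
        p_value=count / n_perm,
        p_value_plus_one=(count + 1) / (n_perm + 1),
        seed=seed, n_perm=n_perm,
    )


class DensityPermutationTest:
    """Grid of permutation tests: {FF, MM} x radii.

    Parameters
    ----------
    group_means
        Mapping category -> Series of per-group mean within-group r_LR
        indexed by group_id (FF over multi-female groups, MM over
        multi-male groups; see :func:`shellkin.pairs.multi_member_groups`).
    neighbour_counts
        DataFrame from :func:`shellkin.spatial.neighbourhood_density`.
    """

    def __init__(self, group_means: dict[str, pd.Series],
                 neighbour_counts: pd.DataFrame, radii=DEFAULT_RADII):
        self.group_means = group_means
        self.counts = neighbour_counts.set_index("group_id")
        self.radii = [float(r) for r in radii]

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> "DensityPermutationResults":
        cells = []
        for category, means in sorted(self.group_means.items()):
            counts = self.counts.loc[means.index]
            for r in self.radii:
                cells.append(permutation_slope_test(
                    means.to_numpy(), counts[f"n_{r:g}"].to_numpy(),
                    n_perm=n_perm, seed=seed, category=category, radius_cm=r,
                ))
        return DensityPermutationResults(cells)


@dataclass
class DensityPermutationResults:
    cells: list[PermutationResult]

    def cell(self, category: str, radius_cm: float) -> PermutationResult:
        for c in self.cells:
            if c.category == category and c.radius_cm == float(radius_cm):
                return c
        raise KeyError((category, radius_cm))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.cells])

    def null_slope_table(self) -> pd.DataFrame:
        """Long-format null slopes for histogram reproduction."""
        frames = [
            pd.DataFrame({
                "category": c.category, "radius_cm": c.radius_cm,
                "null_slope": np.round(c.null_slopes, 8),
            })
            for c in self.cells
        ]
        return pd.concat(frames, ignore_index=True)


def run_density_tests(group_means: dict[str, pd.Series],
                      neighbour_counts: pd.DataFrame, radii=DEFAULT_RADII,
                      n_perm: int = 10_000, seed: int = 0) -> DensityPermutationResults:
    """Functional wrapper over :class:`DensityPermutationTest`."""
    return DensityPermutationTest(group_means, neighbour_counts, radii).fit(
        n_perm=n_perm, seed=seed)
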