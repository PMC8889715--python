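"""Analysis-table assembly: group composition and dyad subsets.

Splits the all-dyads relatedness table into the sets the downstream models
consume: within-group pairs in the four sex/stage categories (female-female,
male-male, female-male among adults, juvenile-juvenile), between-group
same-sex adult pairs with their inter-territory distances, and per-group
mean within-group relatedness restricted to groups that actually hold at
least one same-sex adult pair ("multi-female" / "multi-male" groups).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable

__all__ = [
    "group_composition_summary",
    "within_group_pairs",
    "between_group_same_sex_pairs",
    "multi_member_groups",
    "WITHIN_CATEGORIES",
]

WITHIN_CATEGORIES = ("FF", "MM", "FM", "JJ")


def group_composition_summary(table: GenotypeTable) -> tuple[pd.DataFrame, dict]:
    """Per-group composition plus population-level summary statistics.

    Returns ``(per_group, summary)``. ``per_group`` has one row per group
    (``n_females, n_males, n_juveniles, group_size, has_dominant_male``).
    ``summary`` carries means/SDs/ranges, integer histograms of each count
    (the binning used for composition histograms) and the Spearman rank
    correlation between the numbers of males and females per group.
    """
    rows = []
    for gid, members in sorted(table.groups().items()):
        nf = sum(1 for m in members if m.stage == "adult" and m.sex == "female")
        nm = sum(1 for m in members if m.stage == "adult" and m.sex == "male")
        nj = sum(1 for m in members if m.stage == "juvenile")
        rows.append(dict(
            group_id=gid, n_females=nf, n_males=nm, n_juveniles=nj,
            group_size=len(members),
            has_dominant_male=any(m.dominance == "dominant" for m in members),
        ))
    per_group = pd.DataFrame(rows)

    def _stats(col):
        v = per_group[col]
        return dict(mean=float(v.mean()), sd=float(v.std(ddof=1)),
                    min=int(v.min()), max=int(v.max()),
                    histogram={int(k): int(c) for k, c in
                               v.value_counts().sort_index().items()})

    if len(per_group) >= 2 and per_group["n_males"].nunique() > 1 \
            and per_group["n_females"].nunique() > 1:
        rho = float(stats.spearmanr(per_group["n_males"], per_group["n_females"])[0])
    else:
        rho = float("nan")
    summary = {
        "n_groups": int(len(per_group)),
        "n_fish": int(per_group["group_size"].sum()),
        "group_size": _stats("group_size"),
        "females": _stats("n_females"),
        "males": _stats("n_males"),
        "juveniles": _stats("n_juveniles"),
        "spearman_males_vs_females": rho,
    }
    return per_group, summary


def within_group_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Within-group dyads in the FF/MM/FM/JJ categories.

    Adult-juvenile and unknown-sex dyads are dropped; per-category counts
    are attached as ``DataFrame.attrs['category_counts']``.
    """
    out = pairs[(pairs["same_group"]) &
                (pairs["category"].isin(WITHIN_CATEGORIES))].reset_index(drop=True)
    out.attrs["category_counts"] = {
        c: int((out["category"] == c).sum()) for c in WITHIN_CATEGORIES
    }
    return out


def between_group_same_sex_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Between-group same-sex adult dyads (FF and MM) with distances.

    A retained dyad without a distance is a hard error — the distance is
    the predictor of the decay model.
    """
    out = pairs[(~pairs["same_group"]) &
                (pairs["category"].isin(("FF", "MM")))].reset_index(drop=True)
    if out["distance_cm"].isna().any():
        bad = out.loc[out["distance_cm"].isna(), ["id_1", "id_2"]].iloc[0]
        raise ValueError(
            f"between-group pair ({bad['id_1']}, {bad['id_2']}) has no distance; "
            "supply a territory map"
        )
    out.attrs["category_counts"] = {
        c: int((out["category"] == c).sum()) for c in ("FF", "MM")
    }
    return out


def multi_member_groups(pairs: pd.DataFrame, category: str) -> pd.Series:
    """Per-group mean within-group r_LR for one same-sex category.

    Only groups holding at least one within-group pair of ``category``
    appear (multi-female groups for FF, multi-male for MM); groups without
    such pairs are omitted, not zero-filled.
    """
    if category not in ("FF", "MM"):
        raise ValueError("category must be FF or MM")
    sub = pairs[(pairs["same_group"]) & (pairs["category"] == category)]
    means = sub.groupby("group_1")["r_lr"].mean().sort_index()
    means.index.name = "group_id"
    means.name = f"mean_r_{category.lower()}"
    return means


def partition_check(pairs: pd.DataFrame) -> bool:
    """True when within/between subsets of the covered categories are a
    disjoint, exhaustive partition of the eligible dyads."""
    win = within_group_pairs(pairs)
    btw = between_group_same_sex_pairs(pairs)
    covered = len(win) + len(btw)
    eligible = int(((pairs["same_group"] & pairs["category"].isin(WITHIN_CATEGORIES)) |
                    (~pairs["same_group"] & pairs["category"].isin(("FF", "MM")))).sum())
    keys = set(map(tuple, win[["id_1", "id_2"]].to_numpy())) & \
        set(map(tuple, btw[["id_1", "id_2"]].to_numpy()))
    return covered == eligible and not keys
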