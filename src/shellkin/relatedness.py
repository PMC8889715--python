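"""Symmetric Lynch-Ritland pairwise relatedness from microsatellite genotypes.

For a reference genotype ``(a, b)``, a proband genotype ``(c, d)`` and
population allele frequencies ``p_a, p_b`` the single-locus directional
estimator and its weight are

.. math::

    r = \\frac{p_a(\\delta_{bc} + \\delta_{bd}) + p_b(\\delta_{ac} +
        \\delta_{ad}) - 4 p_a p_b}{(1 + \\delta_{ab})(p_a + p_b) - 4 p_a p_b}
    \\qquad
    w = \\frac{(1 + \\delta_{ab})(p_a + p_b) - 4 p_a p_b}{2 p_a p_b}

with :math:`\\delta` the Kronecker indicator on allele identity. A locus is
undefined for a direction when the r-denominator vanishes (which covers
monomorphic loci). Each direction's multilocus estimate is the
weight-averaged sum over its defined loci, and the symmetric estimate is
the mean of the two directional estimates, each taken over the loci defined
in its own direction. The estimator is unbiased around pedigree relatedness
(0 unrelated, 0.25 half-sib, 0.5 parent-offspring/full-sib) and negative
values are meaningful — no truncation is applied.

Dyads are retained only when *both* individuals were successfully genotyped
at a minimum number of loci (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, FrequencyTable, GenotypeTable, Individual

logger = logging.getLogger(__name__)

__all__ = [
    "LocusEstimate",
    "PairRelatedness",
    "lr_locus",
    "lr_pair",
    "pairwise_matrix",
    "read_relatedness_table",
    "write_relatedness_table",
    "PAIR_COLUMNS",
]

_DEN_TOL = 1e-12

PAIR_COLUMNS = ["id_1", "id_2", "group_1", "group_2", "category",
                "same_group", "distance_cm", "n_loci", "r_lr"]


@dataclass(frozen=True)
class LocusEstimate:
    """Directional single-locus estimate (reference -> proband)."""

    r_locus: float
    weight: float
    reference_id: str = ""
    proband_id: str = ""
    locus: str = ""


@dataclass(frozen=True)
class PairRelatedness:
    """Symmetric multilocus relatedness for one dyad."""

    id_1: str
    id_2: str
    r_lr: float
    n_loci_used: int
    category: str = "other"
    same_group: bool = False
    distance_cm: float | None = None
    group_1: str = ""
    group_2: str = ""


def _lr_terms(pa, pb, dab, dac, dad, dbc, dbd):
    num = pa * (dbc + dbd) + pb * (dac + dad) - 4.0 * pa * pb
    den = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
    return num, den


def lr_locus(ref_genotype, proband_genotype, locus_freqs: dict,
             reference_id: str = "", proband_id: str = "", locus: str = ""):
    """Single-locus directional estimate, or ``None`` when undefined.

    Raises ``KeyError`` if an allele is absent from ``locus_freqs`` — the
    caller should first apply :meth:`FrequencyTable.augment` (novel alleles
    enter at frequency ``1/(2 n_ref + 1)``).
    """
    a, b = ref_genotype
    c, d = proband_genotype
    try:
        pa, pb = locus_freqs[a], locus_freqs[b]
        locus_freqs[c], locus_freqs[d]
    except KeyError as exc:
        raise KeyError(
            f"allele {exc} missing from frequency table at locus {locus!r}; "
            "augment the FrequencyTable before estimating"
        )
    num, den = _lr_terms(pa, pb, float(a == b), float(a == c), float(a == d),
                         float(b == c), float(b == d))
    if abs(den) < _DEN_TOL:
        return None
    return LocusEstimate(
        r_locus=num / den,
        weight=den / (2.0 * pa * pb),
        reference_id=reference_id,
        proband_id=proband_id,
        locus=locus,
    )


def _pair_category(x: Individual, y: Individual) -> str:
    sx, sy = sorted([ (x.stage, x.sex), (y.stage, y.sex) ])
    stages = (sx[0], sy[0])
    if stages == ("juvenile", "juvenile"):
        return "JJ"
    if stages == ("adult", "juvenile"):
        return "AJ"
    sexes = tuple(sorted((x.sex, y.sex)))
    if sexes == ("female", "female"):
        return "FF"
    if sexes == ("male", "male"):
        return "MM"
    if sexes == ("female", "male"):
        return "FM"
    return "other"


def lr_pair(x: Individual, y: Individual, table: GenotypeTable,
            freqs: FrequencyTable, min_loci: int = 10,
            distance_cm: float | None = None):
    """Symmetric multilocus estimate for one dyad.

    Returns a :class:`PairRelatedness`, or ``None`` when the dyad is
    excluded (either fish genotyped at fewer than ``min_loci`` loci, or no
    locus defined in either direction).
    """
    if x.id == y.id:
        raise ValueError("self-pair requested")
    ix, iy = table.row(x.id), table.row(y.id)
    ok = ~table.missing_mask
    if ok[ix].sum() < min_loci or ok[iy].sum() < min_loci:
        return None
    sums = {"xy": [0.0, 0.0], "yx": [0.0, 0.0]}
    n_used = 0
    for j, locus in enumerate(table.loci):
        gx, gy = table.calls[ix, j], table.calls[iy, j]
        if gx[0] == MISSING or gy[0] == MISSING:
            continue
        fmap = freqs.freqs[locus]
        for al in (*gx, *gy):
            if int(al) not in fmap:
                freqs.augment(locus, int(al))
                fmap = freqs.freqs[locus]
        e1 = lr_locus(tuple(gx), tuple(gy), fmap, x.id, y.id, locus)
        e2 = lr_locus(tuple(gy), tuple(gx), fmap, y.id, x.id, locus)
        if e1 is not None:
            sums["xy"][0] += e1.weight * e1.r_locus
            sums["xy"][1] += e1.weight
        if e2 is not None:
            sums["yx"][0] += e2.weight * e2.r_locus
            sums["yx"][1] += e2.weight
        if e1 is not None or e2 is not None:
            n_used += 1
    directions = [s / w for s, w in sums.values() if w > 0]
    if not directions:
        logger.info("pair (%s, %s): all shared loci undefined; excluded", x.id, y.id)
        return None
    id_1, id_2 = sorted([x.id, y.id])
    g1 = x.group_id if id_1 == x.id else y.group_id
    g2 = y.group_id if id_1 == x.id else x.group_id
    same = x.group_id == y.group_id
    return PairRelatedness(
        id_1=id_1, id_2=id_2,
        r_lr=float(np.mean(directions)),
        n_loci_used=n_used,
        category=_pair_category(x, y),
        same_group=same,
        distance_cm=0.0 if same else distance_cm,
        group_1=g1, group_2=g2,
    )


# -- vectorised all-dyads computation ------------------------------------

def _locus_codes(table: GenotypeTable, freqs: FrequencyTable):
    """Integer-coded calls and frequency vectors per locus (augmenting
    the frequency table with any novel alleles seen in ``table``)."""
    coded, fvecs = [], []
    for j, locus in enumerate(table.loci):
        col = table.calls[:, j, :]
        present = np.unique(col[col != MISSING])
        for al in present:
            if int(al) not in freqs.freqs[locus]:
                freqs.augment(locus, int(al))
        labels = sorted(freqs.freqs[locus])
        lut = {al: i for i, al in enumerate(labels)}
        codes = np.full(col.shape, -1, dtype=np.int64)
        mask = col != MISSING
        codes[mask] = [lut[int(v)] for v in col[mask]]
        coded.append(codes)
        fvecs.append(np.array([freqs.freqs[locus][al] for al in labels]))
    return coded, fvecs


def _directional(a, b, c, d, pa, pb, valid):
    """Vectorised directional (num, den, w, defined) over dyad arrays."""
    dab = (a == b).astype(float)
    dac = (a == c).astype(float)
    dad = (a == d).astype(float)
    dbc = (b == c).astype(float)
    dbd = (b == d).astype(float)
    num = pa * (dbc + dbd) + pb * (dac + dad) - 4.0 * pa * pb
    den = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
    defined = valid & (np.abs(den) > _DEN_TOL)
    w = np.where(defined, den / (2.0 * pa * pb), 0.0)
    r = np.divide(num, den, out=np.zeros_like(num), where=defined)
    return r, w, defined


def compute_r_for_dyads(table: GenotypeTable, freqs: FrequencyTable,
                        idx1: np.ndarray, idx2: np.ndarray):
    """Symmetric r_LR and loci-used counts for explicit dyad index arrays.

    Vectorised over dyads, one pass per locus. Returns ``(r, n_loci)``
    arrays aligned with ``idx1``/``idx2``; dyads with no defined locus get
    ``nan``.
    """
    coded, fvecs = _locus_codes(table, freqs)
    m = len(idx1)
    s_xy = np.zeros(m); w_xy = np.zeros(m)
    s_yx = np.zeros(m); w_yx = np.zeros(m)
    n_used = np.zeros(m, dtype=np.int64)
    for codes, f in zip(coded, fvecs):
        a = codes[idx1, 0]; b = codes[idx1, 1]
        c = codes[idx2, 0]; d = codes[idx2, 1]
        valid = (a >= 0) & (c >= 0)
        pa = f[np.clip(a, 0, None)]; pb = f[np.clip(b, 0, None)]
        pc = f[np.clip(c, 0, None)]; pd_ = f[np.clip(d, 0, None)]
        r1, w1, d1 = _directional(a, b, c, d, pa, pb, valid)
        r2, w2, d2 = _directional(c, d, a, b, pc, pd_, valid)
        s_xy += w1 * r1; w_xy += np.where(d1, w1, 0.0)
        s_yx += w2 * r2; w_yx += np.where(d2, w2, 0.0)
        n_used += (d1 | d2).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(w_xy > 0, s_xy / np.where(w_xy > 0, w_xy, 1.0), np.nan)
        r2 = np.where(w_yx > 0, s_yx / np.where(w_yx > 0, w_yx, 1.0), np.nan)
    both = np.stack([r1, r2])
    cnt = (~np.isnan(both)).sum(axis=0)
    tot = np.nansum(both, axis=0)
    r = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return r, n_used


def pairwise_matrix(table: GenotypeTable, freqs: FrequencyTable,
                    territory_map=None, min_loci: int = 10) -> pd.DataFrame:
    """Symmetric r_LR for every unordered dyad of retained individuals.

    Individuals genotyped at fewer than ``min_loci`` loci are excluded
    before pairing. When ``territory_map`` is given each dyad is annotated
    with the centroid distance between the two territories (0 within a
    group). Returns a DataFrame with columns :data:`PAIR_COLUMNS`.
    """
    keep = np.flatnonzero(table.n_genotyped_loci() >= min_loci)
    inds = [table.individuals[i] for i in keep]
    n = len(keep)
    iu, ju = np.triu_indices(n, k=1)
    idx1, idx2 = keep[iu], keep[ju]
    r, n_used = compute_r_for_dyads(table, freqs, idx1, idx2)

    ids = np.array([i.id for i in inds])
    gids = np.array([i.group_id for i in inds])
    cats = np.array([_pair_category(inds[i], inds[j]) for i, j in zip(iu, ju)])
    same = gids[iu] == gids[ju]
    dist = np.full(len(iu), np.nan)
    if territory_map is not None:
        dist = territory_map.distance_between_arrays(gids[iu], gids[ju])
    dist = np.where(same, 0.0, dist)

    # enforce lexicographic dyad ordering
    swap = ids[iu] > ids[ju]
    first = np.where(swap, ids[ju], ids[iu])
    second = np.where(swap, ids[iu], ids[ju])
    g1 = np.where(swap, gids[ju], gids[iu])
    g2 = np.where(swap, gids[iu], gids[ju])

    df = pd.DataFrame({
        "id_1": first, "id_2": second, "group_1": g1, "group_2": g2,
        "category": cats, "same_group": same, "distance_cm": dist,
        "n_loci": n_used, "r_lr": r,
    })
    excluded = df["r_lr"].isna()
    if excluded.any():
        logger.info("%d dyads excluded (no defined loci)", int(excluded.sum()))
    return df.loc[~excluded].reset_index(drop=True)


def within_group_matrix(table: GenotypeTable, freqs: FrequencyTable,
                        min_loci: int = 10) -> pd.DataFrame:
    """Like :func:`pairwise_matrix` restricted to same-group dyads.

    Avoids the full all-dyads sweep when only within-group structure is
    needed (e.g. replicated simulations); output schema is identical, with
    ``distance_cm`` fixed at 0.
    """
    keep = set(np.flatnonzero(table.n_genotyped_loci() >= min_loci))
    rows_i, rows_j = [], []
    for members in table.groups().values():
        idx = [table.row(m.id) for m in members if table.row(m.id) in keep]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                rows_i.append(idx[a]); rows_j.append(idx[b])
    if not rows_i:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    idx1, idx2 = np.array(rows_i), np.array(rows_j)
    r, n_used = compute_r_for_dyads(table, freqs, idx1, idx2)
    inds = table.individuals
    ids1 = np.array([inds[i].id for i in idx1])
    ids2 = np.array([inds[i].id for i in idx2])
    cats = np.array([_pair_category(inds[i], inds[j]) for i, j in zip(idx1, idx2)])
    gids = np.array([inds[i].group_id for i in idx1])
    swap = ids1 > ids2
    first = np.where(swap, ids2, ids1)
    second = np.where(swap, ids1, ids2)
    df = pd.DataFrame({
        "id_1": first, "id_2": second, "group_1": gids, "group_2": gids,
        "category": cats, "same_group": True, "distance_cm": 0.0,
        "n_loci": n_used, "r_lr": r,
    })
    return df.loc[~df["r_lr"].isna()].reset_index(drop=True)


def between_group_same_sex_matrix(table: GenotypeTable, freqs: FrequencyTable,
                                  territory_map, min_loci: int = 10) -> pd.DataFrame:
    """Between-group same-sex adult dyads (FF and MM) only.

    Avoids the full all-dyads sweep when only the distance-decay input is
    needed; output schema is identical to :func:`pairwise_matrix`.
    """
    keep = table.n_genotyped_loci() >= min_loci
    rows_i, rows_j = [], []
    for sex in ("female", "male"):
        idx = [i for i, ind in enumerate(table.individuals)
               if keep[i] and ind.sex == sex and ind.stage == "adult"]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ia, ib = idx[a], idx[b]
                if table.individuals[ia].group_id != table.individuals[ib].group_id:
                    rows_i.append(ia); rows_j.append(ib)
    if not rows_i:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    idx1, idx2 = np.array(rows_i), np.array(rows_j)
    r, n_used = compute_r_for_dyads(table, freqs, idx1, idx2)
    inds = table.individuals
    ids1 = np.array([inds[i].id for i in idx1])
    ids2 = np.array([inds[i].id for i in idx2])
    g1 = np.array([inds[i].group_id for i in idx1])
    g2 = np.array([inds[i].group_id for i in idx2])
    cats = np.array(["FF" if inds[i].sex == "female" else "MM" for i in idx1])
    dist = territory_map.distance_between_arrays(g1, g2)
    swap = ids1 > ids2
    df = pd.DataFrame({
        "id_1": np.where(swap, ids2, ids1), "id_2": np.where(swap, ids1, ids2),
        "group_1": np.where(swap, g2, g1), "group_2": np.where(swap, g1, g2),
        "category": cats, "same_group": False, "distance_cm": dist,
        "n_loci": n_used, "r_lr": r,
    })
    return df.loc[~df["r_lr"].isna()].reset_index(drop=True)


# -- precomputed relatedness tables --------------------------------------

def read_relatedness_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a precomputed pairwise-relatedness CSV.

    The native schema is :data:`PAIR_COLUMNS`; ``column_map`` renames
    foreign columns onto it (e.g. supplementary tables that label the dyad
    ``fish_1/fish_2`` and the estimate ``rlr``), so published relatedness
    tables can feed the model stages without raw genotypes. Duplicated
    dyads with conflicting r values are a hard error.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        logger.warning("relatedness table %s is empty", path)
        return pd.DataFrame(columns=PAIR_COLUMNS)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("id_1", "id_2", "r_lr") if c not in df.columns]
    if missing:
        raise ValueError(f"relatedness table lacks columns {missing}")
    for col, default in (("group_1", ""), ("group_2", ""), ("category", "other"),
                         ("n_loci", -1)):
        if col not in df.columns:
            df[col] = default
    if "same_group" not in df.columns:
        df["same_group"] = (df["group_1"] == df["group_2"]) & (df["group_1"] != "")
    if "distance_cm" not in df.columns:
        df["distance_cm"] = np.where(df["same_group"], 0.0, np.nan)
    lo = df[["id_1", "id_2"]].min(axis=1)
    hi = df[["id_1", "id_2"]].max(axis=1)
    df["id_1"], df["id_2"] = lo, hi
    key = df["id_1"].astype(str) + "\x00" + df["id_2"].astype(str)
    dup = df.assign(_k=key).groupby("_k")["r_lr"].nunique()
    if (dup > 1).any():
        bad = dup.index[dup > 1][0].replace("\x00", "/")
        raise ValueError(f"conflicting duplicate dyad in table: {bad}")
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df[PAIR_COLUMNS]


def write_relatedness_table(pairs: pd.DataFrame, path) -> None:
    out = pairs.copy()
    out["r_lr"] = out["r_lr"].round(6)
    if "distance_cm" in out:
        out["distance_cm"] = out["distance_cm"].round(3)
    out.to_csv(path, index=False)
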