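"""Genotype tables, reference allele frequencies and marker polymorphism.

The data model mirrors a codominant microsatellite study: each individual
carries an unordered diploid allele pair per locus (alleles are opaque
integer labels, e.g. fragment sizes), with per-locus missingness. Population
allele frequencies are estimated from a kinship-thinned reference subset —
the dominant male plus at most one randomly chosen adult female per
territory — so that large families do not distort the frequency spectrum.

Missing data conventions accepted on read: empty cell, ``NA``, or the
GenAlEx-style ``0`` allele; a missing call always removes both alleles at
the locus (no half-calls).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "GenotypeTable",
    "FrequencyTable",
    "MarkerSummary",
    "read_genotype_table",
    "write_genotype_table",
    "reference_subset",
    "allele_frequencies",
    "marker_summary",
    "hwe_test",
]

SEXES = ("female", "male", "unknown")
STAGES = ("adult", "juvenile")
DOMINANCE = ("dominant", "subordinate", "na")

MISSING = -1  # sentinel allele code inside call arrays


@dataclass(frozen=True)
class Individual:
    """One fish: identity, group membership, sex/stage and dominance."""

    id: str
    group_id: str
    sex: str = "unknown"
    stage: str = "adult"
    dominance: str = "na"
    standard_length_cm: float | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"bad sex {self.sex!r} for {self.id}")
        if self.stage not in STAGES:
            raise ValueError(f"bad stage {self.stage!r} for {self.id}")
        if self.dominance not in DOMINANCE:
            raise ValueError(f"bad dominance {self.dominance!r} for {self.id}")


class GenotypeTable:
    """Individuals x loci diploid genotype matrix.

    Parameters
    ----------
    individuals
        Ordered list of :class:`Individual`; IDs must be unique.
    loci
        Ordered locus names.
    calls
        ``(n_individuals, n_loci, 2)`` integer array of allele labels, with
        ``-1`` in both slots for a missing call. Allele pairs are unordered;
        the stored order is not meaningful.
    """

    def __init__(self, individuals: list[Individual], loci: list[str], calls: np.ndarray):
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual IDs: {dupes}")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(individuals)}, {len(loci)}, 2)"
            )
        # normalise half-calls (one allele missing) to fully missing
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            warnings.warn(f"{int(half.sum())} half-calls set to missing")
            calls = calls.copy()
            calls[half] = MISSING
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.calls = calls
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def row(self, individual_id: str) -> int:
        return self._index[individual_id]

    def genotype(self, individual_id: str, locus: str):
        """Allele pair at ``locus`` or ``None`` when missing."""
        g = self.calls[self.row(individual_id), self.loci.index(locus)]
        if g[0] == MISSING:
            return None
        return (int(g[0]), int(g[1]))

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def n_genotyped_loci(self) -> np.ndarray:
        """Per-individual count of successfully genotyped loci."""
        return (~self.missing_mask).sum(axis=1)

    def groups(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.group_id, []).append(ind)
        return out

    def validate(self) -> list[str]:
        """Structural checks; returns a list of warnings (raises on errors).

        Each group must have at most one dominant male among its adult
        males and juveniles must carry dominance ``na``.
        """
        notes = []
        for ind in self.individuals:
            if ind.stage == "juvenile" and ind.dominance != "na":
                raise ValueError(f"juvenile {ind.id} has dominance {ind.dominance}")
        for gid, members in self.groups().items():
            doms = [m for m in members if m.dominance == "dominant"]
            if len(doms) > 1:
                raise ValueError(f"group {gid} has {len(doms)} dominant males")
            if not doms:
                notes.append(f"group {gid} has no genotyped dominant male")
            for d in doms:
                if not (d.sex == "male" and d.stage == "adult"):
                    raise ValueError(f"dominant {d.id} is not an adult male")
        return notes

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "id": [i.id for i in self.individuals],
            "group_id": [i.group_id for i in self.individuals],
            "sex": [i.sex for i in self.individuals],
            "stage": [i.stage for i in self.individuals],
            "dominance": [i.dominance for i in self.individuals],
            "sl_cm": [i.standard_length_cm for i in self.individuals],
        }
        df = pd.DataFrame(cols)
        for j, locus in enumerate(self.loci):
            for slot in (0, 1):
                col = self.calls[:, j, slot].astype(object)
                col[self.calls[:, j, slot] == MISSING] = ""
                df[f"{locus}_{slot + 1}"] = col
        return df


# -- readers / writers ---------------------------------------------------

def _parse_allele(value) -> int:
    if value is None:
        return MISSING
    s = str(value).strip()
    if s in ("", "NA", "nan", "None"):
        return MISSING
    a = int(float(s))
    return MISSING if a == 0 else a  # GenAlEx missing convention


def _row_individual(rec: dict, row_label: str) -> Individual:
    sex = str(rec.get("sex", "unknown")).strip().lower()
    if sex in ("f", "female"):
        sex = "female"
    elif sex in ("m", "male"):
        sex = "male"
    elif sex in ("", "u", "unknown", "nan"):
        sex = "unknown"
    else:
        warnings.warn(f"{row_label}: unknown sex code {sex!r}, stored as unknown")
        sex = "unknown"
    stage = str(rec.get("stage", "adult")).strip().lower() or "adult"
    dom = str(rec.get("dominance", "na")).strip().lower().replace("n/a", "na") or "na"
    if dom in ("", "nan"):
        dom = "na"
    sl = rec.get("sl_cm")
    try:
        sl = float(sl) if sl not in (None, "") and sl == sl else None
    except (TypeError, ValueError):
        sl = None
    return Individual(
        id=str(rec["id"]),
        group_id=str(rec["group_id"]),
        sex=sex,
        stage=stage if stage in STAGES else "adult",
        dominance=dom,
        standard_length_cm=sl,
    )


def read_genotype_table(path, format: str = "csv") -> GenotypeTable:
    """Read a genotype file.

    ``csv``: columns ``id,group_id,sex,stage,dominance,sl_cm`` followed by
    two columns ``<locus>_1,<locus>_2`` per locus.

    ``genalex``: the three GenAlEx header rows (counts line, title line,
    column line with one locus name per allele pair) followed by data rows
    ``sample, pop, alleles...``; optional trailing ``sex,stage,dominance``
    columns carry the metadata GenAlEx itself does not store. ``0`` means
    missing in either dialect.
    """
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        meta = ["id", "group_id", "sex", "stage", "dominance", "sl_cm"]
        allele_cols = [c for c in df.columns if c not in meta]
        loci = []
        for c in allele_cols:
            base, _, suffix = c.rpartition("_")
            if suffix not in ("1", "2") or not base:
                raise ValueError(f"unrecognised allele column {c!r}")
            if base not in loci:
                loci.append(base)
        for locus in loci:
            for s in ("1", "2"):
                if f"{locus}_{s}" not in df.columns:
                    raise ValueError(f"locus {locus} lacks column {locus}_{s}")
        individuals, rows = [], []
        for ridx, rec in df.iterrows():
            try:
                row = [
                    (_parse_allele(rec[f"{l}_1"]), _parse_allele(rec[f"{l}_2"]))
                    for l in loci
                ]
            except ValueError as exc:
                raise ValueError(f"row {ridx} ({rec.get('id')}): bad allele: {exc}")
            individuals.append(_row_individual(rec.to_dict(), f"row {ridx}"))
            rows.append(row)
        calls = np.array(rows, dtype=np.int64) if rows else np.empty((0, len(loci), 2), int)
        return GenotypeTable(individuals, loci, calls)

    if format == "genalex":
        raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False,
                          skip_blank_lines=False)
        header = [str(x).strip() for x in raw.iloc[2].tolist()]
        loci = [h for h in header[2:] if h and h.lower() not in ("sex", "stage", "dominance")]
        n_loci = len(loci)
        extra = [h.lower() for h in header[2 + 2 * n_loci:] if h]
        individuals, rows = [], []
        for ridx in range(3, len(raw)):
            rec = [str(x).strip() for x in raw.iloc[ridx].tolist()]
            if not rec or not rec[0]:
                continue
            alleles = rec[2:2 + 2 * n_loci]
            row = [
                (_parse_allele(alleles[2 * j]), _parse_allele(alleles[2 * j + 1]))
                for j in range(n_loci)
            ]
            meta = {"id": rec[0], "group_id": rec[1]}
            for k, name in enumerate(extra):
                pos = 2 + 2 * n_loci + k
                if pos < len(rec):
                    meta[name] = rec[pos]
            individuals.append(_row_individual(meta, f"row {ridx}"))
            rows.append(row)
        calls = np.array(rows, dtype=np.int64) if rows else np.empty((0, n_loci, 2), int)
        return GenotypeTable(individuals, loci, calls)

    raise ValueError(f"unknown format {format!r}")


def write_genotype_table(table: GenotypeTable, path, format: str = "csv") -> None:
    """Write ``table``; inverse of :func:`read_genotype_table`."""
    if format == "csv":
        table.to_dataframe().to_csv(path, index=False)
        return
    if format == "genalex":
        n, L = len(table), len(table.loci)
        lines = [
            ",".join([str(L), str(n), "1", str(n)] + [""] * (2 * L + 1)),
            ",".join(["shellkin export"] + [""] * (2 * L + 4)),
        ]
        header = ["Sample", "Pop"]
        for locus in table.loci:
            header += [locus, ""]
        header += ["sex", "stage", "dominance"]
        lines.append(",".join(header))
        for i, ind in enumerate(table.individuals):
            rec = [ind.id, ind.group_id]
            for j in range(L):
                g = table.calls[i, j]
                rec += ["0" if g[0] == MISSING else str(g[0]),
                        "0" if g[1] == MISSING else str(g[1])]
            rec += [ind.sex, ind.stage, ind.dominance]
            lines.append(",".join(rec))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


# -- reference subset and allele frequencies ------------------------------

def reference_subset(table: GenotypeTable, seed: int) -> list[Individual]:
    """Kinship-thinned reference subset for frequency estimation.

    From every territory, the dominant male (when genotyped) plus one
    uniformly chosen adult female (when any is present). Deterministic for
    a given seed; groups without a genotyped dominant male contribute only
    their female and are logged.
    """
    chosen: list[Individual] = []
    for gid in sorted(table.groups()):
        members = table.groups()[gid]
        doms = [m for m in members if m.dominance == "dominant"]
        if doms:
            chosen.append(doms[0])
        else:
            logger.info("group %s: no genotyped dominant male in table", gid)
        females = sorted(
            (m for m in members if m.sex == "female" and m.stage == "adult"),
            key=lambda m: m.id,
        )
        if females:
            rng = rng_for(seed, "reference-subset", gid)
            chosen.append(females[int(rng.integers(len(females)))])
    return chosen


@dataclass
class FrequencyTable:
    """Per-locus allele frequency maps estimated from a reference subset."""

    loci: list[str]
    freqs: dict[str, dict[int, float]]
    n_reference: int
    reference_ids: list[str] = field(default_factory=list)
    n_augmented: int = 0

    def __post_init__(self):
        for locus in self.loci:
            f = self.freqs[locus]
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus}: frequencies sum to {total}")
            if any(v <= 0 for v in f.values()):
                raise ValueError(f"{locus}: non-positive frequency")

    def monomorphic(self, locus: str) -> bool:
        return len(self.freqs[locus]) == 1

    def frequency(self, locus: str, allele: int) -> float:
        return self.freqs[locus][allele]

    def augment(self, locus: str, allele: int) -> None:
        """Add a novel allele seen outside the reference subset.

        The newcomer enters at frequency ``1 / (2 n_reference + 1)`` and the
        locus is renormalised — dropping the locus instead would bias pairs
        that carry rare alleles.
        """
        if allele in self.freqs[locus]:
            return
        eps = 1.0 / (2 * self.n_reference + 1)
        f = self.freqs[locus]
        scale = 1.0 - eps
        self.freqs[locus] = {a: v * scale for a, v in f.items()}
        self.freqs[locus][allele] = eps
        self.n_augmented += 1
        logger.info("locus %s: augmented with novel allele %s at %.3g", locus, allele, eps)


def allele_frequencies(subset: list[Individual], table: GenotypeTable) -> FrequencyTable:
    """Allele frequencies per locus over the non-missing subset genotypes."""
    if not subset:
        raise ValueError("empty reference subset")
    rows = [table.row(ind.id) for ind in subset]
    calls = table.calls[rows]
    freqs: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(table.loci):
        col = calls[:, j, :]
        alleles = col[col != MISSING]
        if alleles.size == 0:
            raise ValueError(f"locus {locus}: no non-missing calls in reference subset")
        labels, counts = np.unique(alleles, return_counts=True)
        freqs[locus] = {int(a): c / alleles.size for a, c in zip(labels, counts)}
    return FrequencyTable(
        loci=list(table.loci),
        freqs=freqs,
        n_reference=len(subset),
        reference_ids=[ind.id for ind in subset],
    )


# -- marker polymorphism summary -----------------------------------------

def expected_heterozygosity(freq_map: dict[int, float]) -> float:
    """``1 - sum p_i^2`` (no small-sample correction)."""
    return 1.0 - sum(p * p for p in freq_map.values())


def hwe_test(genotypes: np.ndarray, method: str = "chisq",
             n_mc: int = 2000, seed: int = 0) -> float:
    """Hardy-Weinberg test P-value for one locus.

    Parameters
    ----------
    genotypes
        ``(n, 2)`` array of allele labels, missing rows removed.
    method
        ``"chisq"`` — chi-square on genotype counts with rare-allele
        pooling (alleles with expected copy count < 5 merged into one
        class); ``"exact-mc"`` — Monte-Carlo exact test that shuffles the
        observed alleles into genotypes and compares the same chi-square
        statistic (Guo-Thompson style).
    """
    geno = np.asarray(genotypes)
    geno = geno[geno[:, 0] != MISSING]
    n = len(geno)
    if n == 0:
        return 1.0
    alleles, counts = np.unique(geno, return_counts=True)
    p = counts / (2 * n)
    if len(alleles) < 2:
        return 1.0

    # pool alleles whose expected copy count is below 5
    keep = counts >= 5
    if keep.sum() < len(alleles):
        pooled_labels = {a: (a if k else -9) for a, k in zip(alleles, keep)}
    else:
        pooled_labels = {a: a for a in alleles}

    def _chisq(g: np.ndarray):
        """Chi-square statistic and class count, with genotype classes of
        expected count < 1 merged into one (keeps the chi-square
        approximation honest at the Bonferroni tail)."""
        lab = np.vectorize(pooled_labels.get)(g)
        lab.sort(axis=1)
        al, cnt = np.unique(lab, return_counts=True)
        q = dict(zip(al, cnt / (2 * len(g))))
        pairs_, obs_ = np.unique(lab, axis=0, return_counts=True)
        obs_map = {tuple(x): c for x, c in zip(pairs_, obs_)}
        classes = sorted(q)
        kept = []
        pooled_o = pooled_e = 0.0
        for i, a in enumerate(classes):
            for b in classes[i:]:
                e = len(g) * (q[a] ** 2 if a == b else 2 * q[a] * q[b])
                o = obs_map.get((min(a, b), max(a, b)), 0)
                if e < 1.0:
                    pooled_o += o
                    pooled_e += e
                else:
                    kept.append((o, e))
        if pooled_e > 0:
            kept.append((pooled_o, pooled_e))
        stat = sum((o - e) ** 2 / e for o, e in kept)
        return stat, len(kept)

    stat, n_classes = _chisq(geno)
    k_eff = len(set(pooled_labels.values()))
    if k_eff < 2:
        return 1.0
    if method == "chisq":
        df = max(n_classes - k_eff, 1)
        return float(stats.chi2.sf(stat, df))
    if method == "exact-mc":
        rng = rng_for(seed, "hwe-mc")
        flat = geno.reshape(-1).copy()
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(flat)
            if _chisq(flat.reshape(-1, 2))[0] >= stat - 1e-12:
                hits += 1
        return (hits + 1) / (n_mc + 1)
    raise ValueError(f"unknown HWE method {method!r}")


@dataclass
class MarkerSummary:
    """Per-locus polymorphism table (k, N, Hobs, Hexp, HWE)."""

    table: pd.DataFrame
    bonferroni_alpha: float = 0.0025

    @property
    def mean_alleles_per_locus(self) -> float:
        return float(self.table["k"].mean())

    @property
    def mean_expected_heterozygosity(self) -> float:
        return float(self.table["h_exp"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def marker_summary(table: GenotypeTable, freqs: FrequencyTable,
                   hwe_method: str = "chisq", seed: int = 0,
                   bonferroni_alpha: float = 0.0025) -> MarkerSummary:
    """Marker polymorphism over the reference subset behind ``freqs``.

    For each locus: allele count k, number of reference individuals
    genotyped N, observed heterozygosity (proportion of heterozygotes),
    expected heterozygosity ``1 - sum p^2`` and a Hardy-Weinberg test
    P-value with its Bonferroni pass flag (``hwe_p >= bonferroni_alpha``).
    """
    rows = [table.row(i) for i in freqs.reference_ids] if freqs.reference_ids \
        else list(range(len(table)))
    calls = table.calls[rows]
    records = []
    for j, locus in enumerate(table.loci):
        col = calls[:, j, :]
        ok = col[:, 0] != MISSING
        geno = col[ok]
        n = int(ok.sum())
        h_obs = float((geno[:, 0] != geno[:, 1]).mean()) if n else float("nan")
        h_exp = expected_heterozygosity(freqs.freqs[locus])
        p = hwe_test(geno, method=hwe_method, seed=seed)
        records.append(
            dict(locus=locus, k=len(freqs.freqs[locus]), n_genotyped=n,
                 h_obs=round(h_obs, 6), h_exp=round(h_exp, 6),
                 hwe_p=round(p, 6), hwe_pass=bool(p >= bonferroni_alpha))
        )
    return MarkerSummary(pd.DataFrame(records), bonferroni_alpha)
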