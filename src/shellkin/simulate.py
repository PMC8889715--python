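"""Synthetic study-shaped populations with known pedigree truth.

Generates everything the pipeline consumes — a territory map, social groups,
microsatellite genotypes — from a multi-generation pedigree with
sex-specific dispersal, so that every downstream stage can be validated
against known truth (parameter recovery) rather than against unavailable
field data.

The generative model:

* territories are a clustered hard-core point process in a ~10 x 10 m
  quadrat with a 30 cm minimum nearest-neighbour spacing — clumped, like a
  surveyed shell bed, so neighbourhood density has real dynamic range;
* each territory holds one dominant male, queueing subordinate males and a
  few adult females; the dominant male sires every brood (high reproductive
  skew; no extra-group paternity), except that daughters do not spawn with
  their own father;
* the population runs through ``n_cycles`` overlapping breeding cycles:
  adults die at sex-specific rates, a dead dominant male is succeeded by
  his longest-queueing subordinate or — when the queue is empty — by a
  subordinate taking over from a nearby group, maturing offspring recruit
  and may emigrate, resident females may switch groups between broods, and
  every female then breeds;
* dispersal is travel-budget limited: a mover draws a distance budget from
  its sex-specific exponential kernel (scale ``d_f`` / ``d_m``), and each
  territory within budget admits the joiner with a fixed probability
  (residents resist prospective joiners), so emigration success rises with
  local territory availability — the ecological constraint on movement;
* genotypes are inherited Mendelianly; genotyping failure is a
  per-individual mixture (a small fraction of fish fail across most loci,
  the rest drop single loci rarely), calibrated so ~95% of fish pass the
  >= 10-loci retention filter.

Defaults reproduce the study population's marginal shapes — ~128 groups of
6.3 fish on average (1.9 females, 1.5 males, 3.0 juveniles), 20 loci with
~16 observable alleles each and expected heterozygosity ~0.75 — and, with
female-biased dispersal (females emigrate more often and farther, males
queue at home and relocate only to nearby vacancies), the study's standing
kin structure: high within-group male-male relatedness, a steep short-range
decline of between-group male-male relatedness, and female relatedness that
accumulates only where dispersal is availability-limited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._util import rng_for
from .datasets import STUDY_SHAPE
from .genotypes import (MISSING, FrequencyTable, GenotypeTable, Individual,
                        allele_frequencies, reference_subset)
from .pairs import group_composition_summary
from .spatial import TerritoryMap

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_shell_bed",
    "simulate_population",
    "simulate_dyads",
    "export_study_shape_report",
    "frequency_table_from_vectors",
]


@dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic population (distances in cm)."""

    n_territories: int = 128
    quadrat_cm: tuple = (1000.0, 1000.0)
    min_spacing_cm: float = 30.0
    n_clusters: int = 3            # clumps of the territory intensity field
    cluster_sd_cm: float = 130.0   # clump spread; baseline fills the rest
    cluster_weight: float = 0.85   # intensity mass in clumps vs uniform floor

    founder_females_mean: float = 1.9   # Poisson, clipped at max_females
    founder_subordinates_mean: float = 0.4
    max_females: int = 6
    brood_size_mean: float = 3.2        # Poisson offspring per female per cycle
    maturation_prob_female: float = 0.104  # newborn -> adult recruit next cycle
    maturation_prob_male: float = 0.15     # males recruit into queues earlier
    juvenile_census_survival: float = 0.52  # final cohort observed as juveniles
    adult_female_survival: float = 0.85     # per breeding cycle
    adult_male_survival: float = 0.74
    n_cycles: int = 14                  # overlapping breeding cycles before census

    n_loci: int = 20
    allele_count_range: tuple = (6, 27)  # uniform integer, mean ~16.5
    dirichlet_concentration: float = 0.28
    rare_allele_floor: float = 0.008    # keeps nominal alleles observable

    p_disperse_female: float = 0.9
    p_disperse_male: float = 0.2
    dispersal_scale_female_cm: float = 150.0
    dispersal_scale_male_cm: float = 60.0
    breeding_dispersal_prob: float = 0.45  # adult females may switch groups each cycle
    male_queue_cap: int = 3  # subordinate males tolerated per territory
    avoid_father_mating: bool = True  # daughters skip spawning with their own father
    join_prob_female: float = 0.15  # per reachable territory: residents admit a joiner
    join_prob_male: float = 0.15    # male joiners face more resistance
    takeover_from_neighbours: bool = True  # vacant dominances go to nearby queuers

    individual_failure_rate: float = 0.05
    failed_locus_dropout: float = 0.85
    base_locus_dropout: float = 0.015

    def __post_init__(self):
        if self.founder_females_mean < 0 or self.brood_size_mean < 0:
            raise ValueError("negative rate in config")
        for p in (self.maturation_prob_female, self.maturation_prob_male,
                  self.p_disperse_female, self.p_disperse_male,
                  self.breeding_dispersal_prob, self.join_prob_female,
                  self.join_prob_male, self.juvenile_census_survival,
                  self.adult_female_survival, self.adult_male_survival,
                  self.individual_failure_rate, self.failed_locus_dropout,
                  self.base_locus_dropout):
            if not 0 <= p <= 1:
                raise ValueError("probability outside [0, 1] in config")
        if self.min_spacing_cm >= min(self.quadrat_cm):
            raise ValueError("spacing must be below the quadrat size")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated population."""

    parents: dict = field(default_factory=dict)        # id -> (mother, father) | None
    natal_group: dict = field(default_factory=dict)    # id -> group_id
    realized_group: dict = field(default_factory=dict)  # id -> group_id
    dispersal_events: list = field(default_factory=list)
    failed_dispersals: list = field(default_factory=list)  # emigration drawn, no reachable territory
    failed_individuals: list = field(default_factory=list)
    birth_cycle: dict = field(default_factory=dict)  # id -> cycle introduced (founders 0)

    def pedigree_relatedness(self, id_a: str, id_b: str) -> float:
        """Twice the kinship coefficient (founders unrelated)."""
        return 2.0 * self._kinship(id_a, id_b)

    def _kinship(self, a: str, b: str, _memo: dict | None = None) -> float:
        """Recursive kinship; always expands the later-born individual, so
        the expanded one is never an ancestor of the other."""
        if _memo is None:
            _memo = getattr(self, "_kin_memo", None)
            if _memo is None:
                _memo = self._kin_memo = {}
        if a == b:
            return 0.5
        key = (a, b) if a < b else (b, a)
        if key in _memo:
            return _memo[key]
        if self.birth_cycle.get(a, 0) < self.birth_cycle.get(b, 0):
            a, b = b, a
        pa = self.parents.get(a)
        if pa is None:
            pb = self.parents.get(b)
            if pb is None:
                val = 0.0
            else:
                val = 0.5 * (self._kinship(a, pb[0], _memo) +
                             self._kinship(a, pb[1], _memo))
        else:
            val = 0.5 * (self._kinship(pa[0], b, _memo) +
                         self._kinship(pa[1], b, _memo))
        _memo[key] = val
        return val

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "parents": {k: list(v) if v else None for k, v in self.parents.items()},
                "natal_group": self.natal_group,
                "realized_group": self.realized_group,
                "dispersal_events": self.dispersal_events,
                "failed_dispersals": self.failed_dispersals,
                "failed_individuals": self.failed_individuals,
                "birth_cycle": self.birth_cycle,
            }, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            parents={k: tuple(v) if v else None for k, v in d["parents"].items()},
            natal_group=d["natal_group"],
            realized_group=d["realized_group"],
            dispersal_events=d["dispersal_events"],
            failed_dispersals=d.get("failed_dispersals", []),
            failed_individuals=d["failed_individuals"],
            birth_cycle=d.get("birth_cycle", {}),
        )


# -- territory map -------------------------------------------------------

def generate_shell_bed(config: SimulationConfig, seed: int) -> TerritoryMap:
    """Clustered hard-core point process over the quadrat.

    Proposals are drawn from a clumped intensity field (a mixture of
    Gaussian clusters over a uniform floor — surveyed shell beds are
    strongly clumped, with dense patches and sparse fringes, which is what
    gives neighbourhood density its dynamic range) and rejected within
    ``min_spacing_cm`` of an accepted point. Fails loudly if the packing
    cannot be completed in a bounded number of proposals. Set
    ``cluster_weight = 0`` for a homogeneous hard-core process.
    """
    rng = rng_for(seed, "shell-bed")
    w, h = config.quadrat_cm
    centres = rng.uniform((0.15 * w, 0.15 * h), (0.85 * w, 0.85 * h),
                          size=(max(config.n_clusters, 1), 2))
    pts: list[np.ndarray] = []
    max_tries = 20_000 * max(config.n_territories, 1)
    tries = 0
    sp2 = config.min_spacing_cm ** 2
    while len(pts) < config.n_territories:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {config.n_territories} territories at "
                f"{config.min_spacing_cm} cm spacing in {w}x{h} cm"
            )
        if rng.random() < config.cluster_weight:
            c = centres[int(rng.integers(len(centres)))]
            cand = rng.normal(c, config.cluster_sd_cm)
            if not (0 <= cand[0] <= w and 0 <= cand[1] <= h):
                continue
        else:
            cand = rng.uniform((0, 0), (w, h))
        if all(((cand - p) ** 2).sum() >= sp2 for p in pts):
            pts.append(cand)
    ids = [f"G{i + 1:03d}" for i in range(config.n_territories)]
    return TerritoryMap(ids, np.array(pts))


# -- allele frequencies ---------------------------------------------------

def _draw_locus_frequencies(config: SimulationConfig, rng: np.random.Generator):
    """Per-locus true allele frequency vectors.

    Dirichlet prior with a rare-allele floor: low concentration gives the
    skewed spectra (few common + many rare alleles) that reconcile high
    nominal allele counts with expected heterozygosity ~0.75, while the
    floor keeps every allele frequent enough to be observable in a sample
    of a few hundred fish.
    """
    lo, hi = config.allele_count_range
    out = []
    for _ in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        raw = rng.dirichlet(np.full(k, config.dirichlet_concentration))
        p = np.maximum(raw, config.rare_allele_floor)
        p /= p.sum()
        out.append(p)
    return out


def frequency_table_from_vectors(fvecs, loci=None, n_reference: int = 1000,
                                 allele_base: int = 100) -> FrequencyTable:
    """Wrap true frequency vectors as a :class:`FrequencyTable`.

    Allele labels are ``allele_base + 2*i`` (even steps, like dinucleotide
    fragment sizes).
    """
    loci = loci or [f"L{i + 1:02d}" for i in range(len(fvecs))]
    freqs = {
        locus: {allele_base + 2 * i: float(p) for i, p in enumerate(f)}
        for locus, f in zip(loci, fvecs)
    }
    return FrequencyTable(loci=loci, freqs=freqs, n_reference=n_reference)


def _sample_genotype(fvec, rng, allele_base=100):
    a, b = rng.choice(len(fvec), size=2, p=fvec)
    return allele_base + 2 * int(a), allele_base + 2 * int(b)


# -- population simulation ------------------------------------------------

def simulate_population(config: SimulationConfig, seed: int):
    """Simulate one study-shaped population.

    Runs ``n_cycles`` overlapping breeding cycles. Per cycle: adults die
    with sex-specific probabilities (a dead dominant male is replaced by
    his longest-queueing subordinate, or by an unrelated immigrant male
    when the queue is empty — territory takeover); the previous cycle's
    newborns recruit with probability ``maturation_prob`` and either stay
    or emigrate under the travel-budget kernel; then every adult female
    breeds with her group's dominant male. The final cycle's newborns are
    the census juveniles. Multi-cycle turnover is what lets related
    females accumulate in dispersal-limited (sparse) neighbourhoods and
    male lineages accumulate everywhere, the standing kin structure the
    study sampled.

    Returns ``(table, territory_map, truth)`` — a :class:`GenotypeTable`
    whose ``group_id`` fields are the realized (post-dispersal) groups, a
    :class:`TerritoryMap`, and the :class:`SyntheticTruth` pedigree.
    """
    tmap = generate_shell_bed(config, seed)
    rng = rng_for(seed, "population")
    fvecs = _draw_locus_frequencies(config, rng_for(seed, "loci"))
    loci = [f"L{i + 1:02d}" for i in range(config.n_loci)]
    dist = tmap.distances()
    gindex = {g: i for i, g in enumerate(tmap.group_ids)}
    scale = {"female": config.dispersal_scale_female_cm,
             "male": config.dispersal_scale_male_cm}
    p_move = {"female": config.p_disperse_female, "male": config.p_disperse_male}

    truth = SyntheticTruth()
    genotypes: dict[str, np.ndarray] = {}
    counter = [0]

    def _founder_genotype():
        g = np.empty((config.n_loci, 2), dtype=np.int64)
        for j, f in enumerate(fvecs):
            g[j] = _sample_genotype(f, rng)
        return g

    def _mendelian(mother: str, father: str):
        gm, gf = genotypes[mother], genotypes[father]
        pick_m = rng.integers(0, 2, size=config.n_loci)
        pick_f = rng.integers(0, 2, size=config.n_loci)
        idx = np.arange(config.n_loci)
        return np.stack([gm[idx, pick_m], gf[idx, pick_f]], axis=1)

    def _new_founder(gid: str, sex: str, cycle: int, tag: str) -> str:
        counter[0] += 1
        iid = f"{gid}-{tag}{counter[0]}"
        genotypes[iid] = _founder_genotype()
        truth.parents[iid] = None
        truth.birth_cycle[iid] = cycle
        truth.natal_group[iid] = gid
        truth.realized_group[iid] = gid
        return iid

    # group state: dominant male, queueing subordinates (oldest first), females
    dominant: dict[str, str] = {}
    subs: dict[str, list[str]] = {g: [] for g in tmap.group_ids}
    females: dict[str, list[str]] = {g: [] for g in tmap.group_ids}
    for gid in tmap.group_ids:
        dominant[gid] = _new_founder(gid, "male", 0, "DM")
        for _ in range(min(int(rng.poisson(config.founder_subordinates_mean)), 4)):
            subs[gid].append(_new_founder(gid, "male", 0, "SM"))
        for _ in range(min(int(rng.poisson(config.founder_females_mean)),
                           config.max_females)):
            females[gid].append(_new_founder(gid, "female", 0, "F"))

    join_prob = {"female": config.join_prob_female, "male": config.join_prob_male}

    def _disperse(iid: str, gid: str, sex: str, always_attempt: bool = False) -> str:
        """Travel-budget dispersal with resident resistance.

        A distance budget drawn from the sex-specific exponential kernel
        limits the reachable territories; candidate destinations are
        visited in kernel-weighted random order and each admits the
        joiner with a fixed per-territory probability (residents resist
        prospective joiners), so emigration success rises smoothly with
        the number of territories within reach. Failure means staying
        home — the availability constraint on dispersal.
        """
        if not always_attempt and rng.random() >= p_move[sex]:
            return gid
        budget = rng.exponential(scale[sex])
        d = dist[gindex[gid]].copy()
        d[gindex[gid]] = np.inf
        eligible = np.flatnonzero(d <= budget)
        dest = None
        if eligible.size:
            w = np.exp(-d[eligible] / scale[sex])
            order = rng.permuted(eligible) if w.sum() <= 0 else rng.choice(
                eligible, size=eligible.size, replace=False, p=w / w.sum())
            for cand in order:
                if rng.random() < join_prob[sex]:
                    dest = tmap.group_ids[int(cand)]
                    break
        if dest is None:
            truth.failed_dispersals.append(dict(id=iid, origin=gid, sex=sex))
            return gid
        truth.dispersal_events.append(dict(
            id=iid, origin=gid, destination=dest,
            distance_cm=round(float(dist[gindex[gid], gindex[dest]]), 3),
            sex=sex,
        ))
        return dest

    newborns: list[tuple[str, str]] = []  # (id, natal group) of last cohort
    for cycle in range(1, config.n_cycles + 1):
        if cycle > 1:
            # adult turnover
            for gid in tmap.group_ids:
                females[gid] = [f for f in females[gid]
                                if rng.random() < config.adult_female_survival]
                subs[gid] = [m for m in subs[gid]
                             if rng.random() < config.adult_male_survival]
            for gid in tmap.group_ids:
                if rng.random() >= config.adult_male_survival:
                    if subs[gid]:
                        dominant[gid] = subs[gid].pop(0)  # queue inheritance
                        continue
                    # vacancy: a queueing subordinate from a nearby group
                    # moves in and takes over (males relocate to accessible
                    # vacancies rather than exploring at large)
                    # takeover is male movement: disabled when males never
                    # disperse at all
                    donor = None
                    cands = [g for g in tmap.group_ids if g != gid and subs[g]]
                    if config.takeover_from_neighbours and cands and \
                            config.p_disperse_male > 0:
                        d = np.array([dist[gindex[gid], gindex[g]] for g in cands])
                        w = np.exp(-d / config.dispersal_scale_male_cm)
                        if w.sum() > 0:
                            donor = cands[int(rng.choice(len(cands), p=w / w.sum()))]
                    if donor is not None:
                        newdom = subs[donor].pop(0)
                        dominant[gid] = newdom
                        truth.realized_group[newdom] = gid
                        truth.dispersal_events.append(dict(
                            id=newdom, origin=donor, destination=gid,
                            distance_cm=round(float(dist[gindex[donor], gindex[gid]]), 3),
                            sex="male",
                        ))
                    else:
                        dominant[gid] = _new_founder(gid, "male", cycle, "TM")
            # breeding dispersal: resident adult females may switch groups
            # (scaled by the female dispersal propensity, so p_f = 0 pins
            # every female to her group)
            bd_prob = config.breeding_dispersal_prob * config.p_disperse_female
            for gid in tmap.group_ids:
                movers = [f for f in females[gid]
                          if rng.random() < bd_prob]
                for f in movers:
                    dest = _disperse(f, gid, "female", always_attempt=True)
                    if dest != gid:
                        females[gid].remove(f)
                        females[dest].append(f)
                        truth.realized_group[f] = dest
            # recruitment of the previous cohort (sex-specific maturation)
            for oid, natal in newborns:
                sex = "female" if rng.random() < 0.5 else "male"
                m_p = (config.maturation_prob_female if sex == "female"
                       else config.maturation_prob_male)
                if rng.random() >= m_p:
                    continue
                realized = _disperse(oid, natal, sex)
                if sex == "female":
                    if realized != natal and \
                            len(females[realized]) >= config.max_females + 3:
                        realized = natal  # destination saturated: stay home
                    females[realized].append(oid)
                    truth.realized_group[oid] = realized
                else:
                    truth.realized_group[oid] = realized
                    if len(subs[realized]) < config.male_queue_cap:
                        subs[realized].append(oid)
                    # surplus males beyond the queue cap are not tolerated
                    # and perish (floaters face heavy predation)
        # breeding (skipping father-daughter spawnings — inbreeding avoidance)
        newborns = []
        for gid in tmap.group_ids:
            dad = dominant[gid]
            for mum in females[gid]:
                if config.avoid_father_mating:
                    pm = truth.parents.get(mum)
                    if pm is not None and pm[1] == dad:
                        continue
                for _ in range(int(rng.poisson(config.brood_size_mean))):
                    counter[0] += 1
                    oid = f"{gid}-O{counter[0]}"
                    genotypes[oid] = _mendelian(mum, dad)
                    truth.parents[oid] = (mum, dad)
                    truth.birth_cycle[oid] = cycle
                    truth.natal_group[oid] = gid
                    truth.realized_group[oid] = gid
                    newborns.append((oid, gid))

    # census: all living adults, plus final-cohort juveniles that survive
    # to the census
    meta: list[dict] = []
    for gid in tmap.group_ids:
        meta.append(dict(id=dominant[gid], sex="male", stage="adult",
                         dominance="dominant"))
        for m in subs[gid]:
            meta.append(dict(id=m, sex="male", stage="adult", dominance="subordinate"))
        for f in females[gid]:
            meta.append(dict(id=f, sex="female", stage="adult", dominance="na"))
    for oid, natal in newborns:
        if rng.random() < config.juvenile_census_survival:
            meta.append(dict(id=oid, sex="unknown", stage="juvenile", dominance="na"))

    # genotyping failure
    drop_rng = rng_for(seed, "dropout")
    individuals, calls = [], []
    for rec in meta:
        iid = rec["id"]
        failed = drop_rng.random() < config.individual_failure_rate
        if failed:
            truth.failed_individuals.append(iid)
        rate = config.failed_locus_dropout if failed else config.base_locus_dropout
        g = genotypes[iid].copy()
        lost = drop_rng.random(config.n_loci) < rate
        g[lost] = MISSING
        individuals.append(Individual(
            id=iid, group_id=truth.realized_group[iid], sex=rec["sex"],
            stage=rec["stage"], dominance=rec["dominance"],
        ))
        calls.append(g)
    table = GenotypeTable(individuals, loci,
                          np.stack(calls) if calls else np.empty((0, len(loci), 2)))
    table.validate()
    return table, tmap, truth


# -- dyad-level simulation (estimator oracle inputs) ----------------------

RELATIONSHIPS = ("unrelated", "half-sib", "full-sib", "parent-offspring")

PEDIGREE_EXPECTATION = {"unrelated": 0.0, "half-sib": 0.25,
                        "full-sib": 0.5, "parent-offspring": 0.5}


def simulate_dyads(fvecs, relationship: str, n_dyads: int, seed: int,
                   allele_base: int = 100):
    """Genotype pairs of a fixed pedigree relationship, no missingness.

    Returns ``(table, idx1, idx2)`` — a GenotypeTable of ``2 n`` fish where
    dyad ``i`` is rows ``(idx1[i], idx2[i])``. Used to check the estimator
    against its pedigree expectation with exactly known frequencies.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}")
    rng = rng_for(seed, "dyads", relationship)
    L = len(fvecs)
    ks = np.array([len(f) for f in fvecs])

    def draw(n):
        """(n, L, 2) allele-code draws from the true frequencies."""
        out = np.empty((n, L, 2), dtype=np.int64)
        for j, f in enumerate(fvecs):
            out[:, :, 0][:, j] = rng.choice(ks[j], size=n, p=f)
            out[:, :, 1][:, j] = rng.choice(ks[j], size=n, p=f)
        return out

    def pass_one(parent):
        """One gamete per locus from each parent row."""
        n = parent.shape[0]
        pick = rng.integers(0, 2, size=(n, L))
        return np.take_along_axis(parent, pick[:, :, None], axis=2)[:, :, 0]

    n = n_dyads
    if relationship == "unrelated":
        g1, g2 = draw(n), draw(n)
    elif relationship == "parent-offspring":
        g1 = draw(n)
        child = np.stack([pass_one(g1), draw(n)[:, :, 0]], axis=2)
        g2 = child
    elif relationship == "full-sib":
        mum, dad = draw(n), draw(n)
        g1 = np.stack([pass_one(mum), pass_one(dad)], axis=2)
        g2 = np.stack([pass_one(mum), pass_one(dad)], axis=2)
    else:  # half-sib: shared father, different mothers
        dad, mum1, mum2 = draw(n), draw(n), draw(n)
        g1 = np.stack([pass_one(mum1), pass_one(dad)], axis=2)
        g2 = np.stack([pass_one(mum2), pass_one(dad)], axis=2)

    calls = np.empty((2 * n, L, 2), dtype=np.int64)
    calls[0::2], calls[1::2] = g1, g2
    calls = allele_base + 2 * calls
    loci = [f"L{i + 1:02d}" for i in range(L)]
    individuals = [
        Individual(id=f"D{i // 2 + 1}-{'ab'[i % 2]}", group_id=f"D{i // 2 + 1}")
        for i in range(2 * n)
    ]
    table = GenotypeTable(individuals, loci, calls)
    return table, np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)


# -- study-shape report ---------------------------------------------------

def export_study_shape_report(table: GenotypeTable, tmap: TerritoryMap,
                              truth: SyntheticTruth, seed: int = 0,
                              min_loci: int = 10) -> dict:
    """Compare simulated marginals with the study population's.

    Reports group-size structure, marker polymorphism of the reference
    subset, the >= ``min_loci`` retention fraction and nearest-neighbour
    spacing, side by side with the published values.
    """
    _, comp = group_composition_summary(table)
    subset = reference_subset(table, seed)
    freqs = allele_frequencies(subset, table)
    k_obs = [len(freqs.freqs[l]) for l in freqs.loci]
    h_exp = [1.0 - sum(p * p for p in freqs.freqs[l].values()) for l in freqs.loci]
    retained = float((table.n_genotyped_loci() >= min_loci).mean())
    report = {
        "simulated": {
            "n_territories": len(tmap.group_ids),
            "n_fish": len(table),
            "mean_group_size": round(comp["group_size"]["mean"], 3),
            "sd_group_size": round(comp["group_size"]["sd"], 3),
            "mean_females": round(comp["females"]["mean"], 3),
            "mean_males": round(comp["males"]["mean"], 3),
            "mean_juveniles": round(comp["juveniles"]["mean"], 3),
            "mean_alleles_per_locus": round(float(np.mean(k_obs)), 3),
            "mean_expected_heterozygosity": round(float(np.mean(h_exp)), 4),
            "retained_fraction": round(retained, 4),
            "n_reference_fish": len(subset),
            "min_nearest_neighbour_cm": round(
                float(tmap.nearest_neighbour_distances().min()), 2),
            "n_dispersal_events": len(truth.dispersal_events),
        },
        "study": {
            "n_territories": STUDY_SHAPE["n_territories"],
            "n_fish": STUDY_SHAPE["n_fish"],
            "mean_group_size": STUDY_SHAPE["mean_group_size"],
            "mean_females": STUDY_SHAPE["mean_females"],
            "mean_males": STUDY_SHAPE["mean_males"],
            "mean_juveniles": STUDY_SHAPE["mean_juveniles"],
            "mean_alleles_per_locus": 16.4,
            "mean_expected_heterozygosity": 0.75,
            "retained_fraction": STUDY_SHAPE["retained_fraction"],
            "n_reference_fish": STUDY_SHAPE["n_reference_fish"],
        },
    }
    return report
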