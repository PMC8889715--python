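import numpy as np
import pandas as pd
import pytest

import shellkin as sk
from shellkin.simulate import _draw_locus_frequencies
from shellkin._util import rng_for


@pytest.fixture(scope="session")
def small_population():
    """A reduced study-shaped population (64 territories) with truth."""
    cfg = sk.SimulationConfig(n_territories=64)
    table, tmap, truth = sk.simulate_population(cfg, seed=101)
    return cfg, table, tmap, truth


@pytest.fixture(scope="session")
def small_freqs(small_population):
    _, table, _, _ = small_population
    subset = sk.reference_subset(table, seed=101)
    return sk.allele_frequencies(subset, table)


@pytest.fixture(scope="session")
def small_pairs(small_population, small_freqs):
    _, table, tmap, _ = small_population
    return sk.pairwise_matrix(table, small_freqs, territory_map=tmap)


@pytest.fixture(scope="session")
def study_fvecs():
    """True per-locus allele-frequency vectors at study-like polymorphism."""
    return _draw_locus_frequencies(sk.SimulationConfig(), rng_for(3, "loci"))


@pytest.fixture()
def toy_genotype_csv(tmp_path):
    """Three fish, two loci, one missing call."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "id,group_id,sex,stage,dominance,sl_cm,L1_1,L1_2,L2_1,L2_2\n"
        "a,G1,male,adult,dominant,2.9,100,102,200,200\n"
        "b,G1,female,adult,na,2.0,100,100,,\n"
        "c,G2,male,adult,dominant,2.7,102,104,200,202\n"
    )
    return path


def make_within_pairs(rng, n_groups=100, means=None, group_sd=0.05, resid_sd=0.2,
                      counts=(("FF", 3), ("MM", 2), ("FM", 4), ("JJ", 5))):
    """Synthetic within-group pairs table with known category means."""
    means = means or {"FF": 0.05, "MM": 0.23, "FM": 0.09, "JJ": 0.24}
    rows = []
    for g in range(n_groups):
        ge = rng.normal(0.0, group_sd)
        for cat, n in counts:
            for _ in range(n):
                rows.append(dict(group_1=f"G{g:03d}", group_2=f"G{g:03d}",
                                 category=cat, same_group=True, distance_cm=0.0,
                                 n_loci=20,
                                 r_lr=means[cat] + ge + rng.normal(0.0, resid_sd)))
    return pd.DataFrame(rows)
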