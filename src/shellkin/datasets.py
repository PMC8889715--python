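"""Packaged reference data for the study population.

Two small tables travel with the package:

* the published 20-locus microsatellite marker panel summary for the
  *Neolamprologus multifasciatus* study population (allele counts, sample
  sizes, observed/expected heterozygosity and Hardy-Weinberg P per locus),
  used as the reference point for marker-polymorphism aggregation;
* the field census of the fully sampled ~10 x 10 m shell-bed quadrat
  (812 fish in 128 territories: 239 adult females, 191 adult males,
  382 juveniles), used as the target shape for the synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_marker_panel", "study_census", "STUDY_SHAPE"]

#: Field census of the study quadrat.
STUDY_SHAPE = {
    "n_territories": 128,
    "n_fish": 812,
    "n_females": 239,
    "n_males": 191,
    "n_juveniles": 382,
    "mean_group_size": 6.3,
    "mean_females": 1.9,
    "mean_males": 1.5,
    "mean_juveniles": 3.0,
    "retained_fraction": 0.951,  # fish with >= 10 loci genotyped
    "n_reference_fish": 233,  # dominant male + <=1 random female per group
}


def load_marker_panel() -> pd.DataFrame:
    """The 20-locus marker panel summary as a DataFrame.

    Columns: ``locus, multiplex, k, n_genotyped, h_obs, h_exp, hwe_p,
    primer_conc_pmol_ul``.
    """
    with resources.files("shellkin.data").joinpath("marker_panel.csv").open() as fh:
        return pd.read_csv(fh)


def study_census() -> dict:
    """Copy of :data:`STUDY_SHAPE`."""
    return dict(STUDY_SHAPE)
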