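"""End-to-end orchestration: frequencies -> r_LR -> composition -> models.

One call, :func:`run_full_analysis`, reproduces the whole analysis from a
genotype table plus territory coordinates (or from a precomputed pairwise
relatedness table plus neighbour counts), writing every stage's output and
a single JSON index. All floating-point text is written at fixed precision
so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genotypes import (allele_frequencies, marker_summary, read_genotype_table,
                        reference_subset)
from .models import DistanceDecayGAM, PairingMixedModel
from .pairs import (between_group_same_sex_pairs, group_composition_summary,
                    multi_member_groups, within_group_pairs)
from .permutation import run_density_tests
from .relatedness import (pairwise_matrix, read_relatedness_table,
                          write_relatedness_table)
from .spatial import DEFAULT_RADII, TerritoryMap, neighbourhood_density

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    genotypes: str | None = None
    coords: str | None = None
    relatedness: str | None = None       # precomputed pairwise table
    neighbour_counts: str | None = None  # precomputed counts (with coords absent)
    radii: tuple = DEFAULT_RADII
    min_loci: int = 10
    n_perm: int = 10_000
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.genotypes is None) == (self.relatedness is None):
            raise ValueError(
                "supply exactly one of genotypes or a precomputed relatedness table"
            )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["radii"] = list(self.radii)
        return d


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle.

    Outputs in ``out_dir``: ``marker_summary.csv`` (genotype mode only),
    ``pairwise.csv``, ``composition.json``, ``contrasts.json``,
    ``decay_curves.csv``, ``permutation.json``, ``null_slopes.csv`` and the
    ``index.json`` that lists them all with the run configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index: dict = {"shellkin_version": __version__, "config": config.to_dict(),
                   "outputs": {}, "stages": {}}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return wrap

    tmap = None
    if config.coords:
        tmap = _stage("coords")(lambda: TerritoryMap.from_csv(config.coords))

    if config.genotypes:
        table = _stage("genotypes")(
            lambda: read_genotype_table(config.genotypes, format="csv"))
        subset = reference_subset(table, config.seed)
        freqs = allele_frequencies(subset, table)
        summary = marker_summary(table, freqs, seed=config.seed)
        summary.to_csv(out / "marker_summary.csv")
        index["outputs"]["marker_summary"] = "marker_summary.csv"
        index["stages"]["frequencies"] = {
            "n_reference": freqs.n_reference,
            "n_augmented_alleles": freqs.n_augmented,
        }
        pairs = _stage("relatedness")(
            lambda: pairwise_matrix(table, freqs, territory_map=tmap,
                                    min_loci=config.min_loci))
        per_group, comp = group_composition_summary(table)
        _dump(comp, out / "composition.json")
        index["outputs"]["composition"] = "composition.json"
    else:
        pairs = _stage("relatedness-table")(
            lambda: read_relatedness_table(config.relatedness,
                                           column_map=config.column_map or None))

    write_relatedness_table(pairs, out / "pairwise.csv")
    index["outputs"]["pairwise"] = "pairwise.csv"

    win = within_group_pairs(pairs)
    index["stages"]["within_group"] = {
        "n_pairs": int(len(win)),
        "n_groups": int(win["group_1"].nunique()),
        "category_counts": win.attrs["category_counts"],
    }

    lmm = _stage("lmm")(lambda: PairingMixedModel(win).fit(seed=config.seed))
    _dump(lmm.to_dict(), out / "contrasts.json")
    index["outputs"]["contrasts"] = "contrasts.json"

    btw = _stage("between_group")(lambda: between_group_same_sex_pairs(pairs))
    index["stages"]["between_group"] = {
        "n_pairs": int(len(btw)),
        "category_counts": btw.attrs["category_counts"],
    }
    gam = _stage("gam")(lambda: DistanceDecayGAM(btw).fit())
    gam.curve_table().to_csv(out / "decay_curves.csv", index=False)
    index["outputs"]["decay_curves"] = "decay_curves.csv"
    index["stages"]["gam"] = gam.to_dict()

    # neighbourhood density
    if tmap is not None:
        counts = neighbourhood_density(tmap, config.radii)
    elif config.neighbour_counts:
        counts = pd.read_csv(config.neighbour_counts, dtype={"group_id": str})
    else:
        raise RuntimeError("stage 'density' failed: no coordinates or "
                           "neighbour-count table supplied")
    counts.to_csv(out / "neighbour_counts.csv", index=False)
    index["outputs"]["neighbour_counts"] = "neighbour_counts.csv"

    means = {c: multi_member_groups(pairs, c) for c in ("FF", "MM")}
    index["stages"]["multi_member_groups"] = {
        c: int(len(m)) for c, m in means.items()
    }
    perm = _stage("permutation")(
        lambda: run_density_tests(means, counts, radii=config.radii,
                                  n_perm=config.n_perm, seed=config.seed))
    _dump({"cells": [c.to_dict() for c in perm.cells]}, out / "permutation.json")
    perm.null_slope_table().to_csv(out / "null_slopes.csv", index=False)
    index["outputs"]["permutation"] = "permutation.json"
    index["outputs"]["null_slopes"] = "null_slopes.csv"

    _dump(index, out / "index.json")
    return index
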