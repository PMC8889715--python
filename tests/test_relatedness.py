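"""Lynch-Ritland estimator: hand-derived values, pedigree expectations,
symmetry and filter behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import shellkin as sk
from shellkin.genotypes import MISSING, FrequencyTable, GenotypeTable, Individual
from shellkin.relatedness import (compute_r_for_dyads, lr_locus, lr_pair,
                                  read_relatedness_table, within_group_matrix,
                                  write_relatedness_table)
from shellkin.simulate import (PEDIGREE_EXPECTATION, frequency_table_from_vectors,
                               simulate_dyads)


class TestLrLocus:
    def test_heterozygous_match_hand_value(self):
        # p_A=0.2, p_B=0.8, both fish A/B: r = 1, w = 0.36/0.32
        est = lr_locus((1, 2), (1, 2), {1: 0.2, 2: 0.8})
        assert est.r_locus == pytest.approx(1.0)
        assert est.weight == pytest.approx(1.125)

    def test_opposite_homozygotes_hand_value(self):
        # p_A=0.2: r = -0.16/0.64 = -0.25
        est = lr_locus((1, 1), (2, 2), {1: 0.2, 2: 0.8})
        assert est.r_locus == pytest.approx(-0.25)

    def test_degenerate_denominator_undefined(self):
        # p_A=p_B=0.5, reference A/B: denominator 0
        assert lr_locus((1, 2), (1, 1), {1: 0.5, 2: 0.5}) is None

    def test_monomorphic_locus_undefined(self):
        assert lr_locus((1, 1), (1, 1), {1: 1.0}) is None

    def test_missing_allele_raises_with_guidance(self):
        with pytest.raises(KeyError, match="augment"):
            lr_locus((1, 3), (1, 2), {1: 0.2, 2: 0.8}, locus="Lx")


def _two_fish_table(genos_x, genos_y, loci=None):
    loci = loci or [f"L{i+1}" for i in range(len(genos_x))]
    inds = [Individual("x", "G1", "female", "adult", "na"),
            Individual("y", "G2", "female", "adult", "na")]
    calls = np.array([genos_x, genos_y], dtype=np.int64)
    return GenotypeTable(inds, loci, calls), inds


class TestLrPair:
    def test_weighted_average_of_directions(self):
        # construct loci whose directional estimates are (1.0, w=1.125) and
        # (0.0, w=3.0) identically in both directions:
        # locus1: p=(0.2,0.8), both A/B -> r=1, w=1.125 (symmetric)
        # locus2: p=(0.2,0.8), x=A/A, y=A/B -> check by construction
        freqs = FrequencyTable(
            loci=["L1", "L2"],
            freqs={"L1": {1: 0.2, 2: 0.8}, "L2": {1: 0.2, 2: 0.8}},
            n_reference=100)
        e1 = lr_locus((1, 2), (1, 2), freqs.freqs["L1"])
        assert (e1.r_locus, e1.weight) == (pytest.approx(1.0), pytest.approx(1.125))
        # hand-check of the combined estimate for these two loci
        t, (x, y) = _two_fish_table([(1, 2), (1, 1)], [(1, 2), (2, 2)])
        pr = lr_pair(x, y, t, freqs, min_loci=2)
        e2a = lr_locus((1, 1), (2, 2), freqs.freqs["L2"])
        e2b = lr_locus((2, 2), (1, 1), freqs.freqs["L2"])
        exp_dir1 = (e1.weight * e1.r_locus + e2a.weight * e2a.r_locus) / (e1.weight + e2a.weight)
        exp_dir2 = (e1.weight * e1.r_locus + e2b.weight * e2b.r_locus) / (e1.weight + e2b.weight)
        assert pr.r_lr == pytest.approx((exp_dir1 + exp_dir2) / 2)
        assert pr.n_loci_used == 2

    def test_hand_weighted_average_formula(self):
        # directional estimates r=(1.0, 0.0), weights (1.125, 3.0), same in
        # reverse: combined = 1.125 / 4.125
        r = (1.125 * 1.0 + 3.0 * 0.0) / (1.125 + 3.0)
        assert r == pytest.approx(0.2727, abs=1e-4)

    def test_min_loci_filter_excludes(self):
        genos_x = [(1, 2)] * 9 + [(MISSING, MISSING)] * 11
        genos_y = [(1, 2)] * 20
        t, (x, y) = _two_fish_table(genos_x, genos_y)
        freqs = FrequencyTable(
            loci=t.loci, freqs={l: {1: 0.2, 2: 0.8} for l in t.loci}, n_reference=50)
        assert lr_pair(x, y, t, freqs) is None  # 9 < 10 genotyped loci
        assert lr_pair(x, y, t, freqs, min_loci=9) is not None

    def test_self_pair_rejected(self, small_population, small_freqs):
        _, table, _, _ = small_population
        ind = table.individuals[0]
        with pytest.raises(ValueError, match="self"):
            lr_pair(ind, ind, table, small_freqs)


class TestPedigreeExpectation:
    @pytest.mark.parametrize("relationship", list(PEDIGREE_EXPECTATION))
    def test_unbiased_for_pedigree_classes(self, study_fvecs, relationship):
        # 2,000 simulated dyads per class on 20 study-like loci
        table, i1, i2 = simulate_dyads(study_fvecs, relationship, 2000, seed=11)
        ft = frequency_table_from_vectors(study_fvecs)
        r, n = compute_r_for_dyads(table, ft, i1, i2)
        assert float(np.mean(r)) == pytest.approx(
            PEDIGREE_EXPECTATION[relationship], abs=0.02)

    def test_variance_shrinks_with_locus_count(self, study_fvecs):
        table, i1, i2 = simulate_dyads(study_fvecs, "half-sib", 1500, seed=13)
        ft20 = frequency_table_from_vectors(study_fvecs)
        r20, _ = compute_r_for_dyads(table, ft20, i1, i2)
        # same dyads restricted to the first 5 loci
        sub = GenotypeTable(table.individuals, table.loci[:5], table.calls[:, :5])
        ft5 = frequency_table_from_vectors(study_fvecs[:5])
        r5, _ = compute_r_for_dyads(sub, ft5, i1, i2)
        assert np.std(r20) < np.std(r5)


class TestPairwiseMatrix:
    def test_all_dyads_count(self, small_population, small_freqs, small_pairs):
        _, table, _, _ = small_population
        n_ret = int((table.n_genotyped_loci() >= 10).sum())
        assert len(small_pairs) == n_ret * (n_ret - 1) // 2

    def test_symmetry_under_input_order(self, small_population, small_freqs):
        _, table, _, _ = small_population
        retained = [i for i in table.individuals
                    if table.n_genotyped_loci()[table.row(i.id)] >= 10]
        a, b = retained[0], retained[5]
        p1 = lr_pair(a, b, table, small_freqs)
        p2 = lr_pair(b, a, table, small_freqs)
        assert p1.r_lr == pytest.approx(p2.r_lr, abs=1e-12)
        assert (p1.id_1, p1.id_2) == (p2.id_1, p2.id_2)

    def test_matrix_agrees_with_scalar_path(self, small_population, small_freqs,
                                            small_pairs):
        _, table, _, _ = small_population
        by_id = {i.id: i for i in table.individuals}
        rows = small_pairs.sample(25, random_state=0)
        for _, row in rows.iterrows():
            pr = lr_pair(by_id[row.id_1], by_id[row.id_2], table, small_freqs)
            assert pr.r_lr == pytest.approx(row.r_lr, abs=1e-9)
            assert pr.n_loci_used == row.n_loci

    def test_monomorphic_locus_leaves_estimates_unchanged(self, study_fvecs):
        table, i1, i2 = simulate_dyads(study_fvecs[:6], "full-sib", 300, seed=17)
        ft = frequency_table_from_vectors(study_fvecs[:6])
        r_before, _ = compute_r_for_dyads(table, ft, i1, i2)
        # append a monomorphic locus to every genotype
        calls = np.concatenate(
            [table.calls, np.full((len(table), 1, 2), 999, dtype=np.int64)], axis=1)
        t2 = GenotypeTable(table.individuals, table.loci + ["Lmono"], calls)
        ft2 = frequency_table_from_vectors(study_fvecs[:6] + [np.array([1.0])],
                                           loci=t2.loci)
        ft2.freqs["Lmono"] = {999: 1.0}
        r_after, _ = compute_r_for_dyads(t2, ft2, i1, i2)
        assert np.allclose(r_before, r_after)

    def test_within_group_matrix_matches_full(self, small_population, small_freqs,
                                              small_pairs):
        _, table, _, _ = small_population
        win = within_group_matrix(table, small_freqs)
        full_win = small_pairs[small_pairs.same_group]
        merged = win.merge(full_win, on=["id_1", "id_2"], suffixes=("_w", "_f"))
        assert len(merged) == len(win) == len(full_win)
        assert np.allclose(merged.r_lr_w, merged.r_lr_f)

    def test_novel_allele_augmentation(self):
        # allele seen in the pair but absent from the reference table
        freqs = FrequencyTable(loci=["L1"], freqs={"L1": {1: 0.5, 2: 0.5}},
                               n_reference=10)
        t, (x, y) = _two_fish_table([[1, 3]], [[2, 3]], loci=["L1"])
        pr = lr_pair(x, y, t, freqs, min_loci=1)
        assert pr is not None
        assert freqs.n_augmented == 1
        assert 3 in freqs.freqs["L1"]
        assert sum(freqs.freqs["L1"].values()) == pytest.approx(1.0)
        assert freqs.freqs["L1"][3] == pytest.approx(1 / 21)


class TestRelatednessTable:
    def test_round_trip(self, small_pairs, tmp_path):
        path = tmp_path / "pairs.csv"
        write_relatedness_table(small_pairs, path)
        back = read_relatedness_table(path)
        assert len(back) == len(small_pairs)
        assert np.allclose(back.r_lr, small_pairs.r_lr.round(6))

    def test_column_mapping_for_foreign_schema(self, small_pairs, tmp_path):
        foreign = small_pairs.rename(columns={"id_1": "fish_1", "id_2": "fish_2",
                                              "r_lr": "rlr"})
        path = tmp_path / "foreign.csv"
        foreign.to_csv(path, index=False)
        back = read_relatedness_table(
            path, column_map={"fish_1": "id_1", "fish_2": "id_2", "rlr": "r_lr"})
        assert len(back) == len(small_pairs)

    def test_conflicting_duplicates_hard_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        pd.DataFrame({"id_1": ["a", "a"], "id_2": ["b", "b"],
                      "r_lr": [0.1, 0.2]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_relatedness_table(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id_1,id_2,r_lr\n")
        out = read_relatedness_table(path)
        assert len(out) == 0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(pa=st.floats(0.05, 0.9), data=st.data())
def test_lr_locus_direction_weight_positive_when_defined(pa, data):
    """Whenever a locus estimate is defined, its weight is positive and the
    reversed-direction estimate is also defined (symmetric denominators)."""
    pb = 1.0 - pa
    g1 = (data.draw(st.sampled_from([1, 2])), data.draw(st.sampled_from([1, 2])))
    g2 = (data.draw(st.sampled_from([1, 2])), data.draw(st.sampled_from([1, 2])))
    fmap = {1: pa, 2: pb}
    e = lr_locus(g1, g2, fmap)
    if e is not None:
        assert e.weight > 0
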