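"""Mixed model with Tukey contrasts, Yeo-Johnson transform, decay GAM.

The LMM contrasts and the GAM curves are additionally cross-checked against
independent R implementations (lme4 + multcomp, mgcv) via Rscript.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shellkin.models import (DistanceDecayGAM, PairingMixedModel, yeo_johnson,
                             yeo_johnson_transform, _yeo_johnson_inverse)
from conftest import make_within_pairs


class TestYeoJohnson:
    def test_lambda_one_is_identity(self):
        x = np.array([-1.5, -0.2, 0.0, 0.4, 2.0])
        assert np.allclose(yeo_johnson_transform(x, 1.0), x)

    def test_mle_lambda_near_one_for_gaussian(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 4000)
        _, lam = yeo_johnson(x)
        assert lam == pytest.approx(1.0, abs=0.12)

    @pytest.mark.parametrize("lam", [-1.5, -0.5, 0.0, 0.5, 1.0, 2.0])
    def test_monotone_and_invertible(self, lam):
        x = np.linspace(-3, 3, 201)
        y = yeo_johnson_transform(x, lam)
        assert (np.diff(y) > 0).all()  # strictly monotone: ranks preserved
        assert np.allclose(_yeo_johnson_inverse(y, lam), x, atol=1e-8)


class TestPairingMixedModel:
    def test_constant_response_gives_zero_contrasts(self):
        rng = np.random.default_rng(1)
        df = make_within_pairs(rng, n_groups=30, group_sd=0.0, resid_sd=0.0,
                               means={"FF": 0.1, "MM": 0.1, "FM": 0.1, "JJ": 0.1})
        res = PairingMixedModel(df).fit(seed=0, n_mc=10_000)
        for c in res.contrasts:
            assert c.estimate == pytest.approx(0.0, abs=1e-10)

    def test_parameter_recovery_at_simulation_truth(self):
        # true MM - FF difference is 0.18; recovered within 2 SE
        rng = np.random.default_rng(7)
        df = make_within_pairs(rng, n_groups=100)
        res = PairingMixedModel(df).fit(seed=1)
        c = res.contrast("MM vs FF")
        assert abs(c.estimate - 0.18) < 2 * c.se
        assert res.group_variance > 0

    def test_contrast_antisymmetry_and_consistency(self):
        rng = np.random.default_rng(3)
        df = make_within_pairs(rng, n_groups=60)
        res = PairingMixedModel(df).fit(seed=2)
        mmff = res.contrast("MM vs FF")
        ffmm = res.contrast("FF vs MM")
        assert mmff.estimate == pytest.approx(-ffmm.estimate)
        assert mmff.p_adjusted == ffmm.p_adjusted
        # transitive consistency of the contrast estimates
        assert res.contrast("MM vs FF").estimate == pytest.approx(
            res.contrast("MM vs FM").estimate + res.contrast("FM vs FF").estimate,
            abs=1e-9)
        # adjusted p never below unadjusted
        for c in res.contrasts:
            assert c.p_adjusted >= c.p_unadjusted - 1e-12

    def test_zero_group_variance_degenerates_to_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(9)
        df = make_within_pairs(rng, n_groups=40, group_sd=0.0)
        res = PairingMixedModel(df).fit(seed=0)
        X = pd.get_dummies(pd.Categorical(df.category), drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        ols = sm.OLS(df.r_lr.to_numpy(), X.to_numpy()).fit()
        cats = sorted(df.category.unique())
        for i, cat in enumerate(cats[1:], start=1):
            est = res.contrast(f"{cat} vs {cats[0]}").estimate
            assert est == pytest.approx(ols.params[i], abs=1e-6)

    def test_sparse_category_contrast_undefined(self):
        rng = np.random.default_rng(5)
        df = make_within_pairs(rng, n_groups=30,
                               counts=(("FF", 3), ("MM", 3), ("FM", 3)))
        df = pd.concat([df, pd.DataFrame([dict(
            group_1="G000", group_2="G000", category="JJ", same_group=True,
            distance_cm=0.0, n_loci=20, r_lr=0.2)])], ignore_index=True)
        res = PairingMixedModel(df).fit(seed=0, n_mc=10_000)
        jj = res.contrast("JJ vs FF")
        assert np.isnan(jj.estimate) and np.isnan(jj.p_adjusted)

    def test_matches_r_lme4_multcomp(self, tmp_path):
        # dual-route check: REML fixed effects and single-step Tukey
        # adjustment against the reference R stack
        rng = np.random.default_rng(11)
        df = make_within_pairs(rng, n_groups=40,
                               counts=(("FF", 2), ("MM", 2), ("FM", 3), ("JJ", 3)))
        fixture = tmp_path / "lmm_fixture.csv"
        df.to_csv(fixture, index=False)
        res = PairingMixedModel(df).fit(seed=3)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages({{library(lme4); library(multcomp)}})
            d <- read.csv("{fixture}")
            d$category <- factor(d$category)
            m <- lmer(r_lr ~ category + (1|group_1), data=d, REML=TRUE)
            s <- summary(glht(m, linfct=mcp(category="Tukey")))
            out <- data.frame(contrast=names(s$test$coefficients),
                              estimate=as.numeric(s$test$coefficients),
                              z=as.numeric(s$test$tstat),
                              p=as.numeric(s$test$pvalues))
            write.csv(out, "{tmp_path / 'r_contrasts.csv'}", row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        r_out = pd.read_csv(tmp_path / "r_contrasts.csv")
        for _, row in r_out.iterrows():
            a, b = row.contrast.split(" - ")
            c = res.contrast(f"{a} vs {b}")
            assert c.estimate == pytest.approx(row.estimate, abs=1e-3)
            assert c.z == pytest.approx(row.z, abs=0.05)
            assert c.p_adjusted == pytest.approx(row.p, abs=0.02)


def _decay_pairs(rng, n_per_cat=2500, mm_decline=True):
    rows = []
    for cat in ("FF", "MM"):
        d = rng.uniform(10, 900, n_per_cat)
        if cat == "MM" and mm_decline:
            mu = np.clip(0.25 * (1 - d / 200.0), 0.0, None)
        else:
            mu = np.full(d.shape, 0.05)
        rows.append(pd.DataFrame(dict(
            id_1="a", id_2="b", group_1="x", group_2="y", category=cat,
            same_group=False, distance_cm=d, n_loci=20,
            r_lr=mu + rng.normal(0, 0.12, d.size))))
    return pd.concat(rows, ignore_index=True)


class TestDistanceDecayGAM:
    def test_constant_response_flat_smooth_edf_one(self):
        rng = np.random.default_rng(2)
        df = _decay_pairs(rng, mm_decline=False)
        df["r_lr"] = 0.07  # exactly constant
        res = DistanceDecayGAM(df).fit()
        for cat in ("FF", "MM"):
            f = res.fits[cat]
            assert f.edf <= 1.05
            assert np.ptp(f.fitted_raw) < 1e-6

    def test_recovers_simulated_decline_structure(self):
        rng = np.random.default_rng(4)
        df = _decay_pairs(rng)
        res = DistanceDecayGAM(df).fit()
        mm, ff = res.fits["MM"], res.fits["FF"]
        grid = mm.grid_cm
        sel = grid <= 200
        mm_curve = mm.fitted_raw[sel]
        # MM monotone decreasing over 0-200 cm (up to small numerical slack)
        assert (np.diff(mm_curve) < 1e-3).all()
        mm_drop = mm_curve[0] - mm_curve[-1]
        ff_interp = np.interp(grid[sel], ff.grid_cm, ff.fitted_raw)
        ff_drop = abs(ff_interp[0] - ff_interp[-1])
        assert mm_drop > 0.1
        assert ff_drop < mm_drop / 3
        assert res.fits["MM"].p_value < 1e-4

    def test_requires_both_categories(self):
        rng = np.random.default_rng(6)
        df = _decay_pairs(rng)
        with pytest.raises(ValueError):
            DistanceDecayGAM(df[df.category == "MM"])

    def test_degenerate_distance_range_rejected(self):
        rng = np.random.default_rng(8)
        df = _decay_pairs(rng)
        df["distance_cm"] = 100.0
        with pytest.raises(ValueError, match="degenerate"):
            DistanceDecayGAM(df)

    def test_matches_r_mgcv_curves(self, tmp_path):
        rng = np.random.default_rng(5)
        df = _decay_pairs(rng, n_per_cat=2000)
        res = DistanceDecayGAM(df).fit()
        curves = res.curve_table()
        fixture = tmp_path / "gam_fixture.csv"
        grid_file = tmp_path / "grid.csv"
        df.to_csv(fixture, index=False)
        curves.to_csv(grid_file, index=False)
        out = tmp_path / "diff.csv"
        rscript = tmp_path / "oracle.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(mgcv))
            d <- read.csv("{fixture}")
            g <- read.csv("{grid_file}")
            # same transform family: mgcv fit on the raw scale is compared
            # against the back-transformed curves, so tolerances are loose
            res <- data.frame(cat=character(), maxdiff=double(), edf=double())
            for (cat in c("FF","MM")) {{
              s <- d[d$category==cat,]
              m <- gam(r_lr ~ s(distance_cm, bs="cr", k=5), data=s, method="GCV.Cp")
              pr <- predict(m, newdata=data.frame(distance_cm=g$distance_cm))
              cmp <- if (cat=="FF") g$fitted_FF else g$fitted_MM
              res <- rbind(res, data.frame(cat=cat, maxdiff=max(abs(pr-cmp)),
                                           edf=sum(summary(m)$edf)))
            }}
            write.csv(res, "{out}", row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        r_out = pd.read_csv(out).set_index("cat")
        for cat in ("FF", "MM"):
            assert r_out.loc[cat, "maxdiff"] < 0.02
            assert abs(r_out.loc[cat, "edf"] - res.fits[cat].edf) < 1.2
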