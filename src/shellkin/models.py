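"""Fitted-model stages: within-group mixed model and distance-decay GAM.

Two model classes in the statsmodels mould — construct from a pairs table,
``fit()`` returns a results object with estimates, uncertainties and a
``summary()`` table.

:class:`PairingMixedModel`
    Gaussian linear mixed model of within-group pairwise relatedness on the
    dyad category (FF / MM / FM / JJ) with a random intercept per social
    group (each within-group dyad belongs to exactly one group; individual
    identities are deliberately not modelled as random effects because a
    dyadic design cannot separate intra- from inter-individual variance
    with these data). All six pairwise category contrasts are reported with
    single-step (Tukey-style max-|z|) multiplicity adjustment computed from
    the joint normal distribution of the contrast z statistics by seeded
    Monte Carlo.

:class:`DistanceDecayGAM`
    Penalized cubic regression spline (five knots, quantile-placed) of
    Yeo-Johnson-transformed relatedness on inter-territory distance, fitted
    per category (FF, MM) with the smoothing parameter chosen by
    generalized cross-validation. Reports effective degrees of freedom, an
    approximate F test of the smooth, fitted curves on a distance grid and
    a sex-difference comparison of the two curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from ._util import rng_for

__all__ = [
    "yeo_johnson",
    "yeo_johnson_transform",
    "ContrastResult",
    "PairingMixedModel",
    "PairingMixedModelResults",
    "DecayFit",
    "DistanceDecayGAM",
    "DistanceDecayResults",
]


# -- Yeo-Johnson ---------------------------------------------------------

def yeo_johnson_transform(values: np.ndarray, lmbda: float) -> np.ndarray:
    """Yeo-Johnson mapping at a given lambda (identity when lambda = 1)."""
    return stats.yeojohnson(np.asarray(values, dtype=float), lmbda=lmbda)


def yeo_johnson(values, bounds: tuple = (-2.0, 2.0)) -> tuple[np.ndarray, float]:
    """Transform ``values`` with the Gaussian-MLE lambda.

    The transform is defined for negative inputs (the reason it is used on
    relatedness estimates, which routinely dip below zero) and is strictly
    monotone for every lambda, so rank order is preserved. The lambda
    search is bounded to [-2, 2]: outside that range the mapping is so
    aggressive that back-transformed fits become numerically unstable,
    while the fit improvement is negligible.
    """
    from scipy.optimize import minimize_scalar

    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.ptp(arr) < 1e-12:
        return arr.copy(), 1.0  # constant input: identity
    res = minimize_scalar(lambda lm: -stats.yeojohnson_llf(lm, arr),
                          bounds=bounds, method="bounded")
    lmbda = float(res.x)
    return stats.yeojohnson(arr, lmbda=lmbda), lmbda


# -- within-group mixed model --------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """One pairwise category contrast from the mixed model."""

    label: str
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


class PairingMixedModel:
    """LMM of within-group r_LR on dyad category with a group intercept.

    Parameters
    ----------
    pairs
        Within-group pairs table with ``r_lr``, ``category`` and
        ``group_1`` columns (see :func:`shellkin.pairs.within_group_pairs`).
    random_intercept
        When False the group intercept is dropped and the model is plain
        OLS (useful for the degeneracy check: a zero-variance random
        effect must reproduce OLS estimates).
    """

    def __init__(self, pairs: pd.DataFrame, random_intercept: bool = True):
        df = pairs.dropna(subset=["r_lr"]).copy()
        self.categories = sorted(df["category"].unique())
        if len(self.categories) < 2:
            raise ValueError("need >= 2 dyad categories to fit contrasts")
        if random_intercept and df["group_1"].nunique() < 2:
            raise ValueError("need >= 2 groups for a group random intercept")
        self.data = df
        self.random_intercept = random_intercept

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, **kw) -> "PairingMixedModel":
        return cls(pairs, **kw)

    def _design(self):
        cat = pd.Categorical(self.data["category"], categories=self.categories)
        X = pd.get_dummies(cat, drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        return X.to_numpy(), list(X.columns)

    def fit(self, seed: int = 0, n_mc: int = 100_000,
            zero_variance_tol: float = 1e-8) -> "PairingMixedModelResults":
        """Fit by REML; contrasts adjusted by max-|z| Monte Carlo.

        When the estimated group-intercept variance collapses to the
        boundary (< ``zero_variance_tol``) the fixed effects are re-solved
        by OLS, which is the exact limit of the mixed model at zero
        variance.
        """
        y = self.data["r_lr"].to_numpy(dtype=float)
        X, names = self._design()
        group_var = np.nan
        used_ols = not self.random_intercept
        if self.random_intercept:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mlm = sm.MixedLM(y, X, groups=self.data["group_1"].to_numpy())
                res = mlm.fit(reml=True)
            # cov_re is already on the response scale
            group_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
            if group_var < zero_variance_tol:
                used_ols = True
        if used_ols:
            res = sm.OLS(y, X).fit()
            group_var = 0.0 if self.random_intercept else np.nan
        beta = np.asarray(res.params, dtype=float)[: len(names)]
        cov = np.asarray(res.cov_params())[: len(names), : len(names)]

        # category means: mu_k = const + beta_k (first category is baseline)
        k = len(self.categories)
        A = np.zeros((k, len(names)))
        A[:, 0] = 1.0
        for i in range(1, k):
            A[i, i] = 1.0
        mu = A @ beta
        cov_mu = A @ cov @ A.T

        counts = self.data["category"].value_counts()
        contrasts = self._contrasts(mu, cov_mu, counts, seed, n_mc)
        return PairingMixedModelResults(
            categories=self.categories,
            category_means={c: float(m) for c, m in zip(self.categories, mu)},
            group_variance=group_var,
            residual_variance=float(res.scale) if hasattr(res, "scale")
            else float(res.mse_resid),
            contrasts=contrasts,
            n_obs=len(y),
            n_groups=int(self.data["group_1"].nunique()),
            used_ols=used_ols,
        )

    def _contrasts(self, mu, cov_mu, counts, seed, n_mc):
        k = len(self.categories)
        pairs = [(i, j) for i in range(k) for j in range(i)]  # "later vs earlier"
        L = np.zeros((len(pairs), k))
        labels = []
        for r, (i, j) in enumerate(pairs):
            L[r, i], L[r, j] = 1.0, -1.0
            labels.append(f"{self.categories[i]} vs {self.categories[j]}")
        est = L @ mu
        cov_c = L @ cov_mu @ L.T
        se = np.sqrt(np.diag(cov_c))
        z = est / se
        p_un = 2.0 * stats.norm.sf(np.abs(z))
        # single-step adjustment: P(max_j |Z_j| >= |z_i|) under the joint
        # normal of the contrast statistics
        corr = cov_c / np.outer(se, se)
        corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(se))
        rng = rng_for(seed, "tukey-mc")
        draws = rng.multivariate_normal(np.zeros(len(se)), corr, size=n_mc,
                                        method="cholesky")
        maxabs = np.abs(draws).max(axis=1)
        out = []
        for r, (i, j) in enumerate(pairs):
            defined = counts.get(self.categories[i], 0) >= 2 and \
                counts.get(self.categories[j], 0) >= 2
            p_adj = float((maxabs >= abs(z[r])).mean()) if defined else np.nan
            out.append(ContrastResult(
                label=labels[r],
                estimate=float(est[r]) if defined else np.nan,
                se=float(se[r]),
                z=float(z[r]) if defined else np.nan,
                p_unadjusted=float(p_un[r]),
                p_adjusted=max(p_adj, float(p_un[r])) if defined else np.nan,
            ))
        return out


@dataclass
class PairingMixedModelResults:
    categories: list[str]
    category_means: dict[str, float]
    group_variance: float
    residual_variance: float
    contrasts: list[ContrastResult]
    n_obs: int
    n_groups: int
    used_ols: bool

    def contrast(self, label: str) -> ContrastResult:
        for c in self.contrasts:
            if c.label == label:
                return c
        # accept reversed labels with flipped sign
        a, _, b = label.partition(" vs ")
        for c in self.contrasts:
            if c.label == f"{b} vs {a}":
                return ContrastResult(label, -c.estimate, c.se, -c.z,
                                      c.p_unadjusted, c.p_adjusted)
        raise KeyError(label)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(contrast=c.label, estimate=c.estimate, se=c.se, z=c.z,
                 p_unadjusted=c.p_unadjusted, p_adjusted=c.p_adjusted)
            for c in self.contrasts
        ])

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "group_variance": round(self.group_variance, 8),
            "residual_variance": round(self.residual_variance, 8),
            "category_means": {k: round(v, 6) for k, v in self.category_means.items()},
            "contrasts": [
                dict(contrast=c.label, estimate=_r6(c.estimate), se=_r6(c.se),
                     z=_r6(c.z), p_unadjusted=_r6(c.p_unadjusted),
                     p_adjusted=_r6(c.p_adjusted))
                for c in self.contrasts
            ],
        }


def _r6(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), 6)


# -- between-group distance-decay GAM ------------------------------------

@dataclass
class DecayFit:
    """Per-category spline fit of transformed r_LR on distance."""

    category: str
    edf: float
    f_stat: float
    p_value: float
    alpha: float
    grid_cm: np.ndarray
    fitted: np.ndarray  # on the transformed scale
    fitted_raw: np.ndarray  # back-transformed to the r_LR scale
    n_obs: int


class DistanceDecayGAM:
    """Distance decay of between-group same-sex relatedness.

    Parameters
    ----------
    pairs
        Between-group same-sex adult pairs with ``r_lr``, ``distance_cm``
        and ``category`` in {FF, MM}.
    n_knots
        Basis size of the cubic regression spline (default five knots,
        placed at distance quantiles by the B-spline basis).
    """

    _ALPHAS = np.logspace(0, 12, 13)

    def __init__(self, pairs: pd.DataFrame, n_knots: int = 5, min_pairs: int = 50):
        df = pairs.dropna(subset=["r_lr", "distance_cm"]).copy()
        for cat in ("FF", "MM"):
            if (df["category"] == cat).sum() < min_pairs:
                raise ValueError(f"need >= {min_pairs} {cat} pairs")
        if df["distance_cm"].nunique() < 2:
            raise ValueError("degenerate distance range")
        self.data = df
        self.n_knots = n_knots

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, **kw) -> "DistanceDecayGAM":
        return cls(pairs, **kw)

    def _fit_one(self, x, y, alpha=None):
        bs = BSplines(x[:, None], df=[self.n_knots], degree=[3])
        ex = np.ones((len(y), 1))
        if alpha is None:
            # GCV grid; ties broken toward the heavier penalty so a
            # constant response collapses to the smoothest admissible fit
            best = None
            for a in self._ALPHAS:
                res = GLMGam(y, exog=ex, smoother=bs, alpha=[a]).fit()
                n = len(y)
                edf = float(res.edf.sum())
                rss = float(np.sum(res.resid_response ** 2))
                g = rss * n / (n - edf) ** 2
                if best is None or g < best[0] * (1 - 1e-9):
                    best = (g, a, res)
                elif g <= best[0] * (1 + 1e-9):
                    best = (g, a, res)  # tie: prefer larger alpha
            _, alpha, res = best
        else:
            res = GLMGam(y, exog=ex, smoother=bs, alpha=[alpha]).fit()
        return res, float(alpha), bs

    def fit(self, grid_points: int = 101) -> "DistanceDecayResults":
        y_all = self.data["r_lr"].to_numpy(dtype=float)
        y_t, lmbda = yeo_johnson(y_all)
        fits = {}
        parts = {}
        for cat in ("FF", "MM"):
            mask = (self.data["category"] == cat).to_numpy()
            x = self.data["distance_cm"].to_numpy(dtype=float)[mask]
            y = y_t[mask]
            if np.ptp(y) < 1e-12:
                # constant response: the penalization limit — a flat curve
                # with one effective degree of freedom
                grid = np.linspace(x.min(), x.max(), grid_points)
                const = np.full(grid_points, y.mean())
                fits[cat] = DecayFit(category=cat, edf=1.0, f_stat=0.0,
                                     p_value=1.0, alpha=float(self._ALPHAS[-1]),
                                     grid_cm=grid, fitted=const,
                                     fitted_raw=_yeo_johnson_inverse(const, lmbda),
                                     n_obs=int(mask.sum()))
                parts[cat] = (0.0, 1.0, int(mask.sum()))
                continue
            res, alpha, bs = self._fit_one(x, y)
            n = len(y)
            edf_smooth = float(res.edf[1:].sum())
            edf_total = float(res.edf.sum())
            rss = float(np.sum(res.resid_response ** 2))
            rss0 = float(np.sum((y - y.mean()) ** 2))
            if edf_smooth > 1e-8 and n - edf_total > 0 and rss > 0:
                f = ((rss0 - rss) / edf_smooth) / (rss / (n - edf_total))
                p = float(stats.f.sf(f, edf_smooth, n - edf_total))
            else:
                f, p = 0.0, 1.0
            lo, hi = x.min(), x.max()
            grid = np.linspace(lo, hi, grid_points)
            grid_in = np.clip(grid, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
            fitted = res.predict(np.ones((grid_points, 1)), exog_smooth=grid_in[:, None])
            fits[cat] = DecayFit(
                category=cat, edf=edf_smooth, f_stat=float(f), p_value=p,
                alpha=alpha, grid_cm=grid,
                fitted=np.asarray(fitted),
                fitted_raw=_yeo_johnson_inverse(np.asarray(fitted), lmbda),
                n_obs=n,
            )
            parts[cat] = (rss, edf_total, n)
        sex_diff = self._sex_difference(y_t, parts)
        return DistanceDecayResults(lmbda=lmbda, fits=fits, sex_difference=sex_diff)

    def _sex_difference(self, y_t, parts):
        """Approximate F test: category-specific smooths vs a shared smooth
        (both with a category intercept)."""
        if np.ptp(y_t) < 1e-12:
            return {"f_stat": 0.0, "p_value": 1.0, "edf_shared": 2.0,
                    "edf_separate": 2.0}
        x = self.data["distance_cm"].to_numpy(dtype=float)
        is_mm = (self.data["category"] == "MM").to_numpy(dtype=float)
        bs = BSplines(x[:, None], df=[self.n_knots], degree=[3])
        ex = np.column_stack([np.ones(len(y_t)), is_mm])
        res_shared = GLMGam(y_t, exog=ex, smoother=bs, alpha=[1.0]).fit()
        rss_shared = float(np.sum(res_shared.resid_response ** 2))
        edf_shared = float(res_shared.edf.sum())
        rss_sep = sum(parts[c][0] for c in parts)
        edf_sep = sum(parts[c][1] for c in parts)
        n = len(y_t)
        d_edf = max(edf_sep - edf_shared, 1e-6)
        denom_df = max(n - edf_sep, 1.0)
        f = max(rss_shared - rss_sep, 0.0) / d_edf / (rss_sep / denom_df)
        p = float(stats.f.sf(f, d_edf, denom_df))
        return {"f_stat": float(f), "p_value": p,
                "edf_shared": edf_shared, "edf_separate": float(edf_sep)}


def _yeo_johnson_inverse(y, lmbda):
    """Inverse Yeo-Johnson mapping."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lmbda) > 1e-12:
        out[pos] = np.power(np.clip(y[pos] * lmbda + 1, 1e-300, None), 1.0 / lmbda) - 1
    else:
        out[pos] = np.expm1(y[pos])
    lam2 = 2.0 - lmbda
    if abs(lam2) > 1e-12:
        out[~pos] = 1 - np.power(np.clip(1 - y[~pos] * lam2, 1e-300, None), 1.0 / lam2)
    else:
        out[~pos] = -np.expm1(-y[~pos])
    return out


@dataclass
class DistanceDecayResults:
    lmbda: float
    fits: dict[str, DecayFit]
    sex_difference: dict

    def curve_table(self) -> pd.DataFrame:
        """Fitted decay curves on a common distance grid (r_LR scale)."""
        grid = self.fits["FF"].grid_cm
        ff = self.fits["FF"].fitted_raw
        mm_fit = self.fits["MM"]
        mm = np.interp(grid, mm_fit.grid_cm, mm_fit.fitted_raw)
        return pd.DataFrame({
            "distance_cm": np.round(grid, 3),
            "fitted_FF": np.round(ff, 6),
            "fitted_MM": np.round(mm, 6),
        })

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(category=c, n=f.n_obs, edf=round(f.edf, 3),
                 F=round(f.f_stat, 3), p=f.p_value, alpha=f.alpha)
            for c, f in self.fits.items()
        ])

    def to_dict(self) -> dict:
        return {
            "yeo_johnson_lambda": round(self.lmbda, 6),
            "fits": {
                c: dict(n=f.n_obs, edf=round(f.edf, 4), F=round(f.f_stat, 4),
                        p=round(f.p_value, 8), alpha=f.alpha)
                for c, f in self.fits.items()
            },
            "sex_difference": {k: round(v, 6) for k, v in self.sex_difference.items()},
        }
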