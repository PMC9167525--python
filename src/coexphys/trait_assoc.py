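"""Module eigengene-trait association with jack-knife robustness screening.

Traits are first regressed on a mass covariate (body mass by default; heart
mass for the cardiac metabolic rates) and the residuals correlated with
module eigengenes by signed Pearson correlation, within each acclimation
temperature stratum. BH-FDR is applied across modules within each trait.
Significant correlations are screened for outlier robustness: 100 jack-knife
subsamples of 90% of the individuals each, a correlation "passing" when it
is raw-significant with the full-sample sign in at least 70 of the 100
replicates. Traits explained by more than one passing module get a multiple
correlation coefficient (correlation of OLS fitted values with the trait).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .diffexp import bh_adjust

#: default mass covariate per trait: whole-animal traits are corrected for
#: body mass, cardiac metabolic rates for heart mass
DEFAULT_MASS_COVARIATES = {
    "WAM": "body_mass",
    "CT_max": "body_mass",
    "CaM_GLU": "heart_mass",
    "CaM_FA": "heart_mass",
    "CaM_LKA": "heart_mass",
    "CaM_END": "heart_mass",
}


def mass_residuals(trait: pd.Series, mass: pd.Series) -> pd.Series:
    """Residuals of an OLS fit of trait on a mass covariate.

    Missing values in either variable propagate as NaN residuals.
    """
    ok = trait.notna() & mass.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing (trait, mass) pairs")
    t = trait[ok].to_numpy(dtype=float)
    m = mass[ok].to_numpy(dtype=float)
    if np.allclose(m, m[0]):
        raise ValueError("mass covariate has zero variance")
    slope, intercept = np.polyfit(m, t, 1)
    out = pd.Series(np.nan, index=trait.index, name=trait.name)
    out[ok] = t - (intercept + slope * m)
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Signed Pearson correlation with the two-sided t-test p-value."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_me_traits(mes: pd.DataFrame, traits: pd.DataFrame,
                        min_pairs: int = 4) -> pd.DataFrame:
    """Signed Pearson correlation of every (module, trait) pair.

    Pairwise-complete observations; BH correction across modules within each
    trait (the multiple-testing family of the analysis).
    """
    rows = []
    for trait in traits.columns:
        t = traits[trait]
        for module in mes.columns:
            me = mes[module]
            ok = t.notna() & me.notna()
            if ok.sum() < min_pairs:
                raise ValueError(
                    f"fewer than {min_pairs} complete pairs for "
                    f"({module}, {trait})")
            r, p = pearson_with_p(me[ok].to_numpy(), t[ok].to_numpy())
            rows.append((module, trait, int(ok.sum()), r, p))
    out = pd.DataFrame(rows, columns=["module", "trait", "n", "r", "p"])
    out["q"] = np.nan
    for trait in traits.columns:
        sel = out["trait"] == trait
        out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out


def jackknife_support(me: pd.Series, trait: pd.Series, frac: float = 0.9,
                      reps: int = 100, alpha: float = 0.05,
                      min_support: int = 70,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[int, bool]:
    """Outlier-robustness screen for one module-trait correlation.

    Each replicate draws floor(frac * n) samples without replacement and
    recomputes the signed Pearson correlation; a replicate supports the
    association when its raw p < alpha and its sign matches the full-sample
    correlation. Returns (support count, support >= min_support).
    """
    ok = me.notna() & trait.notna()
    x = me[ok].to_numpy(dtype=float)
    y = trait[ok].to_numpy(dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(
            "jack-knife screen needs n >= 10 so the 90% subsample drops "
            "at least one sample")
    m = int(np.floor(frac * n))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    r_full, _ = pearson_with_p(x, y)
    sign_full = np.sign(r_full)
    support = 0
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        r, p = pearson_with_p(x[idx], y[idx])
        if p < alpha and np.sign(r) == sign_full:
            support += 1
    return support, support >= min_support


def multiple_correlation(trait: pd.Series, mes: pd.DataFrame) -> float:
    """Correlation of OLS fitted values (trait ~ ME1 + ... + MEk) with the trait.

    Equals the square root of the regression R^2, and is therefore at least
    the largest single |r| among the regressors.
    """
    ok = trait.notna()
    for c in mes.columns:
        ok &= mes[c].notna()
    y = trait[ok].to_numpy(dtype=float)
    X = mes.loc[ok].to_numpy(dtype=float)
    if X.shape[1] >= len(y) - 2:
        raise ValueError("too many eigengenes for the sample size")
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    fitted = X1 @ beta
    if np.allclose(fitted, fitted[0]):
        return 0.0
    return float(np.corrcoef(fitted, y)[0, 1])


def gene_significance(expr: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """GS: Pearson correlation of each gene's expression with a trait."""
    ok = trait.notna()
    t = trait[ok].to_numpy(dtype=float)
    x = expr.loc[:, ok.index[ok]].to_numpy(dtype=float)
    tz = (t - t.mean()) / t.std(ddof=1)
    xm = x - x.mean(axis=1, keepdims=True)
    xs = x.std(axis=1, ddof=1)
    xs[xs == 0] = np.nan
    gs = (xm @ tz) / ((len(t) - 1) * xs)
    return pd.Series(gs, index=expr.index, name="GS")


def hub_gs(gs: pd.Series, members: pd.Index) -> tuple[str, float, float]:
    """Hub-GS gene of a module for one trait.

    Returns (gene with max |GS| among members, its signed GS, fraction of
    members with GS > 0). Ties broken by smallest gene id.
    """
    sub = gs.loc[members].dropna()
    if sub.empty:
        raise ValueError("module has no genes with defined GS")
    best = sub.abs().max()
    gene = sorted(sub.index[sub.abs() == best])[0]
    return gene, float(sub[gene]), float((sub > 0).mean())


def association_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Table of passing associations with a final AVERAGE row.

    One row per significant (trait, module), sorted by trait then module;
    the AVERAGE row holds the mean of |r| rounded to 2 decimals.
    """
    rows = results.sort_values(["trait", "module"]).reset_index(drop=True)
    if rows.empty:
        return rows
    avg = round(float(rows["r"].abs().mean()), 2)
    avg_row = {c: "" for c in rows.columns}
    avg_row["trait"] = "AVERAGE"
    avg_row["r"] = avg
    return pd.concat([rows, pd.DataFrame([avg_row])], ignore_index=True)


def range_spread(values) -> float:
    """Fold-difference statistic (max - min) / min; requires min > 0."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values")
    if v.min() <= 0:
        raise ValueError("range spread requires a strictly positive minimum")
    return float((v.max() - v.min()) / v.min())


class ModuleTraitAssociation(BaseEstimator):
    """Eigengene-trait association with FDR + jack-knife screening.

    Parameters
    ----------
    frac, reps, alpha, min_support : jack-knife screen parameters
        (defaults 0.9 / 100 / 0.05 / 70).
    fdr : float, BH-FDR threshold within each trait (default 0.05).
    mass_covariates : mapping trait -> sample-table column used for the
        residual correction; None disables correction. "body_mass" for all
        traits reproduces a blanket body-mass correction.
    seed : int, jack-knife reproducibility.

    Attributes
    ----------
    results_ : one row per (module, trait): r, p, q, jack-knife support,
        pass flag.
    multiple_correlations_ : dict trait -> multiple correlation R over its
        passing modules (traits with >= 2 passing modules).
    residual_traits_ : the mass-corrected trait table used throughout.
    """

    def __init__(self, frac: float = 0.9, reps: int = 100,
                 alpha: float = 0.05, min_support: int = 70,
                 fdr: float = 0.05, mass_covariates: dict | None = None,
                 seed: int = 0):
        self.frac = frac
        self.reps = reps
        self.alpha = alpha
        self.min_support = min_support
        self.fdr = fdr
        self.mass_covariates = mass_covariates
        self.seed = seed

    def fit(self, mes: pd.DataFrame, traits: pd.DataFrame,
            samples: pd.DataFrame | None = None):
        """mes: samples x modules; traits: samples x traits."""
        covmap = (DEFAULT_MASS_COVARIATES if self.mass_covariates is None
                  else self.mass_covariates)
        resid = {}
        for trait in traits.columns:
            cov = covmap.get(trait) if samples is not None else None
            if cov is not None and cov in getattr(samples, "columns", []):
                resid[trait] = mass_residuals(traits[trait], samples[cov])
            else:
                resid[trait] = traits[trait]
        resid = pd.DataFrame(resid, index=traits.index)
        self.residual_traits_ = resid

        res = correlate_me_traits(mes, resid)
        supports, passes = [], []
        rng = np.random.default_rng(self.seed)
        for _, row in res.iterrows():
            if row["q"] < self.fdr:
                support, ok = jackknife_support(
                    mes[row["module"]], resid[row["trait"]], self.frac,
                    self.reps, self.alpha, self.min_support, rng)
            else:
                support, ok = 0, False
            supports.append(support)
            passes.append(ok and row["q"] < self.fdr)
        res["support"] = supports
        res["pass"] = passes
        self.results_ = res

        self.multiple_correlations_ = {}
        for trait in resid.columns:
            mods = res.loc[(res["trait"] == trait) & res["pass"], "module"]
            if len(mods) >= 2:
                self.multiple_correlations_[trait] = multiple_correlation(
                    resid[trait], mes[list(mods)])
        return self
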