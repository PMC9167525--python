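"""Negative-binomial GLM differential expression.

A deliberately transparent NB-GLM engine for the two designs of the emulated
study: a population x acclimation-temperature interaction model (per-population
12-vs-28 contrasts) and a population-only model within one temperature
(three pairwise population contrasts). Dispersions come from a Poisson-fit
method-of-moments estimator; there is no shrinkage across genes, no outlier
filtering and no independent filtering, so gene-level calls are not expected
to match count-for-count what a shrinkage-based tool reports on real data.

Per-gene model: counts ~ NB(mu, phi) with variance mu + phi * mu**2 and
log mu = offset(log s_j) + X beta. Wald tests on contrasts c'beta, with
Benjamini-Hochberg correction jointly across all contrasts of one model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .simulate import POPULATIONS

PHI_MIN = 1e-8
LN2 = float(np.log(2.0))

PAIRWISE_CONTRASTS = ("TE_vs_NRef", "TE_vs_SRef", "NRef_vs_SRef")


def estimate_dispersion(y: np.ndarray, design: np.ndarray,
                        size_factors: np.ndarray) -> float:
    """Method-of-moments NB dispersion after a Poisson GLM fit.

    phi_hat = max(PHI_MIN, sum(((y - mu)^2 - mu) / mu^2) / (n - rank)).
    """
    y = np.asarray(y, dtype=float)
    if not y.any():
        raise ValueError("all-zero gene: dispersion undefined")
    rank = np.linalg.matrix_rank(design)
    if len(y) < rank + 1:
        raise ValueError("need more samples than model coefficients")
    offset = np.log(np.asarray(size_factors, dtype=float))
    fit = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset).fit()
    mu = fit.fittedvalues
    num = (((y - mu) ** 2 - mu) / mu ** 2).sum()
    return float(max(PHI_MIN, num / (len(y) - rank)))


def fit_nb_glm(y: np.ndarray, design: np.ndarray, size_factors: np.ndarray,
               phi: float, tol: float = 1e-8, maxiter: int = 100):
    """Fit one NB GLM with log link and library-size offset.

    Returns a statsmodels GLMResults. Raises ``RuntimeError`` if IRLS does
    not converge or the fit is degenerate (non-finite coefficients or
    covariance); callers flag such genes and exclude them from testing.
    """
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    offset = np.log(np.asarray(size_factors, dtype=float))
    family = sm.families.NegativeBinomial(alpha=max(phi, PHI_MIN))
    model = sm.GLM(np.asarray(y, dtype=float), design, family=family,
                   offset=offset)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except Exception as exc:  # all-zero groups, singular weights, ...
            raise RuntimeError(f"NB GLM fit failed: {exc}") from exc
    if any("PerfectSeparation" in type(w.message).__name__ for w in caught):
        raise RuntimeError(
            "NB GLM fit degenerate (a design cell has no counts); "
            "gene flagged and excluded from testing")
    if not (np.isfinite(res.params).all()
            and np.isfinite(res.cov_params()).all()
            and getattr(res, "converged", True)):
        raise RuntimeError("NB GLM fit did not converge")
    return res


def wald_contrast(fit, contrast: np.ndarray,
                  df: int | None = None) -> tuple[float, float]:
    """Two-sided Wald test of c'beta = 0; returns (statistic, p).

    With ``df=None`` the reference distribution is standard normal. The
    gene-level pipeline passes the residual degrees of freedom instead,
    using a t reference — the usual small-sample correction when the
    dispersion entering the covariance is itself estimated per gene
    (a plain normal reference is measurably anticonservative at n ~ 40).
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit.params.shape:
        raise ValueError("contrast length must equal number of coefficients")
    if not c.any():
        raise ValueError("contrast vector is all zeros")
    est = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov_params() @ c))
    z = est / se
    if df is None:
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 2.0 * stats.t.sf(abs(z), df)
    return z, float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design_matrices(samples: pd.DataFrame, model: str
                     ) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design with N.Ref / 12C as reference levels."""
    pop = samples["population"].to_numpy()
    te = (pop == "TE").astype(float)
    sref = (pop == "S.Ref").astype(float)
    if model == "population_only":
        X = np.column_stack([np.ones(len(pop)), te, sref])
        names = ["intercept", "TE", "S.Ref"]
    elif model == "population_by_temperature_interaction":
        acc = (samples["acclimation"].to_numpy() == 28).astype(float)
        X = np.column_stack([np.ones(len(pop)), te, sref, acc,
                             te * acc, sref * acc])
        names = ["intercept", "TE", "S.Ref", "acc28", "TE:acc28",
                 "S.Ref:acc28"]
    else:
        raise ValueError(f"unknown model {model!r}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; every population x "
            "temperature cell in the model needs samples")
    return X, names


def _fit_gene_table(counts: pd.DataFrame, X: np.ndarray, s: np.ndarray,
                    contrasts: dict[str, np.ndarray],
                    lrt_reduced: np.ndarray | None = None) -> pd.DataFrame:
    """Fit every gene, apply all contrasts, BH jointly across the model."""
    rows = []
    for gene, y in counts.iterrows():
        y = y.to_numpy(dtype=float)
        try:
            phi = estimate_dispersion(y, X, s)
            fit = fit_nb_glm(y, X, s, phi)
        except (ValueError, RuntimeError):
            for name in contrasts:
                rows.append((gene, name, np.nan, np.nan, np.nan, np.nan,
                             np.nan, True, np.nan))
            continue
        lrt_p = np.nan
        if lrt_reduced is not None:
            try:
                red = fit_nb_glm(y, lrt_reduced, s, phi)
                dev = red.deviance - fit.deviance
                df = X.shape[1] - lrt_reduced.shape[1]
                lrt_p = float(stats.chi2.sf(max(dev, 0.0), df))
            except (ValueError, RuntimeError):
                pass
        resid_df = len(y) - X.shape[1]
        for name, c in contrasts.items():
            z, p = wald_contrast(fit, c, df=resid_df)
            l2fc = float(c @ fit.params) / LN2
            se = float(np.sqrt(c @ fit.cov_params() @ c)) / LN2
            rows.append((gene, name, l2fc, se, z, p, phi, False, lrt_p))
    out = pd.DataFrame(
        rows, columns=["gene", "contrast", "log2fc", "se", "stat", "p",
                       "dispersion", "failed", "interaction_p"])
    ok = ~out["failed"] & out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    return out


def acclimation_de_per_population(counts: pd.DataFrame, samples: pd.DataFrame,
                                  size_factors: pd.Series,
                                  alpha: float = 0.05) -> pd.DataFrame:
    """28C-vs-12C differential expression within each population.

    Fits the interaction model per gene and tests the acclimation effect in
    each population; BH correction is applied jointly across all three
    contrasts of the model. An interaction likelihood-ratio test (full vs
    additive model, df 2) is reported per gene in ``interaction_p``.
    """
    X, _ = _design_matrices(samples, "population_by_temperature_interaction")
    X_add = X[:, :4]  # additive model: drop the two interaction columns
    contrasts = {
        "N.Ref_28v12": np.array([0, 0, 0, 1, 0, 0], dtype=float),
        "TE_28v12": np.array([0, 0, 0, 1, 1, 0], dtype=float),
        "S.Ref_28v12": np.array([0, 0, 0, 1, 0, 1], dtype=float),
    }
    s = size_factors.loc[samples.index].to_numpy()
    out = _fit_gene_table(counts[samples.index], X, s, contrasts, X_add)
    out["significant"] = out["q"] < alpha
    return out


def population_de_within_temperature(counts: pd.DataFrame,
                                     samples: pd.DataFrame,
                                     size_factors: pd.Series,
                                     alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise population contrasts within one acclimation temperature."""
    if samples["acclimation"].nunique() != 1:
        raise ValueError("samples must come from a single acclimation "
                         "temperature; subset first")
    X, _ = _design_matrices(samples, "population_only")
    # coefficients are log-fold relative to the N.Ref baseline
    contrasts = {
        "TE_vs_NRef": np.array([0, 1, 0], dtype=float),
        "TE_vs_SRef": np.array([0, 1, -1], dtype=float),
        "NRef_vs_SRef": np.array([0, 0, -1], dtype=float),
    }
    s = size_factors.loc[samples.index].to_numpy()
    out = _fit_gene_table(counts[samples.index], X, s, contrasts)
    out["significant"] = out["q"] < alpha
    return out


def classify_adaptive(flags: pd.DataFrame) -> pd.Series:
    """Flag genes where the warmed population differs from both references.

    True iff TE-vs-N.Ref and TE-vs-S.Ref are significant while
    N.Ref-vs-S.Ref is not — the expression pattern consistent with adaptation
    in the thermally altered population.
    """
    missing = [c for c in PAIRWISE_CONTRASTS if c not in flags.columns]
    if missing:
        raise ValueError(f"missing pairwise contrast columns: {missing}")
    out = (flags["TE_vs_NRef"].astype(bool)
           & flags["TE_vs_SRef"].astype(bool)
           & ~flags["NRef_vs_SRef"].astype(bool))
    return out.rename("adaptive")


def overlap_counts(sets: dict[str, set]) -> dict:
    """Exclusive 7-region Venn partition of three DEG sets + shared fraction.

    ``shared_fraction`` = (genes in at least two sets) / (genes in the union).
    """
    if len(sets) != 3:
        raise ValueError("need exactly three sets")
    names = list(sets)
    a, b, c = (set(sets[n]) for n in names)
    union = a | b | c
    regions = {
        f"{names[0]}_only": len(a - b - c),
        f"{names[1]}_only": len(b - a - c),
        f"{names[2]}_only": len(c - a - b),
        f"{names[0]}&{names[1]}": len((a & b) - c),
        f"{names[0]}&{names[2]}": len((a & c) - b),
        f"{names[1]}&{names[2]}": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    in_two_or_more = (a & b) | (a & c) | (b & c)
    regions["union"] = len(union)
    regions["shared_fraction"] = (len(in_two_or_more) / len(union)
                                  if union else 0.0)
    return regions


def chisq_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise ValueError("contingency table has a zero expected cell")
    return float(stat), int(df), float(p)


class NegativeBinomialDE(BaseEstimator):
    """Per-gene NB-GLM differential expression as an sklearn-style estimator.

    Parameters
    ----------
    model : {"population_by_temperature_interaction", "population_only"}
    alpha : float, default 0.05
        BH-FDR significance threshold.

    Attributes
    ----------
    results_ : DataFrame with one row per (gene, contrast): log2 fold change,
        SE, Wald statistic, raw p, BH q (joint across the model's contrasts),
        dispersion and direction.
    """

    def __init__(self,
                 model: str = "population_by_temperature_interaction",
                 alpha: float = 0.05):
        self.model = model
        self.alpha = alpha

    def fit(self, counts: pd.DataFrame, samples: pd.DataFrame,
            size_factors: pd.Series):
        """counts: genes x samples; samples: metadata indexed like columns."""
        if self.model == "population_by_temperature_interaction":
            self.results_ = acclimation_de_per_population(
                counts, samples, size_factors, self.alpha)
        elif self.model == "population_only":
            self.results_ = population_de_within_temperature(
                counts, samples, size_factors, self.alpha)
        else:
            raise ValueError(f"unknown model {self.model!r}")
        return self

    def significant_genes(self, contrast: str) -> set[str]:
        res = self.results_
        hit = res[(res["contrast"] == contrast) & res["significant"]]
        return set(hit["gene"])
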