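"""Count filtering, median-of-ratios normalization, CV profiling, PCA screen.

All functions take a genes x samples count ``DataFrame`` (the field's
conventional orientation). The sklearn-style :class:`MedianRatioScaler`
operates on the transposed samples x genes orientation as sklearn expects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene and sample identifiers must be unique")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    For each gene with strictly positive counts in every sample, compute its
    geometric mean across samples; the factor of sample ``j`` is the median
    over those genes of ``count_gj / geomean_g``. Genes with any zero count
    contribute nothing.
    """
    _validate_counts(counts)
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "pre-filter low-count genes or samples first")
    xp = x[all_pos]
    log_geomean = np.log(xp).mean(axis=1)
    ratios = np.exp(np.log(xp) - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Library-size-normalized expression with its size factors.

    ``values[g, j] * size_factors[j]`` reconstructs the raw counts exactly.
    """

    values: pd.DataFrame       # counts / s_j
    size_factors: pd.Series
    log_values: pd.DataFrame   # log2(values + 1)


def normalize(counts: pd.DataFrame,
              factors: pd.Series | None = None) -> NormalizedMatrix:
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    values = counts / factors
    return NormalizedMatrix(values=values, size_factors=factors,
                            log_values=np.log2(values + 1.0))


def filter_genes(counts: pd.DataFrame, min_count: int = 30,
                 min_fraction: float = 0.10) -> pd.Index:
    """Keep genes with >= min_count in at least ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n = counts.shape[1]
    needed = math.ceil(min_fraction * n)
    ok = (counts.to_numpy() >= min_count).sum(axis=1) >= needed
    return counts.index[ok]


def filter_samples(counts: pd.DataFrame, min_total_reads: float) -> pd.Index:
    """Keep samples whose total read count is >= min_total_reads (inclusive)."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    ok = counts.sum(axis=0) >= min_total_reads
    if not ok.any():
        raise ValueError("minimum-read filter removed every sample")
    return counts.columns[ok]


def cv_profile(normalized: NormalizedMatrix,
               samples: list[str] | pd.Index | None = None,
               group: str = "", scale: str = "linear") -> pd.DataFrame:
    """Per-gene coefficient of variation, 100 * sd / mean, within a sample group.

    Uses the sample standard deviation (n-1 denominator) on normalized
    values (``scale="log"`` switches to log2 values). Genes with zero mean
    get CV = NaN and ``undefined = True`` rather than being dropped.
    """
    values = normalized.log_values if scale == "log" else normalized.values
    if samples is not None:
        values = values[list(samples)]
    if values.shape[1] < 2:
        raise ValueError("CV needs at least 2 samples in the group")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    undefined = mean == 0
    cv[undefined] = np.nan
    return pd.DataFrame({"cv": cv, "undefined": undefined, "group": group})


def compare_cv(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
               paired: bool = True) -> tuple[float, float]:
    """t-test on per-gene CVs between two groups over their shared genes.

    Paired by gene by default (the same mRNAs are profiled in both groups);
    ``paired=False`` gives Welch's unpaired test.
    """
    shared = profile_a.index.intersection(profile_b.index)
    a = profile_a.loc[shared, "cv"]
    b = profile_b.loc[shared, "cv"]
    keep = a.notna() & b.notna()
    a, b = a[keep].to_numpy(), b[keep].to_numpy()
    if len(a) < 3:
        raise ValueError("need at least 3 shared genes with defined CV")
    if paired:
        diffs = a - b
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0  # identical profiles: no difference to test
        if np.allclose(diffs, diffs[0]):
            raise ValueError(
                "paired CV differences are constant and nonzero; "
                "t statistic undefined (zero variance)")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pca_screen(log_values: pd.DataFrame, labels: pd.Series,
               top_n: int = 500, n_components: int = 4) -> pd.DataFrame:
    """PCA of samples on the most variable genes, with a PC1 mislabel screen.

    Selects the ``top_n`` genes by variance of log expression, centers genes
    (no scaling), and computes sample scores by SVD. A sample is flagged as
    an outlier when a 2-group 1-d k-means partition of the PC1 scores
    disagrees with its provided binary label (e.g. tissue) — the algorithmic
    version of removing samples that cluster with the wrong tissue.

    Returns a DataFrame of PC scores, with ``outlier`` flags and per-component
    variance-explained ratios in ``.attrs["variance_ratio"]``.
    """
    n_genes, n_samples = log_values.shape
    if n_samples < 3:
        raise ValueError("PCA screen needs at least 3 samples")
    if top_n > n_genes:
        raise ValueError(f"top_n={top_n} exceeds the {n_genes} available genes")
    labels = labels.loc[log_values.columns]
    if labels.nunique() != 2:
        raise ValueError("screen labels must be binary (e.g. two tissues)")

    variances = log_values.var(axis=1, ddof=1)
    top = variances.nlargest(top_n).index
    x = log_values.loc[top].to_numpy()             # genes x samples
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    total_var = (sv ** 2).sum()
    k = min(n_components, len(sv))
    scores = u[:, :k] * sv[:k]
    ratio = sv[:k] ** 2 / total_var

    km = KMeans(n_clusters=2, n_init=10, random_state=0)
    part = km.fit_predict(scores[:, [0]])
    # align cluster ids with labels by majority vote, then flag disagreements
    lab_codes = pd.factorize(labels)[0]
    agree = (part == lab_codes).mean()
    if agree < 0.5:
        part = 1 - part
    out = pd.DataFrame(scores, index=log_values.columns,
                       columns=[f"PC{i + 1}" for i in range(k)])
    out["outlier"] = part != lab_codes
    out.attrs["variance_ratio"] = ratio
    return out


class MedianRatioScaler(TransformerMixin, BaseEstimator):
    """Median-of-ratios library-size normalization as an sklearn transformer.

    Parameters
    ----------
    log : bool, default False
        If True, ``transform`` returns ``log2(normalized + 1)``.

    Attributes
    ----------
    size_factors_ : ndarray of shape (n_samples,)
        One positive factor per sample of the matrix passed to ``fit``.

    Notes
    -----
    X is samples x genes (sklearn orientation). Because factors are
    per-sample, ``transform`` must be called on the same samples as ``fit``;
    use ``fit_transform`` in pipelines.
    """

    def __init__(self, log: bool = False):
        self.log = log

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_min_features=2)
        counts = pd.DataFrame(X.T)
        self.size_factors_ = size_factors(counts).to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[0] != len(self.size_factors_):
            raise ValueError(
                "size factors are per-sample; transform the matrix that was fit")
        out = X / self.size_factors_[:, None]
        return np.log2(out + 1.0) if self.log else out
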