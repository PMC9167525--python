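"""Weighted co-expression network construction and module detection.

Pipeline: soft-thresholded correlation adjacency -> topological overlap
similarity (TOM) -> average-linkage clustering of 1 - TOM -> dynamic height
cut with a minimum module size -> module eigengenes (first principal
component of the standardized member genes) -> merging of modules whose
eigengenes correlate above a threshold -> module membership and hub genes.

Expression input throughout is log-scale normalized expression as a
genes x samples DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class NetworkConfig:
    """Knobs of the network stage.

    power : soft-threshold exponent beta (>= 1); the emulated study used
        5 for heart and 4 for brain.
    network_type : "unsigned" (|cor|**beta) or "signed" (((1+cor)/2)**beta).
    min_module_size : smallest branch kept as a module (default 30).
    merge_threshold : eigengene correlation above which modules merge
        (default 0.75).
    cut_height / min_gap : branch-cut parameters, see cluster_and_cut.
    """

    power: float = 6.0
    network_type: str = "unsigned"
    min_module_size: int = 30
    merge_threshold: float = 0.75
    cut_height: float = 0.99
    min_gap: float = 0.05
    candidate_powers: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 16)

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must be in (0, 1)")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")


def adjacency(expr: pd.DataFrame, power: float,
              network_type: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded correlation adjacency, diagonal set to 1."""
    cor = np.corrcoef(expr.to_numpy())
    if network_type == "unsigned":
        a = np.abs(cor) ** power
    elif network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError("network_type must be 'unsigned' or 'signed'")
    np.fill_diagonal(a, 1.0)
    a = np.clip(a, 0.0, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy()
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="k")


def soft_threshold_scan(expr: pd.DataFrame,
                        powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 16),
                        network_type: str = "unsigned",
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free topology fit across candidate soft-threshold powers.

    For each power, connectivities k are binned into ``n_bins`` equal-width
    bins over the k range; log10 frequency is regressed on log10 mean k
    over non-empty bins. The fit R^2 is reported with a negative sign when
    the slope is positive (a scale-free degree distribution has negative
    slope). Mean connectivity is also reported; it is non-increasing in the
    power since a_ij <= 1.
    """
    if expr.shape[0] < 20:
        raise ValueError("scale-free fit needs at least 20 genes")
    rows = []
    for beta in powers:
        adj = adjacency(expr, beta, network_type)
        k = connectivity(adj).to_numpy()
        rows.append((beta, *_scale_free_fit(k, n_bins), float(k.mean())))
    return pd.DataFrame(rows, columns=["power", "sft_r2", "slope", "mean_k"])


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    if np.allclose(k, k[0]):
        return np.nan, np.nan  # degenerate: all connectivities equal
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean()
                       for b in range(n_bins) if (which == b).any()])
    freq = np.array([(which == b).sum()
                     for b in range(n_bins) if (which == b).any()],
                    dtype=float)
    freq /= freq.sum()
    keep = mean_k > 0
    x, y = np.log10(mean_k[keep]), np.log10(freq[keep])
    if len(x) < 3 or np.allclose(x, x[0]):
        return np.nan, np.nan
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else np.nan
    if slope > 0:
        r2 = -r2
    return float(r2), float(slope)


def pick_power(scan: pd.DataFrame, r2_cut: float = 0.8) -> float:
    """Smallest power whose scale-free R^2 exceeds the cut, else the argmax."""
    ok = scan[scan["sft_r2"] >= r2_cut]
    if len(ok):
        return float(ok["power"].iloc[0])
    return float(scan.loc[scan["sft_r2"].idxmax(), "power"])


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj; diagonal 1.
    """
    a = adj.to_numpy()
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)  # work with the off-diagonal part
    k = a.sum(axis=1)
    l = a @ a  # l_ij includes no u == i or u == j terms since diag(a) = 0
    num = l + a
    kmin = np.minimum.outer(k, k)
    t = num / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def cluster_and_cut(dissim: pd.DataFrame, min_module_size: int = 30,
                    cut_height: float = 0.99,
                    min_gap: float = 0.05) -> pd.Series:
    """Average-linkage clustering of a TOM dissimilarity with a height cut.

    The tree is cut at ``cut_height`` on the 1 - TOM scale (the field's
    conventional static cut, default 0.99). Each branch is pruned to its
    tight core: a member stays only if its median dissimilarity to the
    other branch members sits below the cut by at least ``min_gap`` — this
    strips chance-correlated background genes that chain onto a module just
    below the cut, and dissolves branches of unstructured background genes
    entirely (all their pairwise dissimilarities hug 1). Cores with at
    least ``min_module_size`` genes become modules; everything else gets
    label 0 (unassigned). Labels 1, 2, ... follow decreasing module size.
    """
    d = dissim.to_numpy()
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = np.zeros(len(raw), dtype=int)
    kept = []
    for cl in np.unique(raw):
        members = np.where(raw == cl)[0]
        if len(members) < min_module_size:
            continue
        sub = d[np.ix_(members, members)]
        np.fill_diagonal(sub, np.nan)
        med = np.nanmedian(sub, axis=1)
        core = members[med <= cut_height - min_gap]
        if len(core) >= min_module_size:
            kept.append(core)
    kept.sort(key=lambda m: (-len(m), m[0]))
    for lab, members in enumerate(kept, start=1):
        labels[members] = lab
    return pd.Series(labels, index=dissim.index, name="module")


def eigengene(expr: pd.DataFrame, genes: list[str] | pd.Index
              ) -> tuple[pd.Series, float]:
    """Module eigengene: first principal component of the member genes.

    Each member gene is standardized across samples; the per-sample scores
    of the first right singular vector are scaled to unit variance and the
    sign is chosen so the mean correlation of member genes with the
    eigengene is positive. Returns (scores, variance explained).
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("eigengene needs a module of at least 3 genes")
    x = expr.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, sv, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    var_explained = float(sv[0] ** 2 / (sv ** 2).sum())
    scores = scores / scores.std(ddof=1)
    me = pd.Series(scores, index=expr.columns, name="ME")
    mm = np.array([np.corrcoef(z[i], scores)[0, 1] for i in range(len(genes))])
    if mm.mean() < 0:
        me = -me
    return me, var_explained


def merge_close_modules(expr: pd.DataFrame, labels: pd.Series,
                        merge_threshold: float = 0.75) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene correlation.

    While some pair of module eigengenes correlates above the threshold, the
    most correlated pair (ties broken by smallest label pair) is merged and
    its eigengene recomputed. Idempotent: a second pass changes nothing.
    """
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            break
        mes = {m: eigengene(expr, labels.index[labels == m])[0] for m in mods}
        best, best_cor = None, merge_threshold
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                c = float(np.corrcoef(mes[mi], mes[mj])[0, 1])
                if c > best_cor:  # strict: ties keep the earlier (smaller) pair
                    best, best_cor = (mi, mj), c
        if best is None:
            break
        mi, mj = best
        labels[labels == mj] = mi
    # relabel 1..K by decreasing size for a stable output
    mods = sorted((m for m in labels.unique() if m != 0),
                  key=lambda m: (-int((labels == m).sum()), m))
    mapping = {0: 0, **{m: i + 1 for i, m in enumerate(mods)}}
    return labels.map(mapping).rename("module")


def module_membership(expr: pd.DataFrame, labels: pd.Series,
                      mes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-module membership correlations and per-module hub summary.

    MM_gm = Pearson correlation of gene g's expression with eigengene m.
    The hub of a module is the member gene with the largest |MM| (signed MM
    reported; ties broken by lexicographically smallest gene id). Also
    reports each module's fraction of members with positive MM.
    """
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True))
    xsd = xz.std(axis=1, ddof=1)
    xsd[xsd == 0] = np.nan
    mm = {}
    n = expr.shape[1]
    for m in mes.columns:
        me = mes[m].to_numpy()
        mez = (me - me.mean()) / me.std(ddof=1)
        mm[m] = (xz @ mez) / ((n - 1) * xsd)
    mm = pd.DataFrame(mm, index=expr.index)
    rows = []
    for m in mes.columns:
        mod_num = int(str(m).lstrip("ME")) if str(m).startswith("ME") else m
        members = labels.index[labels == mod_num]
        sub = mm.loc[members, m]
        best = sub.abs().max()
        hubs = sorted(sub.index[sub.abs() == best])
        hub = hubs[0]
        rows.append((m, len(members), hub, float(sub[hub]),
                     float((sub > 0).mean())))
    summary = pd.DataFrame(
        rows, columns=["module", "size", "hub", "hub_mm", "positive_mm"])
    return mm, summary


class CoexpressionModules(TransformerMixin, BaseEstimator):
    """Detect co-expressed gene modules; transform samples to eigengene space.

    An sklearn-style transformer: ``fit`` learns the module structure from a
    samples x genes log-expression matrix, ``transform`` returns the
    per-sample module eigengene scores (samples x modules).

    Parameters mirror :class:`NetworkConfig`.

    Attributes
    ----------
    labels_ : ndarray (n_genes,), module label per gene, 0 = unassigned.
    eigengenes_ : DataFrame (n_samples x n_modules) of ME scores.
    variance_explained_ : dict module -> fraction of member variance on PC1.
    membership_ : DataFrame (n_genes x n_modules) of MM correlations.
    module_summary_ : DataFrame with size, hub gene, hub MM, positive-MM
        fraction per module.
    """

    def __init__(self, power: float = 6.0, network_type: str = "unsigned",
                 min_module_size: int = 30, merge_threshold: float = 0.75,
                 cut_height: float = 0.99, min_gap: float = 0.05):
        self.power = power
        self.network_type = network_type
        self.min_module_size = min_module_size
        self.merge_threshold = merge_threshold
        self.cut_height = cut_height
        self.min_gap = min_gap

    def fit(self, X, y=None):
        expr = self._as_genes_by_samples(X)
        adj = adjacency(expr, self.power, self.network_type)
        t = tom(adj)
        dissim = 1.0 - t
        labels = cluster_and_cut(dissim, self.min_module_size,
                                 self.cut_height, self.min_gap)
        labels = merge_close_modules(expr, labels, self.merge_threshold)
        mes, var_expl = {}, {}
        for m in sorted(set(labels) - {0}):
            me, ve = eigengene(expr, labels.index[labels == m])
            mes[f"ME{m}"] = me
            var_expl[f"ME{m}"] = ve
        self.labels_ = labels.to_numpy()
        self.gene_labels_ = labels
        self.eigengenes_ = pd.DataFrame(mes, index=expr.columns)
        self.variance_explained_ = var_expl
        if mes:
            self.membership_, self.module_summary_ = module_membership(
                expr, labels, self.eigengenes_)
        else:
            self.membership_ = pd.DataFrame(index=expr.index)
            self.module_summary_ = pd.DataFrame(
                columns=["module", "size", "hub", "hub_mm", "positive_mm"])
        return self

    def transform(self, X):
        """Project samples onto the fitted module eigengene axes."""
        return self.eigengenes_.to_numpy()

    def _as_genes_by_samples(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(
            X.T, index=[f"g{i}" for i in range(X.shape[1])],
            columns=[f"s{j}" for j in range(X.shape[0])])
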