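"""Exploratory structure of the region x sample signal.

The visualization chain follows quantile normalization -> log2(x + 1) ->
row median centering; clustering and PCA then operate on the normalized
matrix.  All operations are deterministic for fixed input.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the distribution of row-wise sorted means.

    Each column's sorted values are replaced by the across-column means of the
    column-sorted matrix; ties within a column receive the mean of the tied
    target values.
    """
    if m.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    arr = m.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0  # 0-based
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def log2_pseudocount(m: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudo); the default pseudocount of one read keeps zeros finite."""
    if (m.to_numpy() < 0).any():
        raise ValueError("negative values passed to log2_pseudocount")
    return np.log2(m + pseudo)


def median_center_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's median; with an odd sample count medians become 0."""
    return m.sub(m.median(axis=1), axis=0)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Transformer applying quantile normalization -> log2(+pseudo) -> median centering.

    Any step can be switched off; defaults reproduce the standard heatmap
    input (counts are quantile normalized across samples, log2 transformed
    with a pseudocount of one read, and median centered per region).
    """

    def __init__(self, log2: bool = True, pseudo: float = 1.0, median_center: bool = True):
        self.log2 = log2
        self.pseudo = pseudo
        self.median_center = median_center

    def fit(self, X: pd.DataFrame, y=None) -> "QuantileNormalizer":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = quantile_normalize(X)
        if self.log2:
            out = log2_pseudocount(out, self.pseudo)
        if self.median_center:
            out = median_center_rows(out)
        return out


def hierarchical_cluster(
    m: pd.DataFrame, linkage: str = "average", metric: str = "euclidean"
) -> dict:
    """Agglomerative clustering of the samples (columns) of ``m``.

    Returns the scipy linkage matrix, the dendrogram leaf order (sample ids)
    and the 2-cluster partition as a sample -> {1, 2} mapping.
    """
    if m.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = m.to_numpy(dtype=float).T  # samples x features
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    leaves = hierarchy.leaves_list(Z)
    two_cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return {
        "linkage": Z,
        "leaf_order": [m.columns[i] for i in leaves],
        "two_cut": dict(zip(m.columns, two_cut.tolist())),
    }


class TopVariablePCA(BaseEstimator, TransformerMixin):
    """PCA of the samples over the ``n_top`` most variable features.

    Features (rows of the input matrix) are ranked by variance across
    samples; the top 500 (default) are kept, centered, and decomposed by SVD.
    ``transform`` returns sample scores (samples x components).
    """

    def __init__(self, n_top: int = 500, n_components: int = 2):
        self.n_top = n_top
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None) -> "TopVariablePCA":
        variances = X.var(axis=1)
        if not (variances > 0).any():
            raise ValueError("matrix has no feature with nonzero variance")
        n_top = min(self.n_top, X.shape[0])
        if n_top < self.n_top:
            logger.warning("only %d features available (< n_top=%d); using all", n_top, self.n_top)
        self.top_features_ = variances.nlargest(n_top).index
        sub = X.loc[self.top_features_].to_numpy(dtype=float).T  # samples x features
        n_comp = min(self.n_components, sub.shape[0] - 1, sub.shape[1])
        self._pca = PCA(n_components=n_comp, svd_solver="full")
        self._pca.fit(sub)
        self.variance_explained_ = self._pca.explained_variance_ratio_
        self.sample_ids_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        sub = X.loc[self.top_features_].to_numpy(dtype=float).T
        scores = self._pca.transform(sub)
        return pd.DataFrame(
            scores,
            index=X.columns,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        )


def pca_top_variable(
    m: pd.DataFrame, n_top: int = 500, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Functional wrapper: (sample scores, variance explained per component)."""
    est = TopVariablePCA(n_top=n_top, n_components=n_components).fit(m)
    return est.transform(m), est.variance_explained_


def manhattan_table(
    results: pd.DataFrame, regions: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Genome-ordered scatter data: one row per region with -log10 p and direction.

    ``regions`` must carry chrom/start/end and a feature id matching the
    result index; the cumulative x-coordinate concatenates chromosomes in
    ``chrom_sizes`` order.
    """
    rdf = regions.copy()
    id_col = "region_id" if "region_id" in rdf.columns else None
    ids = rdf[id_col] if id_col else rdf.index
    missing = [i for i in ids if i not in results.index]
    if missing:
        raise ValueError(f"regions without a differential result: {missing[:5]} ...")
    offsets: dict[str, int] = {}
    cum = 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = cum
        cum += int(size)
    res = results.loc[list(ids)]
    mid = (rdf["start"].to_numpy() + rdf["end"].to_numpy()) // 2
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(res["p"].to_numpy())
    out = pd.DataFrame(
        {
            "feature_id": list(ids),
            "chrom": rdf["chrom"].to_numpy(),
            "midpoint": mid,
            "x_cumulative": rdf["chrom"].map(offsets).to_numpy() + mid,
            "neg_log10_p": neglogp,
            "direction": res["direction"].to_numpy(),
        }
    )
    return out


def detect_outlier_samples(
    scores: pd.DataFrame, groups: pd.Series, k_sd: float = 3.0
) -> list[str]:
    """Flag samples deviating > ``k_sd`` robust SDs from their group mean on PC1/PC2.

    Robust SD is 1.4826 * MAD within the sample's group; reporting only —
    exclusion is the caller's decision.
    """
    flagged: list[str] = []
    pcs = [c for c in ("PC1", "PC2") if c in scores.columns]
    for grp in pd.unique(groups):
        members = [s for s in scores.index if groups[s] == grp]
        sub = scores.loc[members, pcs]
        center = sub.median(axis=0)
        mad = (sub - center).abs().median(axis=0) * 1.4826
        mad = mad.replace(0.0, np.nan)
        z = ((sub - center) / mad).abs()
        for s in members:
            if (z.loc[s] > k_sd).any():
                flagged.append(s)
    return flagged
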