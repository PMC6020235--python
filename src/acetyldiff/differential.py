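"""Negative-binomial two-group Wald testing with median-of-ratios normalization.

This is the engine behind both the "differentially acetylated regions" (ChIP
arm) and differentially expressed genes (RNA arm).  The model per feature i
and sample j is

    K_ij ~ NB(mu_ij, alpha_i),     Var = mu + alpha * mu^2
    log mu_ij = log s_j + beta0_i + beta1_i * x_j

with x_j the case/control indicator, s_j median-of-ratios size factors and
alpha_i a trend-moderated method-of-moments dispersion.  beta1 is estimated
by iteratively reweighted least squares (Fisher scoring) with alpha fixed;
the Wald statistic beta1/se(beta1) is referred to a standard normal and
Benjamini-Hochberg adjusted across features.

Deliberately simpler than full DESeq2: no Cox-Reid dispersion adjustment, no
outlier replacement, no independent filtering, no LFC shrinkage.  The target
properties are type-I calibration and unbiased fold-change recovery, not
line-for-line DESeq2 equality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .quantify import CountMatrix

LN2 = np.log(2.0)

DIRECTION_LABELS = {"chip": ("hyper", "hypo"), "rna": ("up", "down")}


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features (positive in every sample) of
    count_ij / geometric_mean_i.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in all samples; "
            "filter low-count features before normalization"
        )
    logc = np.log(counts[all_pos])
    log_geomean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geomean, axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def estimate_dispersions(
    cm: CountMatrix,
    size_factors: pd.Series,
    trend_weight: float = 0.5,
    alpha_floor: float = 1e-8,
) -> pd.Series:
    """Trend-moderated method-of-moments NB dispersions on normalized counts.

    Per feature, a pooled within-group variance gives the raw
    alpha_i = max((var_i - mean_i) / mean_i^2, floor); a mean-dispersion
    trend alpha = a0 + a1/mean is fitted by least squares across features
    and the final estimate is the weighted blend
    (1 - w) * alpha_i + w * trend(mean_i).
    """
    n = len(cm.sample_ids)
    if n < 3:
        raise ValueError("dispersion estimation needs at least 3 samples")
    norm = cm.counts.to_numpy(dtype=float) / size_factors.loc[cm.sample_ids].to_numpy()
    group = cm.group_indicator().astype(bool)
    mean_all = norm.mean(axis=1)
    # pooled within-group variance (removes the group effect from the MoM)
    ss = np.zeros(norm.shape[0])
    df_resid = 0
    for mask in (group, ~group):
        sub = norm[:, mask]
        if sub.shape[1] >= 1:
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df_resid += sub.shape[1] - 1
    var_pooled = ss / max(df_resid, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_pooled - mean_all) / mean_all**2
    raw = np.where(np.isfinite(raw), raw, alpha_floor)
    raw = np.maximum(raw, alpha_floor)
    # trend alpha = a0 + a1/mean, least squares over features with mean > 0
    ok = mean_all > 0
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_all[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        trend = coef[0] + coef[1] / np.maximum(mean_all, 1e-12)
        trend = np.maximum(trend, alpha_floor)
    else:
        trend = np.full_like(raw, alpha_floor)
    alpha = (1.0 - trend_weight) * raw + trend_weight * trend
    alpha = np.maximum(alpha, alpha_floor)
    return pd.Series(alpha, index=cm.feature_ids, name="dispersion")


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are propagated and excluded from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def _irls_nb(
    counts: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    x: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    beta_cap: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Fisher-scoring fit of log mu = log s + b0 + b1*x per feature.

    Returns (beta1, se1, converged).  Features whose coefficient walks past
    ``beta_cap`` in absolute value (degenerate groups) or that fail to
    converge within ``max_iter`` are flagged non-converged.
    """
    n_feat, n_samp = counts.shape
    log_sf = np.log(sf)
    case = x.astype(bool)
    eps = 1e-8
    mu_case = (counts[:, case] / sf[case]).mean(axis=1)
    mu_ctrl = (counts[:, ~case] / sf[~case]).mean(axis=1)
    b0 = np.log(np.maximum(mu_ctrl, eps))
    b1 = np.log(np.maximum(mu_case, eps)) - b0
    alive = np.ones(n_feat, dtype=bool)
    n_case = case.sum()
    n_ctrl = n_samp - n_case
    for _ in range(max_iter):
        eta = log_sf[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - log_sf[None, :] + (counts - mu) / np.maximum(mu, 1e-300)
        # per-feature 2x2 normal equations for design [1, x]
        s00 = w.sum(axis=1)
        s01 = (w * x[None, :]).sum(axis=1)
        s11 = (w * (x**2)[None, :]).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * z * x[None, :]).sum(axis=1)
        det = s00 * s11 - s01**2
        bad = det <= 1e-300
        det = np.where(bad, 1.0, det)
        new_b0 = (s11 * t0 - s01 * t1) / det
        new_b1 = (s00 * t1 - s01 * t0) / det
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = np.where(alive, new_b0, b0), np.where(alive, new_b1, b1)
        alive = alive & (delta >= tol) & ~bad & (np.abs(b1) <= beta_cap)
        if not alive.any():
            break
    # final information matrix at the solution
    eta = log_sf[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -700, 700))
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1)
    s01 = (w * x[None, :]).sum(axis=1)
    s11 = (w * (x**2)[None, :]).sum(axis=1)
    det = s00 * s11 - s01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = s00 / det
    se1 = np.sqrt(np.where(det > 0, var_b1, np.nan))
    converged = (~alive) & (np.abs(b1) <= beta_cap) & np.isfinite(se1) & (se1 > 0)
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("both groups need at least 2 samples for the Wald test")
    return b1, se1, converged


class NBWaldTest(BaseEstimator):
    """Two-group negative-binomial Wald test, DESeq2-style but simplified.

    Parameters
    ----------
    p_threshold : float
        Significance cutoff for direction calls (default 0.05).
    use_padj : bool
        Call directions on BH-adjusted p (default) rather than raw p.
    arm : {"chip", "rna"}
        Direction vocabulary: hyper/hypo for ChIP, up/down for RNA.
    trend_weight : float
        Blend weight toward the mean-dispersion trend.
    drop_all_zero : bool
        Drop features with zero counts in every sample before testing.
    dispersions : pd.Series or None
        Fixed per-feature dispersions; skips estimation when given.

    Attributes (after :meth:`fit`)
    ------------------------------
    size_factors_ : pd.Series
    dispersions_ : pd.Series
    results_ : pd.DataFrame with columns feature_id (index), base_mean,
        log2fc, se, wald_z, p, padj, direction.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        use_padj: bool = True,
        arm: str = "chip",
        trend_weight: float = 0.5,
        drop_all_zero: bool = True,
        dispersions: pd.Series | None = None,
    ):
        self.p_threshold = p_threshold
        self.use_padj = use_padj
        self.arm = arm
        self.trend_weight = trend_weight
        self.drop_all_zero = drop_all_zero
        self.dispersions = dispersions

    def fit(self, cm: CountMatrix, y=None) -> "NBWaldTest":
        if self.arm not in DIRECTION_LABELS:
            raise ValueError(f"arm must be one of {sorted(DIRECTION_LABELS)}")
        counts_df = cm.counts
        if self.drop_all_zero:
            nonzero = (counts_df > 0).any(axis=1)
            counts_df = counts_df[nonzero]
            cm = CountMatrix(counts_df, cm.groups)
        sf = estimate_size_factors(cm)
        if self.dispersions is not None:
            alpha = self.dispersions.loc[counts_df.index]
        else:
            alpha = estimate_dispersions(cm, sf, trend_weight=self.trend_weight)
        counts = counts_df.to_numpy(dtype=float)
        x = cm.group_indicator()
        b1, se1, conv = _irls_nb(counts, sf.to_numpy(), alpha.to_numpy(), x)
        wald = np.where(conv, b1 / se1, np.nan)
        p = np.where(conv, 2.0 * stats.norm.sf(np.abs(wald)), np.nan)
        padj = bh_adjust(p)
        base_mean = (counts / sf.to_numpy()).mean(axis=1)
        res = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": b1 / LN2,
                "se": se1 / LN2,
                "wald_z": wald,
                "p": p,
                "padj": padj,
            },
            index=counts_df.index,
        )
        res.index.name = "feature_id"
        res = call_differential(
            res, p_threshold=self.p_threshold, use_padj=self.use_padj, arm=self.arm
        )
        self.size_factors_ = sf
        self.dispersions_ = alpha
        self.results_ = res
        return self

    @property
    def significant_(self) -> pd.DataFrame:
        return self.results_[self.results_["direction"] != "ns"]


def call_differential(
    results: pd.DataFrame,
    p_threshold: float = 0.05,
    use_padj: bool = True,
    arm: str = "chip",
) -> pd.DataFrame:
    """Attach direction calls (hyper/hypo or up/down vs 'ns') to a result table."""
    up_label, down_label = DIRECTION_LABELS[arm]
    pcol = results["padj"] if use_padj else results["p"]
    sig = (pcol < p_threshold).fillna(False).to_numpy()
    lfc = results["log2fc"].to_numpy()
    direction = np.where(
        sig & (lfc > 0), up_label, np.where(sig & (lfc < 0), down_label, "ns")
    )
    out = results.copy()
    out["direction"] = direction
    return out


def nb_wald_test(cm: CountMatrix, **params) -> pd.DataFrame:
    """Functional wrapper: fit :class:`NBWaldTest` and return its result table."""
    return NBWaldTest(**params).fit(cm).results_
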