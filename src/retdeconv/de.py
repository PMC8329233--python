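"""Negative-binomial two-group differential expression (Wald test).

A deliberately small NB engine: median-of-ratios size factors, gene-wise
method-of-moments dispersion on normalized counts, and a Wald test on
log2(q2/q1) where the group means q_k are fitted by Newton iteration under
mu_i = s_i * exp(o_i) * q_group(i). Per-sample log offsets o_i let calibrated
comparisons run on integer counts. No dispersion shrinkage, Cook's filtering,
or independent filtering — the calibration method upstream is agnostic to the
DE backend, and this one is pluggable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AnalysisError, DimensionError
from .markers import bh_adjust
from .synthetic import BulkMatrix

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


def filter_genes(bulk: BulkMatrix, min_sample_fraction: float = 0.20) -> BulkMatrix:
    """Drop genes expressed (count > 0) in less than the given fraction of samples.

    The boundary is kept: a gene nonzero in exactly 20% of samples survives a
    0.20 threshold ("less than" elimination).
    """
    frac = (bulk.counts > 0).mean(axis=1)
    keep = frac >= min_sample_fraction
    return BulkMatrix(counts=bulk.counts.loc[keep].copy(), conditions=bulk.conditions.copy())


def size_factors(counts: pd.DataFrame | BulkMatrix, allow_fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Uses genes with nonzero counts in every sample; when none exist and the
    fallback is allowed, genes nonzero in >= 90% of samples are used with
    geometric means taken over their nonzero entries.
    """
    if isinstance(counts, BulkMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    n_genes, n_samples = mat.shape
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        sub = mat[all_nonzero]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
    else:
        if not allow_fallback:
            raise AnalysisError("size_factors: no gene is nonzero in every sample")
        mostly = (mat > 0).mean(axis=1) >= 0.9
        if not mostly.any():
            raise AnalysisError("size_factors: no gene is nonzero in >= 90% of samples")
        sub = mat[mostly]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
    with np.errstate(invalid="ignore"):
        log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _moment_dispersion(z: np.ndarray, inv_c: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Gene-wise NB dispersion by method of moments on normalized counts.

    For normalized counts z_i = y_i / c_i, Var(z_i) = q/c_i + alpha q^2 within
    a group with mean q; alpha is the within-group moment estimate averaged
    over groups with weights (n_k - 1), floored at DISPERSION_FLOOR.
    """
    G = z.shape[0]
    num = np.zeros(G)
    den = 0.0
    for idx in group_idx:
        n_k = idx.size
        if n_k < 2:
            continue
        zk = z[:, idx]
        qk = zk.mean(axis=1)
        vk = zk.var(axis=1, ddof=1)
        pois = qk * inv_c[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            ak = np.where(qk > 0, (vk - pois) / np.maximum(qk, 1e-300) ** 2, 0.0)
        num += (n_k - 1) * ak
        den += n_k - 1
    if den == 0:
        raise AnalysisError("dispersion estimation needs >= 2 samples in some group")
    return np.maximum(num / den, DISPERSION_FLOOR)


def _fit_group_mean(y: np.ndarray, c: np.ndarray, alpha: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Solve sum_i (y_i - c_i q)/(1 + alpha c_i q) = 0 per gene (Newton on log q)."""
    with np.errstate(divide="ignore"):
        q = y.sum(axis=1) / c.sum()
    zero = q <= 0
    q = np.where(zero, 1e-12, q)
    eta = np.log(q)
    for _ in range(n_iter):
        mu = c[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta[zero] = np.log(1e-12)
    return eta


def nb_wald_test(
    bulk: BulkMatrix | pd.DataFrame,
    group1: str,
    group2: str,
    sf: pd.Series | None = None,
    offsets: pd.Series | None = None,
    dispersion: float | np.ndarray | str = "estimate",
    conditions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group2 vs group1.

    mu_i = s_i * exp(o_i) * q_group(i); the statistic is
    (log q2 - log q1)/SE with SE from the expected Fisher information
    I_k = sum_{i in k} mu_i/(1 + alpha mu_i). Returns a DataFrame with
    base_mean, log2_FC, lfcSE, stat, p_raw, p_adj and a degenerate flag.
    """
    if isinstance(bulk, BulkMatrix):
        counts, conditions = bulk.counts, bulk.conditions
    else:
        counts = bulk
        if conditions is None:
            raise DimensionError("nb_wald_test: conditions required with a raw DataFrame")
    for g in (group1, group2):
        if (conditions == g).sum() < 2:
            raise AnalysisError(f"nb_wald_test: group '{g}' needs >= 2 samples")
    keep = conditions.isin([group1, group2])
    counts = counts.loc[:, keep.index[keep]]
    conditions = conditions[keep]
    if sf is None:
        sf = size_factors(counts)
    sf = sf.reindex(counts.columns)
    if offsets is None:
        offsets = pd.Series(0.0, index=counts.columns)
    offsets = offsets.reindex(counts.columns).fillna(0.0)

    y = counts.to_numpy(dtype=float)
    c = sf.to_numpy() * np.exp(offsets.to_numpy())
    z = y / c[None, :]
    idx1 = np.flatnonzero((conditions == group1).to_numpy())
    idx2 = np.flatnonzero((conditions == group2).to_numpy())

    if isinstance(dispersion, str) and dispersion == "estimate":
        alpha = _moment_dispersion(z, 1.0 / c, [idx1, idx2])
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()
        alpha = np.maximum(alpha, DISPERSION_FLOOR)

    eta1 = _fit_group_mean(y[:, idx1], c[idx1], alpha)
    eta2 = _fit_group_mean(y[:, idx2], c[idx2], alpha)
    mu1 = c[idx1][None, :] * np.exp(eta1)[:, None]
    mu2 = c[idx2][None, :] * np.exp(eta2)[:, None]
    info1 = (mu1 / (1.0 + alpha[:, None] * mu1)).sum(axis=1)
    info2 = (mu2 / (1.0 + alpha[:, None] * mu2)).sum(axis=1)
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / np.maximum(info1, 1e-300) + 1.0 / np.maximum(info2, 1e-300))
    delta = eta2 - eta1
    stat = delta / se
    p = 2.0 * norm.sf(np.abs(stat))

    zero1 = y[:, idx1].sum(axis=1) == 0
    zero2 = y[:, idx2].sum(axis=1) == 0
    degenerate = zero1 | zero2
    stat = np.where(degenerate, 0.0, stat)
    delta = np.where(degenerate, 0.0, delta)
    p = np.where(degenerate, 1.0, p)

    res = pd.DataFrame(
        {
            "base_mean": z.mean(axis=1),
            "log2_FC": delta / LN2,
            "lfcSE": se / LN2,
            "stat": stat,
            "p_raw": p,
            "degenerate": degenerate,
        },
        index=counts.index,
    )
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["dispersion"] = alpha
    return res
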