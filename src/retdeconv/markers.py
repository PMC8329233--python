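"""Cell-type-specific marker gene selection from a labeled single-cell matrix.

A gene is a marker of cell type j when (i) it is significantly higher in type-j
cells than in all other cells (two-sided Wilcoxon rank-sum on log-normalized
expression, BH-adjusted p < 0.05, fold change > 2) and (ii) it is widely
expressed in the target type (>50% of cells) but in no other type (<30% of
cells in every other type). A gene may qualify for more than one type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigError
from .synthetic import SingleCellMatrix

#: per-cell normalization target before log1p (counts-per-10k convention)
NORM_TARGET = 1e4
#: pseudocount protecting fold-change ratios of near-zero means
FC_PSEUDOCOUNT = 1e-9
#: largest group size for which the exact rank-sum null is enumerated
EXACT_MAX_N = 8

DEFAULT_THRESHOLDS = dict(alpha=0.05, min_fc=2.0, min_pct_target=0.5, max_pct_other=0.3)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Uses the exact null distribution for small tie-free samples
    (max group size <= 8) and the tie- and continuity-corrected normal
    approximation otherwise. Degenerate inputs where every value is tied
    return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(x.size, y.size) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expressed_fraction(counts_row, cell_mask) -> float:
    """Fraction of masked cells with a nonzero count for one gene."""
    row = np.asarray(counts_row).ravel()
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("expressed_fraction: mask selects no cells")
    return float(np.count_nonzero(row[mask]) / mask.sum())


@dataclass
class MarkerSet:
    """Markers G_j of one cell type with their selection statistics."""

    cell_type: str
    table: pd.DataFrame  # index gene; fold_change, p_raw, p_adj, pct_target, pct_other_max

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def m(self) -> int:
        return len(self.table)


def _lognorm_dense(counts: sp.spmatrix) -> np.ndarray:
    """Counts-per-10k, log1p. Returns genes x cells dense float array."""
    dense = np.asarray(counts.todense(), dtype=float) if sp.issparse(counts) else np.asarray(counts, float)
    libs = dense.sum(axis=0)
    libs[libs == 0] = 1.0
    return np.log1p(dense / libs * NORM_TARGET)


def _pct_expressed(dense_counts: np.ndarray, groups: pd.Series) -> pd.DataFrame:
    out = {}
    for ct in groups.unique():
        mask = (groups == ct).to_numpy()
        out[ct] = (dense_counts[:, mask] > 0).mean(axis=1)
    return pd.DataFrame(out)


def select_markers(
    sc: SingleCellMatrix,
    scope: str = "all",
    alpha: float = DEFAULT_THRESHOLDS["alpha"],
    min_fc: float = DEFAULT_THRESHOLDS["min_fc"],
    min_pct_target: float = DEFAULT_THRESHOLDS["min_pct_target"],
    max_pct_other: float = DEFAULT_THRESHOLDS["max_pct_other"],
) -> dict[str, MarkerSet]:
    """Select marker sets per cell type within a region scope.

    ``scope`` is "all" or a region label carried by the matrix. Fold change is
    the ratio of normalized (counts-per-10k) group means with a small
    pseudocount, enrichment-directional: only target/rest > ``min_fc`` counts.
    BH adjustment is applied across all genes within each one-vs-rest
    comparison.
    """
    if scope != "all":
        if sc.regions is None:
            raise ConfigError(f"scope '{scope}' requested but the matrix has no region labels")
        keep = (sc.regions == scope).to_numpy()
        if keep.sum() == 0:
            raise AnalysisError(f"scope '{scope}' selects no cells")
    else:
        keep = np.ones(sc.n_cells, dtype=bool)

    dense = np.asarray(sc.counts.todense(), dtype=float)[:, keep]
    groups = sc.cell_types[keep].reset_index(drop=True)
    types = [t for t in pd.unique(groups) if (groups == t).sum() >= 2]
    if len(types) < 2:
        raise AnalysisError("marker selection needs at least 2 cell types in scope")

    logn = _lognorm_dense(dense)
    cp10k = np.expm1(logn)  # normalized expression on the linear scale
    pct = _pct_expressed(dense, groups)

    result: dict[str, MarkerSet] = {}
    gene_index = pd.Index(sc.gene_ids)
    for ct in types:
        mask = (groups == ct).to_numpy()
        target, rest = logn[:, mask], logn[:, ~mask]
        p_raw = _vector_wilcoxon(target, rest)
        p_adj = bh_adjust(p_raw)
        mean_t = cp10k[:, mask].mean(axis=1)
        mean_r = cp10k[:, ~mask].mean(axis=1)
        fc = (mean_t + FC_PSEUDOCOUNT) / (mean_r + FC_PSEUDOCOUNT)
        pct_target = pct[ct].to_numpy()
        other_cols = [c for c in pct.columns if c != ct]
        pct_other_max = pct[other_cols].to_numpy().max(axis=1)
        sel = (p_adj < alpha) & (fc > min_fc) & (pct_target > min_pct_target) & (pct_other_max < max_pct_other)
        table = pd.DataFrame(
            {
                "fold_change": fc[sel],
                "p_raw": p_raw[sel],
                "p_adj": p_adj[sel],
                "pct_target": pct_target[sel],
                "pct_other_max": pct_other_max[sel],
            },
            index=gene_index[sel],
        ).sort_values("p_adj")
        result[ct] = MarkerSet(cell_type=ct, table=table)
    return result


def _vector_wilcoxon(target: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Row-wise asymptotic two-sided rank-sum p; constant rows get p = 1."""
    p = np.ones(target.shape[0])
    pooled = np.concatenate([target, rest], axis=1)
    varying = ~np.all(pooled == pooled[:, [0]], axis=1)
    if varying.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(
                target[varying], rest[varying], axis=1, alternative="two-sided", method="asymptotic"
            )
        p[varying] = np.nan_to_num(res.pvalue, nan=1.0)
    return p


def markers_to_frame(marker_sets: dict[str, MarkerSet]) -> pd.DataFrame:
    """Long-format table (cell_type, gene, stats) for writing markers.tsv."""
    rows = []
    for ct, ms in marker_sets.items():
        tab = ms.table.copy()
        tab.insert(0, "gene", tab.index)
        tab.insert(0, "cell_type", ct)
        rows.append(tab.reset_index(drop=True))
    if not rows:
        return pd.DataFrame(columns=["cell_type", "gene", "fold_change", "p_raw", "p_adj", "pct_target", "pct_other_max"])
    return pd.concat(rows, ignore_index=True)


def frame_to_markers(frame: pd.DataFrame) -> dict[str, MarkerSet]:
    out = {}
    for ct, grp in frame.groupby("cell_type", sort=False):
        out[ct] = MarkerSet(cell_type=ct, table=grp.set_index("gene").drop(columns=["cell_type"]))
    return out
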