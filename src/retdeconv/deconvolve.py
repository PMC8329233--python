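"""Reference-based estimation of cell-type proportions in bulk samples.

A signature matrix of per-type mean relative expression is built from the
labeled single-cell reference, and each bulk sample is decomposed by
non-negative least squares on the signature genes. This is a deliberately
plain solver: cross-subject variance weighting (as in MuSiC) is a separate
method and out of scope here; the module boundary allows a weighted solver to
be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_ind

from .errors import AnalysisError, DimensionError
from .markers import bh_adjust
from .synthetic import BulkMatrix, SingleCellMatrix

DEFAULT_GENE_FILTER = dict(min_pct=0.05, min_cells=10)


@dataclass
class SignatureMatrix:
    """Gene x cell-type mean relative expression; columns sum to 1."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy()
        if (vals < 0).any():
            raise DimensionError("signature profiles must be non-negative")
        sums = vals.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise DimensionError("signature columns must sum to 1")

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def C(self) -> int:
        return self.profiles.shape[1]


@dataclass
class ProportionResult:
    """NNLS proportion estimates for a set of bulk samples."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    residual_norm: pd.Series
    rank_deficient: bool = False
    flags: dict = field(default_factory=dict)


def build_signature(
    sc: SingleCellMatrix,
    min_pct: float = DEFAULT_GENE_FILTER["min_pct"],
    min_cells: int = DEFAULT_GENE_FILTER["min_cells"],
    genes: list[str] | None = None,
) -> SignatureMatrix:
    """Per-type mean relative expression over genes passing the expression filter.

    A gene is retained when, in at least one cell type, it is expressed in at
    least ``min_pct`` of that type's cells and in more than ``min_cells``
    cells. ``genes`` optionally restricts the basis further (e.g. to markers).
    """
    dense = np.asarray(sc.counts.todense(), dtype=float)
    libs = dense.sum(axis=0)
    libs[libs == 0] = 1.0
    rel = dense / libs  # per-cell relative expression

    types = list(pd.unique(sc.cell_types))
    keep = np.zeros(sc.n_genes, dtype=bool)
    col_means = {}
    for ct in types:
        mask = (sc.cell_types == ct).to_numpy()
        n_expr = (dense[:, mask] > 0).sum(axis=1)
        keep |= (n_expr >= min_pct * mask.sum()) & (n_expr > min_cells)
        col_means[ct] = rel[:, mask].mean(axis=1)
    index = pd.Index(sc.gene_ids)
    if genes is not None:
        keep &= np.asarray(index.isin(list(genes)))
    if not keep.any():
        raise AnalysisError("build_signature: no gene passes the expression filter")
    prof = pd.DataFrame(col_means, index=index).loc[keep]
    sums = prof.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise AnalysisError(f"build_signature: cell type(s) with zero passing expression: {bad}")
    return SignatureMatrix(profiles=prof / sums)


def estimate_proportions(bulk: BulkMatrix | pd.DataFrame, sig: SignatureMatrix) -> ProportionResult:
    """Marker-restricted NNLS deconvolution of each bulk sample.

    Bulk vectors are restricted to the signature genes and normalized to
    relative abundance (sum 1) before solving min ||y - S p||^2, p >= 0; the
    estimates are renormalized to sum 1. Library size therefore cannot affect
    the result.
    """
    counts = bulk.counts if isinstance(bulk, BulkMatrix) else bulk
    shared = [g for g in sig.genes if g in counts.index]
    if len(shared) < sig.C:
        raise DimensionError(
            f"estimate_proportions: only {len(shared)} signature genes shared with bulk; need >= {sig.C}"
        )
    S = sig.profiles.loc[shared].to_numpy()
    rank_deficient = np.linalg.matrix_rank(S) < sig.C
    if rank_deficient:
        warnings.warn("signature matrix is rank deficient; proportions are not identifiable", RuntimeWarning)
    Y = counts.loc[shared].to_numpy(dtype=float)
    sums = Y.sum(axis=0)
    props = np.zeros((Y.shape[1], sig.C))
    resid = np.zeros(Y.shape[1])
    for i in range(Y.shape[1]):
        y = Y[:, i] / sums[i] if sums[i] > 0 else Y[:, i]
        p, r = nnls(S, y)
        total = p.sum()
        props[i] = p / total if total > 0 else np.full(sig.C, 1.0 / sig.C)
        resid[i] = r
    cols = list(sig.profiles.columns)
    return ProportionResult(
        proportions=pd.DataFrame(props, index=counts.columns, columns=cols),
        residual_norm=pd.Series(resid, index=counts.columns, name="residual_norm"),
        rank_deficient=rank_deficient,
    )


def test_proportion_difference(
    proportions: pd.DataFrame,
    conditions: pd.Series,
    group1: str | list[str],
    group2: str | list[str],
) -> pd.DataFrame:
    """Welch two-sample t-test per cell type between condition groups.

    Either group may pool several condition labels (the reference analysis
    compares the control stage against the pooled later stages; pairwise
    contrasts are obtained by passing single labels). BH adjustment is across
    the cell types tested. Zero variance in both groups yields p = 1 with a
    degeneracy flag.
    """
    g1 = [group1] if isinstance(group1, str) else list(group1)
    g2 = [group2] if isinstance(group2, str) else list(group2)
    conditions = conditions.reindex(proportions.index)
    m1 = conditions.isin(g1).to_numpy()
    m2 = conditions.isin(g2).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise AnalysisError("test_proportion_difference: each group needs >= 2 samples")
    rows = []
    for ct in proportions.columns:
        a = proportions.loc[m1, ct].to_numpy()
        b = proportions.loc[m2, ct].to_numpy()
        degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
        if degenerate:
            t, p = 0.0, 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = ttest_ind(b, a, equal_var=False)
            if not np.isfinite(p):
                t, p, degenerate = 0.0, 1.0, True
        rows.append(dict(cell_type=ct, mean_1=a.mean(), mean_2=b.mean(), t_stat=float(t), p_raw=float(p), degenerate=degenerate))
    out = pd.DataFrame(rows).set_index("cell_type")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out
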