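"""Proportion-change calibration and cell-type-specific DEG detection.

The core idea: for a gene g specific to cell type j, the bulk fold change
between disease and control factorizes as FC_g ~= PC_j * FC_jg, where
PC_j = p_j(disease)/p_j(control) is the cell type's proportion change and
FC_jg the within-cell-type expression change. If few genes in the marker set
G_j are truly differentially expressed, the mean log bulk fold change over G_j
estimates log PC_j; dividing disease expression by PC_j ("calibration") then
removes the composition component, and an NB test on calibrated expression
targets FC_jg directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de
from .errors import AnalysisError, ConfigError, DimensionError
from .markers import MarkerSet, bh_adjust
from .synthetic import BulkMatrix

log = logging.getLogger(__name__)


def bulk_fold_change(
    bulk: BulkMatrix,
    group1: str,
    group2: str,
    genes: list[str] | None = None,
    sf: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Bulk fold change FC_g = mean_norm(group2) / mean_norm(group1) per gene.

    Counts are normalized by median-of-ratios size factors (computed on the
    full matrix unless ``sf`` is given) so that library-size differences
    between groups do not masquerade as composition change. Genes with a zero
    group mean are flagged undefined (``defined`` = False) unless a
    ``pseudocount`` is added to both means.
    """
    s1 = bulk.samples_in(group1)
    s2 = bulk.samples_in(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise AnalysisError("bulk_fold_change: both groups need >= 2 samples")
    if sf is None:
        sf = de.size_factors(bulk.counts)
    counts = bulk.counts if genes is None else bulk.counts.loc[[g for g in genes if g in bulk.counts.index]]
    if genes is not None and counts.shape[0] < len(genes):
        missing = sorted(set(genes) - set(counts.index))
        raise DimensionError(f"bulk_fold_change: genes absent from bulk: {missing[:5]}...")
    norm = counts / sf.reindex(counts.columns)
    m1 = norm[s1].mean(axis=1) + pseudocount
    m2 = norm[s2].mean(axis=1) + pseudocount
    defined = (m1 > 0) & (m2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(defined, m2 / np.where(m1 > 0, m1, 1.0), np.nan)
        log_fc = np.log(np.where(defined, fc, 1.0))
    out = pd.DataFrame(
        {"FC": fc, "log_FC": np.where(defined, log_fc, np.nan), "defined": defined},
        index=counts.index,
    )
    return out


@dataclass
class ProportionChange:
    """Estimated proportion change of one cell type and its provenance."""

    cell_type: str
    PC: float
    m_used: int
    contributing_log_FCs: np.ndarray
    estimator: str = "mean"
    n_undefined: int = 0


def estimate_proportion_change(
    fold_changes: pd.DataFrame,
    cell_type: str = "",
    robust: str = "mean",
    trim: float = 0.2,
) -> ProportionChange:
    """PC_j = exp(central tendency of log FC over the defined marker records).

    ``robust`` selects the central tendency: "mean" (the estimator's plain
    form), "trimmed_mean" (symmetric trimming of ``trim`` per tail), or
    "median" — the robust options guard against a contaminated marker set in
    which some genes are genuinely differentially expressed.
    """
    defined = fold_changes["defined"].to_numpy(dtype=bool)
    logs = fold_changes.loc[defined, "log_FC"].to_numpy(dtype=float)
    n_undef = int((~defined).sum())
    if n_undef:
        log.info("estimate_proportion_change[%s]: %d undefined fold changes excluded", cell_type, n_undef)
    if logs.size == 0:
        raise AnalysisError(f"estimate_proportion_change[{cell_type}]: no defined fold change")
    if robust == "mean":
        center = logs.mean()
    elif robust == "median":
        center = float(np.median(logs))
    elif robust == "trimmed_mean":
        from scipy.stats import trim_mean

        center = float(trim_mean(logs, trim))
    else:
        raise ConfigError(f"robust: unknown estimator '{robust}'")
    return ProportionChange(
        cell_type=cell_type,
        PC=float(np.exp(center)),
        m_used=int(logs.size),
        contributing_log_FCs=logs,
        estimator=robust,
        n_undefined=n_undef,
    )


def calibrate_expression(
    bulk: BulkMatrix,
    pc: ProportionChange | float,
    disease_group: str,
    genes: list[str] | None = None,
    mode: str = "offset",
    direction: str = "corrected",
    round_counts: bool = True,
):
    """Remove the composition component PC_j from disease-sample expression.

    direction="corrected" (default) divides disease expression by PC_j, so the
    calibrated disease/control fold change estimates the within-cell-type
    FC_jg; direction="paper_literal" multiplies disease expression by PC_j
    instead (retained for reproduction of the alternative convention, which
    does not cancel the composition factor but squares it).

    mode="offset" leaves counts untouched and returns per-sample log offsets
    for the NB engine (the offset enters the model mean, so dividing counts by
    PC is equivalent to a +log PC offset on disease samples). mode=
    "scaled_counts" returns a new BulkMatrix with disease columns scaled
    (rounded half-to-even unless ``round_counts`` is False, in which case
    non-integer values are kept).
    """
    pc_value = pc.PC if isinstance(pc, ProportionChange) else float(pc)
    if not pc_value > 0:
        raise ConfigError("calibrate_expression: PC must be strictly positive")
    if direction not in ("corrected", "paper_literal"):
        raise ConfigError(f"direction: unknown value '{direction}'")
    scale = 1.0 / pc_value if direction == "corrected" else pc_value
    disease = bulk.conditions == disease_group
    if mode == "offset":
        # mean mu = s * exp(o) * q: o = -log(scale) makes q the calibrated level
        offsets = pd.Series(np.where(disease, -np.log(scale), 0.0), index=bulk.conditions.index)
        return offsets
    if mode == "scaled_counts":
        counts = bulk.counts if genes is None else bulk.counts.loc[genes]
        scaled = counts.astype(float).copy()
        cols = bulk.conditions.index[disease]
        scaled[cols] = scaled[cols] * scale
        if round_counts:
            scaled = pd.DataFrame(
                np.rint(scaled.to_numpy()), index=scaled.index, columns=scaled.columns
            )
        return BulkMatrix(counts=scaled, conditions=bulk.conditions.copy())
    raise ConfigError(f"mode: unknown value '{mode}'")


@dataclass
class CtDEGResult:
    """Per-cell-type calibrated differential expression tables."""

    table: pd.DataFrame  # cell_type, gene, calibrated_log2_FC, p_raw, p_adj, direction
    pc: dict[str, ProportionChange] = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def detect_ctdegs(
    bulk: BulkMatrix,
    marker_sets: dict[str, MarkerSet],
    group1: str,
    group2: str,
    pcs: dict[str, ProportionChange] | None = None,
    robust: str = "median",
    alpha: float = 0.05,
    direction: str = "corrected",
    dispersion: float | str = "estimate",
) -> CtDEGResult:
    """Detect cell-type-specific DEGs between two conditions.

    For each cell type: candidates are its marker genes (already widely
    expressed in the type by construction of the marker criteria) present in
    the bulk matrix; PC_j is estimated from their bulk fold changes (median of
    log fold changes by default, robust to a contaminated marker set) unless
    supplied; the NB Wald test runs with the calibration as per-sample log
    offsets; BH adjustment is within each cell type's candidate family. A gene
    specific to several types is tested under each.
    """
    sf = de.size_factors(bulk.counts)
    tables = []
    pcs_out: dict[str, ProportionChange] = {}
    for ct, ms in marker_sets.items():
        genes = [g for g in ms.genes if g in bulk.counts.index]
        if not genes:
            warnings.warn(f"detect_ctdegs: no candidate genes for cell type '{ct}'", RuntimeWarning)
            continue
        if pcs is not None and ct in pcs:
            pc = pcs[ct]
        else:
            fc = bulk_fold_change(bulk, group1, group2, genes=genes, sf=sf)
            pc = estimate_proportion_change(fc, cell_type=ct, robust=robust)
        pcs_out[ct] = pc
        offsets = calibrate_expression(bulk, pc, disease_group=group2, mode="offset", direction=direction)
        sub = BulkMatrix(counts=bulk.counts.loc[genes], conditions=bulk.conditions)
        res = de.nb_wald_test(sub, group1, group2, sf=sf, offsets=offsets, dispersion=dispersion)
        res = res.rename(columns={"log2_FC": "calibrated_log2_FC"})
        res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())  # family = this cell type's candidates
        res.insert(0, "gene", res.index)
        res.insert(0, "cell_type", ct)
        res["direction"] = np.where(res["calibrated_log2_FC"] >= 0, "up", "down")
        res["PC"] = pc.PC
        tables.append(res.reset_index(drop=True))
    if not tables:
        warnings.warn("detect_ctdegs: empty candidate sets for all cell types", RuntimeWarning)
        table = pd.DataFrame(
            columns=["cell_type", "gene", "calibrated_log2_FC", "p_raw", "p_adj", "direction", "PC"]
        )
    else:
        table = pd.concat(tables, ignore_index=True)
    return CtDEGResult(table=table, pc=pcs_out)
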