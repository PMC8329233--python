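"""Synthetic single-cell references and bulk mixtures with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a labeled single-cell reference with cell-type-specific marker genes,
and bulk samples formed as proportion-weighted mixtures of cell-type expression
profiles, Y_ig = sum_j p_ij * X_ijg, with negative-binomial counting noise.
Condition-dependent proportions and planted cell-type-specific expression
changes provide ground truth for proportion-change estimation and ctDEG
detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, DimensionError

# Cell-type names used when 11 or fewer types are simulated; the first entry
# plays the role of the dominant photoreceptor population whose proportion
# declines with disease in the default design.
RETINA_CELL_TYPES = (
    "rods",
    "cones",
    "bipolar",
    "horizontal",
    "amacrine",
    "ganglion",
    "muller",
    "astrocytes",
    "microglia",
    "endothelium",
    "pericytes",
)

REGIONS = ("macula", "periphery")


def _as_list(value, n: int, name: str) -> list:
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ConfigError(f"{name}: expected scalar or length-{n} sequence, got length {len(value)}")
    return value


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    ``conditions`` maps condition labels to sample counts; the first label is
    the reference (control). ``proportions_by_condition`` maps each label to a
    length-C proportion vector summing to 1. ``proportion_noise`` is the
    Dirichlet concentration for subject-level composition around the condition
    mean (``inf`` for identical composition within condition).
    ``ctdeg_fc`` is the expression multiplier applied to planted
    cell-type-specific DE genes in non-reference conditions (<1 means
    down-regulation). ``marker_fc`` is the ratio of a marker's relative
    expression in its own type to its expression in every other type.
    """

    n_celltypes: int = 11
    n_genes: int = 2000
    cells_per_type: int | Sequence[int] = 300
    markers_per_type: int | Sequence[int] = 20
    marker_fc: float = 50.0
    conditions: Sequence[tuple[str, int]] = (("control", 8), ("early", 4), ("advanced", 3))
    proportions_by_condition: Mapping[str, Sequence[float]] | None = None
    ctdeg_fraction: float = 0.1
    ctdeg_fc: float = 0.25
    nb_dispersion: float | Sequence[float] = 0.1
    library_size_mean: float = 5000.0
    bulk_library_size: float = 3e5
    library_size_sigma: float = 0.25
    proportion_noise: float = 300.0
    profile_jitter_sd: float = 0.1
    seed: int = 0

    # filled by __post_init__
    celltype_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        C = self.n_celltypes
        if not isinstance(C, (int, np.integer)) or C < 1:
            raise ConfigError("n_celltypes: must be a positive integer")
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be a positive integer")
        self.cells_per_type = [int(x) for x in _as_list(self.cells_per_type, C, "cells_per_type")]
        if any(x < 2 for x in self.cells_per_type):
            raise ConfigError("cells_per_type: every cell type needs at least 2 cells")
        self.markers_per_type = [int(x) for x in _as_list(self.markers_per_type, C, "markers_per_type")]
        if any(x < 0 for x in self.markers_per_type):
            raise ConfigError("markers_per_type: must be non-negative")
        if sum(self.markers_per_type) > self.n_genes:
            raise ConfigError("markers_per_type: total markers exceed n_genes")
        if not self.marker_fc > 0:
            raise ConfigError("marker_fc: must be strictly positive")
        self.conditions = [(str(lbl), int(n)) for lbl, n in self.conditions]
        if len(self.conditions) < 1:
            raise ConfigError("conditions: at least one condition required")
        if any(n < 1 for _, n in self.conditions):
            raise ConfigError("conditions: sample counts must be positive")
        if len({lbl for lbl, _ in self.conditions}) != len(self.conditions):
            raise ConfigError("conditions: labels must be unique")
        if self.celltype_names is None:
            if C <= len(RETINA_CELL_TYPES):
                self.celltype_names = list(RETINA_CELL_TYPES[:C])
            else:
                self.celltype_names = [f"type_{i:02d}" for i in range(C)]
        else:
            self.celltype_names = [str(x) for x in self.celltype_names]
            if len(self.celltype_names) != C:
                raise ConfigError("celltype_names: length must equal n_celltypes")
        if self.proportions_by_condition is None:
            self.proportions_by_condition = self._default_proportions()
        props = {}
        for lbl, _ in self.conditions:
            if lbl not in self.proportions_by_condition:
                raise ConfigError(f"proportions_by_condition: missing condition '{lbl}'")
            p = np.asarray(self.proportions_by_condition[lbl], dtype=float)
            if p.shape != (C,):
                raise ConfigError(f"proportions_by_condition[{lbl}]: expected length {C}")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"proportions_by_condition[{lbl}]: must be non-negative and sum to 1")
            props[lbl] = p
        self.proportions_by_condition = props
        if not 0.0 <= self.ctdeg_fraction <= 1.0:
            raise ConfigError("ctdeg_fraction: must be in [0, 1]")
        if not self.ctdeg_fc > 0:
            raise ConfigError("ctdeg_fc: must be strictly positive")
        disp = np.atleast_1d(np.asarray(self.nb_dispersion, dtype=float))
        if np.any(disp <= 0):
            raise ConfigError("nb_dispersion: must be strictly positive")
        if disp.size not in (1, self.n_genes):
            raise ConfigError("nb_dispersion: scalar or per-gene vector")
        for name in ("library_size_mean", "bulk_library_size"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name}: must be strictly positive")
        if self.library_size_sigma < 0:
            raise ConfigError("library_size_sigma: must be non-negative")
        if not self.proportion_noise > 0:
            raise ConfigError("proportion_noise: must be strictly positive (np.inf for none)")
        if self.profile_jitter_sd < 0:
            raise ConfigError("profile_jitter_sd: must be non-negative")

    def _default_proportions(self) -> dict[str, np.ndarray]:
        """Dominant first type declines from 0.5 to 0.2 across conditions."""
        C = self.n_celltypes
        K = len(self.conditions)
        out = {}
        for k, (lbl, _) in enumerate(self.conditions):
            frac = k / max(K - 1, 1)
            if C == 1:
                out[lbl] = np.array([1.0])
                continue
            lead = 0.5 - 0.3 * frac
            rest = (1.0 - lead) / (C - 1)
            out[lbl] = np.array([lead] + [rest] * (C - 1))
        return out

    @property
    def dispersion_vector(self) -> np.ndarray:
        disp = np.atleast_1d(np.asarray(self.nb_dispersion, dtype=float))
        if disp.size == 1:
            disp = np.full(self.n_genes, float(disp[0]))
        return disp


@dataclass
class GroundTruth:
    """Simulation record against which every downstream stage can be scored."""

    true_profiles: pd.DataFrame  # genes x cell types, columns sum to 1
    planted_markers: dict[str, list[str]]
    planted_ctdegs: dict[str, dict[str, float]]  # gene -> effect multiplier
    true_PC: dict[str, pd.Series]  # condition -> per-type p^k / p^ref
    true_proportions: pd.DataFrame | None = None  # samples x cell types
    bulk_mean: pd.DataFrame | None = None  # expected (pre-NB) bulk counts
    config: SimConfig | None = None

    def markers_of(self, cell_type: str) -> set[str]:
        return set(self.planted_markers.get(cell_type, ()))

    def ctdegs_of(self, cell_type: str) -> set[str]:
        return set(self.planted_ctdegs.get(cell_type, ()))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative binomial via the gamma-Poisson mixture; dispersion broadcast per row."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float).reshape(-1, 1), mean.shape)
    shape = 1.0 / disp
    lam = rng.gamma(shape, disp * mean)
    return rng.poisson(lam)


def _build_profiles(config: SimConfig, rng: np.random.Generator):
    G, C = config.n_genes, config.n_celltypes
    gene_ids = [f"gene_{i:05d}" for i in range(G)]
    base = rng.gamma(1.5, 1.0, size=G)
    # assign disjoint marker blocks at random gene positions
    total_markers = sum(config.markers_per_type)
    marker_pos = rng.choice(G, size=total_markers, replace=False)
    planted: dict[str, list[str]] = {}
    X = np.tile(base[:, None], (1, C))
    pos_iter = iter(marker_pos)
    for j, ct in enumerate(config.celltype_names):
        idx = np.array([next(pos_iter) for _ in range(config.markers_per_type[j])], dtype=int)
        planted[ct] = [gene_ids[i] for i in idx]
        if idx.size:
            # markers express at a high, floored level in their own type and
            # marker_fc-fold lower everywhere else
            own = rng.gamma(2.0, 1.0, size=idx.size) + 1.0
            X[idx, :] = (own / config.marker_fc)[:, None]
            X[idx, j] = own
    if config.profile_jitter_sd > 0:
        X = X * rng.lognormal(0.0, config.profile_jitter_sd, size=X.shape)
    X = X / X.sum(axis=0, keepdims=True)
    profiles = pd.DataFrame(X, index=gene_ids, columns=list(config.celltype_names))
    return profiles, planted


@dataclass
class SingleCellMatrix:
    """Sparse gene x cell count matrix with cell-type and region labels."""

    counts: sp.csr_matrix  # genes x cells
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: pd.Series  # index = cell_ids
    regions: pd.Series | None = None

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DimensionError("gene_ids length does not match count matrix rows")
        if len(self.cell_ids) != n_cells or len(self.cell_types) != n_cells:
            raise DimensionError("cell labels do not match count matrix columns")
        if self.regions is not None and len(self.regions) != n_cells:
            raise DimensionError("regions length does not match count matrix columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DimensionError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class BulkMatrix:
    """Dense gene x sample count matrix with per-sample condition labels."""

    counts: pd.DataFrame  # genes x samples
    conditions: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.conditions.index):
            self.conditions = self.conditions.reindex(self.counts.columns)
            if self.conditions.isna().any():
                raise DimensionError("every sample needs a condition label")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise DimensionError("bulk counts must be finite and non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def simulate_reference(config: SimConfig) -> tuple[SingleCellMatrix, GroundTruth]:
    """Draw a labeled single-cell reference and the ground truth that made it."""
    rng = np.random.default_rng(config.seed)
    profiles, planted = _build_profiles(config, rng)
    C = config.n_celltypes

    # plant ctDEG effects inside each marker set (applied only in bulk disease
    # conditions); the first ceil(fraction*m) markers of each type are planted
    planted_ctdegs: dict[str, dict[str, float]] = {}
    for ct in config.celltype_names:
        m = len(planted[ct])
        k = math.ceil(config.ctdeg_fraction * m) if config.ctdeg_fraction > 0 else 0
        chosen = rng.choice(planted[ct], size=min(k, m), replace=False) if k else []
        planted_ctdegs[ct] = {g: float(config.ctdeg_fc) for g in chosen}

    ref_label = config.conditions[0][0]
    p_ref = config.proportions_by_condition[ref_label]
    true_pc = {}
    for lbl, _ in config.conditions:
        p_k = config.proportions_by_condition[lbl]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_ref > 0, p_k / np.where(p_ref > 0, p_ref, 1.0), np.nan)
        true_pc[lbl] = pd.Series(ratio, index=list(config.celltype_names))

    blocks = []
    cell_types = []
    regions = []
    X = profiles.to_numpy()
    disp = config.dispersion_vector
    mu_log = math.log(config.library_size_mean) - config.library_size_sigma**2 / 2
    for j, ct in enumerate(config.celltype_names):
        n = config.cells_per_type[j]
        libs = rng.lognormal(mu_log, config.library_size_sigma, size=n)
        mean = X[:, [j]] * libs[None, :]
        blocks.append(sp.csr_matrix(_nb_draw(rng, mean, disp)))
        cell_types.extend([ct] * n)
        regions.extend([REGIONS[i % 2] for i in range(n)])
    counts = sp.hstack(blocks, format="csr")
    n_cells = counts.shape[1]
    cell_ids = [f"cell_{i:06d}" for i in range(n_cells)]
    sc = SingleCellMatrix(
        counts=counts,
        gene_ids=list(profiles.index),
        cell_ids=cell_ids,
        cell_types=pd.Series(cell_types, index=cell_ids, name="cell_type"),
        regions=pd.Series(regions, index=cell_ids, name="region"),
    )
    truth = GroundTruth(
        true_profiles=profiles,
        planted_markers=planted,
        planted_ctdegs=planted_ctdegs,
        true_PC=true_pc,
        config=config,
    )
    return sc, truth


def simulate_bulk(config: SimConfig, truth: GroundTruth, seed: int | None = None) -> BulkMatrix:
    """Draw bulk mixtures Y_ig ~ NB(L_i * sum_j p_ij X_ijg, dispersion).

    Subject proportions p_i are Dirichlet around the condition mean; planted
    ctDEG effects multiply the affected type's profile in every non-reference
    condition. Realized proportions and expected means are stored back into
    ``truth``.
    """
    if truth.config is not None and list(truth.true_profiles.index) != [
        f"gene_{i:05d}" for i in range(config.n_genes)
    ]:
        raise DimensionError("truth gene set does not match config.n_genes")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    X_base = truth.true_profiles.to_numpy()
    gene_index = truth.true_profiles.index
    type_names = list(truth.true_profiles.columns)
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    disp = config.dispersion_vector
    mu_log = math.log(config.bulk_library_size) - config.library_size_sigma**2 / 2

    # disease profile: planted effects multiplied into the owning type's column
    X_disease = X_base.copy()
    for j, ct in enumerate(type_names):
        for g, eff in truth.planted_ctdegs.get(ct, {}).items():
            X_disease[gene_pos[g], j] *= eff

    sample_ids, cond_labels, rows_p, means = [], [], [], []
    ref_label = config.conditions[0][0]
    for lbl, n_k in config.conditions:
        p_mean = config.proportions_by_condition[lbl]
        Xc = X_base if lbl == ref_label else X_disease
        for i in range(n_k):
            sid = f"{lbl}_{i:02d}"
            if np.isinf(config.proportion_noise):
                p_i = p_mean.copy()
            else:
                alpha = config.proportion_noise * np.maximum(p_mean, 1e-12)
                p_i = rng.dirichlet(alpha)
            lib = rng.lognormal(mu_log, config.library_size_sigma)
            mean_i = lib * (Xc @ p_i)
            sample_ids.append(sid)
            cond_labels.append(lbl)
            rows_p.append(p_i)
            means.append(mean_i)
    mean_mat = np.column_stack(means)
    counts = _nb_draw(rng, mean_mat, disp)
    bulk = BulkMatrix(
        counts=pd.DataFrame(counts, index=gene_index, columns=sample_ids),
        conditions=pd.Series(cond_labels, index=sample_ids, name="condition"),
    )
    truth.true_proportions = pd.DataFrame(np.vstack(rows_p), index=sample_ids, columns=type_names)
    truth.bulk_mean = pd.DataFrame(mean_mat, index=gene_index, columns=sample_ids)
    return bulk


def simulate_study(config: SimConfig) -> tuple[SingleCellMatrix, BulkMatrix, GroundTruth]:
    """Reference and bulk in one call, sharing one ground truth."""
    sc, truth = simulate_reference(config)
    bulk = simulate_bulk(config, truth)
    return sc, bulk, truth
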