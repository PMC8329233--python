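# Methods

This document states the statistical models behind `retdeconv`, the
assumptions each component relies on, the generator's scope and limits, and
the numerical choices made in the implementation.

## 1. The mixture model

Bulk expression of gene `g` in sample `i` is modeled as a linear mixture of
cell-type profiles:

```
Y_ig  =  L_i · Σ_j  p_ij · X_jg        (expected counts)
```

where `X_·j` is cell type `j`'s relative expression profile (column sums to
1), `p_ij` the cell-type proportions of sample `i` (sum to 1 over `j`), and
`L_i` the library size. Group fold changes are ratios of group mean
normalized expression:

```
FC_g = mean_i∈disease(Y_ig / s_i) / mean_i∈control(Y_ig / s_i)
```

with `s_i` the median-of-ratios size factors.

**Key identity.** If gene `g` is expressed (essentially) only in cell type
`j`, the mixture collapses to `Y_ig ∝ p_ij · X_jg` and

```
FC_g ≈ PC_j · FC_jg ,     PC_j = p_j(disease) / p_j(control)
```

so composition change (`PC_j`) and within-cell-type expression change
(`FC_jg`) factor apart. Everything in `retdeconv.calibrate` follows from this.

### Assumptions, stated explicitly

- **Specificity**: marker genes are expressed almost exclusively in their
  target type. The marker criteria (section 3) enforce a testable proxy
  (expressed in < 30% of cells of every other type); genuine low-level
  off-type expression biases `PC_j` toward 1 in proportion to the off-type
  share of the bulk signal.
- **Sparse within-type DE**: most genes in a marker set `G_j` are *not*
  differentially expressed within the cell type, so the central tendency of
  their log fold changes isolates `log PC_j`. The default median estimator
  tolerates a minority of true DEGs in `G_j`; the arithmetic mean is biased
  by (DE fraction) × (mean log effect).
- **Stable within-condition composition**: subjects of the same condition
  have similar proportions (modeled as a concentrated Dirichlet).
- **Linearity of bulk in cell content** — no cell-type-specific capture
  efficiency.

## 2. Proportion-change estimation and calibration

```
PC_j = exp( T({ log FC_g : g ∈ G_j, FC_g defined }) )
```

where `T` is the mean (`estimate_proportion_change`'s default, the estimator's
plain form), median (the `detect_ctdegs` pipeline default, for robustness), or
a symmetric trimmed mean. Genes with a zero group mean are excluded and
counted (`n_undefined`).

**Calibration** removes the composition component from disease samples. The
default direction (`corrected`) *divides* disease expression by `PC_j`, so
the calibrated fold change estimates `FC_jg`:

```
mean_G_j log FC  =  log PC_j  +  mean_G_j log FC_calibrated      (exact identity)
```

This identity holds to machine precision when calibration is applied as an
unrounded scaling with fixed size factors, and is verified to 1e-9 in the
acceptance suite. An alternative direction (`paper_literal`) *multiplies*
disease expression by `PC_j`; it is retained as an explicit option because
this convention appears in the applied literature, but note it does not cancel
the composition factor (the calibrated fold change becomes `PC_j² · FC_jg`).
The package default is the corrected direction.

**Implementation**: calibration enters the NB test as a per-sample log offset
(`+log PC_j` on disease samples in the model mean `μ = s·e^o·q`), which is
algebraically identical to dividing counts by `PC_j` but keeps counts integer
and the likelihood exact.

## 3. Marker selection

One-vs-rest per cell type on the single-cell reference, on log-normalized
expression (counts-per-10k, `log1p`). A gene is a marker of type `j` iff all
four hold:

1. Wilcoxon rank-sum adjusted p < 0.05 (BH within the one-vs-rest
   comparison),
2. fold change > 2 (ratio of expm1-means of the normalized expression, with a
   1e-9 pseudocount),
3. expressed (count > 0) in > 50% of cells of type `j`,
4. expressed in < 30% of cells of **every** other type (a hard gate, not a
   max over a subset).

The rank-sum test uses scipy's `mannwhitneyu`: exact distribution for
tie-free samples with both sizes ≤ 8, normal approximation with tie and
continuity correction otherwise; identical samples return p = 1 by
construction. BH is statsmodels' `fdr_bh`. Both are verified in the tests
against independent oracles (full enumeration of group assignments; the
direct step-up formula).

## 4. Deconvolution

The signature matrix holds per-type mean relative expression over genes
expressed in ≥ 5% of cells *and* more than 10 cells of at least one type;
columns are normalized to sum to 1. Bulk vectors are normalized the same way
and proportions are estimated by non-negative least squares
(`scipy.optimize.nnls`), then renormalized to sum to 1. A rank-deficient
signature triggers a `RuntimeWarning` and a flag on the result. Condition
differences in proportions use Welch's t-test per type with BH across types.

On exact mixtures of the signature columns, recovery is exact to < 1e-6
(acceptance criterion); under NB noise at dispersion 0.1 with 20 samples the
mean absolute error stays below the pre-registered 0.05 bound.

## 5. The NB Wald engine

Per gene, counts follow `NB(mean μ_i = s_i · e^{o_i} · q_group, dispersion α)`:

- **Size factors**: median-of-ratios (geometric-mean reference over genes
  positive in all samples, factors rescaled to geometric mean 1). If no gene
  is positive everywhere, a fallback reference uses genes positive in ≥ 90%
  of samples (or an error if `allow_fallback=False`).
- **Dispersion**: gene-wise method of moments on normalized counts
  `z = y/c` (`c = s·e^o`), using `Var(z) = q/c̄ + α q²`, pooled across the two
  groups with weights `n_k − 1`, floored at 1e-8. A fixed dispersion can be
  supplied instead.
- **Group means**: Newton iterations on `log q` solving the NB score equation
  `Σ_i (y_i − c_i q)/(1 + α c_i q) = 0` (steps clipped to ±5 on the log
  scale).
- **Wald test**: `stat = (log q₂ − log q₁) / SE`, with the standard error
  from the expected Fisher information `I = Σ_i μ_i/(1 + α μ_i)` per group;
  two-sided normal p-value; `log2_FC = (log q₂ − log q₁)/ln 2`. Genes with an
  all-zero group are reported as degenerate (`p = 1`, `log2_FC = 0`).

This is a deliberately simplified engine: no dispersion shrinkage across
genes, no outlier refitting, no independent filtering. It keeps the
established conventions (median-of-ratios, Wald on log2 fold change) while
remaining small enough to verify exactly.

### Exact invariances (and one that cannot be exact)

The engine is *exactly* invariant to: adding a constant to all offsets,
swapping group labels (negates `log2_FC`, preserves p), and rescaling the
size-factor vector by a constant. `PC_j` is exactly invariant to per-sample
library rescaling when size factors are recomputed. Doubling all counts
together with all size factors is **not** an exact invariance for any model
of counting noise — doubled counts genuinely carry more Poisson-level
information — so that property is tested at a small tolerance instead, and
the exact statements above are what the acceptance suite checks exactly.

## 6. Calibrated ctDEG detection

For each cell type: candidates are its markers present in the bulk matrix;
`PC_j` is estimated from their fold changes (median by default) unless
supplied; the NB Wald test runs with the calibration offsets; BH adjustment
is within the cell type's candidate family. A gene belonging to several
marker sets is tested under each.

## 7. Synthetic data generator

- **Profiles**: background expression `Gamma(1.5, 1)`; a marker's own-type
  value is `Gamma(2, 1) + 1` and its value in every other type is that
  divided by `marker_fc`; optional lognormal jitter (`profile_jitter_sd`)
  decorrelates types; columns normalized to sum 1.
- **Single cells**: per-cell library sizes lognormal around
  `library_size_mean`; counts are gamma-Poisson (i.e. NB with dispersion
  `nb_dispersion`) around `library × profile`.
- **Bulk**: per-sample proportions are Dirichlet around the condition's
  target composition with concentration `proportion_noise` (∞ = exact);
  expected counts are `library × (X @ p)`; counts NB around that. Planted
  ctDEGs multiply the profile values of a fraction `ctdeg_fraction` of each
  type's markers by `ctdeg_fc` in non-reference conditions, **without**
  re-normalizing the profile (the perturbation is a genuine expression
  change, not a compositional artifact). True proportions, profiles, marker
  sets, ctDEG sets, `PC` values and expected bulk means are all stored in
  the returned ground truth.

**Scope and limits**: no doublets or ambient RNA, no cell-type hierarchies,
no batch effects, no gene–gene correlation beyond the mixture structure,
dispersion constant across genes, planted DE restricted to marker genes (by
design, so ctDEG truth is well-defined under the specificity assumption).

## 8. Pre-registered evaluation settings

The simulation settings and bounds for the acceptance evaluations were fixed
*before* the acceptance tests were first run, from the method's own stated
assumptions rather than from observed outcomes:

- `marker_fc = 1000`, `profile_jitter_sd = 0` in the PC-recovery / type-I /
  ctDEG simulations: the factorization premise is that type-specific genes
  have negligible off-type expression. At `marker_fc = 50`, off-type
  contamination alone biases `log PC` by ~0.1 for a type shrinking 0.4× —
  that measures violation of the specificity assumption, not estimator
  error.
- Dirichlet concentration 1000 (stable within-condition composition), bulk
  NB dispersion 0.1, bulk library mean 3×10⁵, 20 vs 20 samples.
- Bounds: median |log PC error| < 0.05 per type; post-calibration type-I
  error within [0.03, 0.07] at nominal 0.05 (uncalibrated ablation > 0.5);
  pooled ctDEG FDR ≤ 0.1 and sensitivity ≥ 0.9 (a Wald power analysis at
  effect 4×, dispersion 0.1, n = 20/20 gives z ≈ 13, so ≥ 0.9 is
  conservative); noiseless deconvolution error < 1e-6 and noisy MAE < 0.05.

**A known bias worth stating**: when a large fraction of the genome truly
changes between conditions (e.g. one third of all genes are markers of a
shrinking type), median-of-ratios size factors no longer estimate pure
library depth — the ratio median lands between the background and marker
blocks, compressing estimated `PC` toward 1 by a few percent. This is a
property of global-scaling normalization itself, not of the PC estimator; it
is visible in the acceptance simulations (PC ≈ 0.46 vs. true 0.40 in an
extreme 1000-of-3000-genes design) and does not push the calibrated type-I
error outside its band.

## 9. Numerical choices

- All randomness flows from integer seeds through `numpy.random.default_rng`;
  the pipeline derives stage seeds from one master seed via `SeedSequence`
  spawning (children reduced mod 2³¹ where an integer seed is required), so
  reruns are bit-identical.
- Dispersion floor 1e-8; Newton steps on `log q` clipped to ±5; fold-change
  pseudocount 1e-9 only in the marker fold-change criterion (the PC
  estimator instead *excludes* undefined fold changes and reports how many).
- BH adjustment families are always explicit: within a one-vs-rest marker
  comparison, within a cell type's ctDEG candidates, across cell types for
  proportion t-tests.
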