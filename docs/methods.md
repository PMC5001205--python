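# Methods

## Variance model

The package assumes each gene's counts across a homogeneous cell population
follow a negative binomial whose size parameter r is shared by all genes
(invariant to expression level), giving σ² = μ + αμ² with dispersion
α = 1/r, extended by a multiplicative technical-noise factor β to

    σ² = βμ + αμ²,   log₁₀(CV) = ½ log₁₀(β/μ + α).

Assumptions worth keeping in mind: α and β are population-level constants
(no per-gene dispersion); genes are independent; the model is written for
molecule-level (UMI) counts, where amplification duplicates have been
removed. α = 0 with β = 1 is exactly Poisson; β < 1 is permitted
numerically but means sub-Poisson counts, which UMI data do not normally
show. The NB (size, prob) pair implied by a mean μ is
size = μ/(β−1+αμ), prob = 1/(β+αμ). The older convention writing
σ² = μ/(1−p) swaps the role of p; the package sidesteps the clash by
treating (mean, variance) as primary and exposing (size, prob) in the
prob = μ/σ² convention. Whenever βμ + αμ² ≤ μ the NB size would be
undefined or negative, so sampling and theory fall back to Poisson(μ) —
the α → 0 limit.

## Estimation cascade

1. **Robust local regression.** Per-gene means and CVs (SD with the n−1
   denominator) are computed across cells; genes with zero mean or zero CV
   are excluded from curve fitting. The (log₁₀ μ, log₁₀ CV) cloud is
   smoothed by locally weighted polynomial regression on a uniform grid
   (step 0.005 in log₁₀ μ): tricube kernel over a nearest-neighbour span of
   0.3, local degree 2, and four robustness iterations that bisquare-weight
   residuals scaled by six times their median absolute value. Degree 2 is
   the default of the classical local-regression implementations and avoids
   the boundary bias a local-linear fit shows where the curve flattens at
   high expression (local-linear underestimates the plateau by ~0.02 in α
   terms); both degree and span are parameters.
2. **Support.** The curve is only trusted where data are dense: the start
   is the smallest grid position with more than 0.5 % of genes within
   ±0.05 log₁₀ μ, and the curve is cut at its minimum-CV position (leftmost
   minimiser on plateaus), treating everything beyond as flat. The ±0.05
   window equals five subsampling intervals per side.
3. **Subsampling.** The curve is resampled every 0.01 log₁₀ μ from start to
   terminal (inclusive), so each part of the support contributes equally to
   the parametric fit regardless of gene density.
4. **Nonlinear least squares.** (α, β) minimise the squared residuals of
   ½ log₁₀(β/μ + α) over the subsampled points, with α ≥ 0, β > 0.
   Initial values come from the curve's two asymptotes — CV² ≈ β/μ at the
   left end, CV² ≈ α at the right end — and up to three random-restart
   perturbations are tried on non-convergence, after which a fit error
   carrying the best parameters so far is raised. The comparison noise
   model log₁₀(μ^γ + δ) is fitted to the same points; note it cannot
   represent a *scaled* power law c·μ^γ (its only offset is additive in CV),
   which is why it fits poorly whenever β > 1.

## CV difference and significance

D is the signed orthogonal distance from a gene's point to the model curve
in the (log₁₀ μ, log₁₀ CV) plane — "shortest distance" taken literally;
a vertical-offset variant is available via `method="vertical"` for
sensitivity checks. With α = 0 the curve is a straight line and the
analytic point-to-line formula is used; otherwise the distance is minimised
over a dense parameterisation of the curve (step 5·10⁻⁴, spanning one
decade beyond the fitted support each side) with a parabolic refinement of
the grid minimiser; agreement with an independent bounded 1-D minimisation
is tested to 10⁻⁴.

The null for D is Normal(centre, sd): the centre is the mode of a Gaussian
KDE of D (Silverman bandwidth, 512-point grid spanning the data range;
leftmost mode on ties, with a warning), and sd² is the mean of (D−centre)²
over D ≤ centre — a moment fit of the reflected left half, the side not
contaminated by variable genes. Moment matching was chosen over maximum
likelihood for the half-sample because it is explicit and directly
testable. P-values are the upper tail only (low-variability genes are never
called), adjusted by Benjamini–Hochberg; the default call threshold is
FDR < 0.05 for simulation work and 0.001 is conventional for large real
data sets.

Preprocessing applies, in order, the scaling normalization
k̂ᵢⱼ = kᵢⱼ·K̄/Kⱼ (skippable for simulated data, which has no library-size
effect) and removal of genes expressed (count > 0) in fewer than
ceil(0.01·n_cells) cells. Normalization preserves the grand total exactly
and the two steps commute, since scaling cells cannot change which entries
are nonzero.

## Simulator

The generator composes: (1) a master profile Mᵢ ~ Exponential(mean m);
(2) a heterogeneous subpopulation — a fixed-size uniform subset of
round(prct·n_genes) genes receives log₂FC ~ Normal(0, s), one fold change
per gene shared by all heterogeneous cells, and each cell is independently
heterogeneous with probability 1 − 0.9; (3) Gaussian jitter
Normal(loc, max(0.2, 0.2·loc)) truncated at zero, where loc is Mᵢ or
Mᵢ·2^{log₂FCᵢ} in a heterogeneous cell (the SD is recomputed from the
shifted location, keeping the jitter CV constant); (4) NB counts at the
resulting means under σ² = βμ + αμ², with Poisson fallback and zero means
giving zero counts. Negative Gaussian draws are clipped to zero because
expression means are nonnegative; with the 0.2 SD floor this deliberately
produces exact-zero means (hence structural zero counts) for near-silent
genes.

**Jitter granularity.** `jitter_mode` selects where the Gaussian jitter
enters. In `"cell"` mode every (gene, cell) mean is an independent draw;
this adds the jitter variance on top of the model variance — a 20 % extra
CV for well-expressed genes — so the data's true CV–mean locus sits
visibly above the (α, β) curve that generated the counts, and parameter
"recovery" against the generating values is structurally biased
(α̂ ≈ α + 0.04(1+α) for large means). In `"gene"` mode (the default) the
jitter is drawn once per gene, modelling biological variation of the
baseline profile itself: every gene's cross-cell counts then follow the NB
model exactly at its own jittered mean, the cloud sits on the model curve,
and recovery studies are well-posed. The validation studies in the test
suite use `"gene"` mode for this reason; `"cell"` mode is retained for
stress-testing the cascade against model misspecification.

**Study conditions.** The replicate studies (and `scripts/acceptance.py`)
use 15,000 genes × 1,000 cells, prct = 10 %, s = 2, five replicates, and a
master mean of 10 — the high end of the exponential means considered
(0.25, 1, 10), chosen so the fitted support spans roughly three decades
(up to μ ≈ 100) and the high-expression asymptote that identifies α is
actually reached; with a unit master mean the support ends near μ = 10 and
VEG detection is power-starved at realistic fold changes. The class default
of `SimConfig` stays at master mean 1.0, which matches the per-gene UMI
scale of typical real data sets.

What the generator does *not* emulate: library-size variation between
cells (hence normalization is a no-op on simulated data), gene–gene
correlation, batch effects, and zero inflation beyond what NB at low means
produces. Passing recovery tests therefore show the cascade is correct
under the model's own assumptions, not that real data satisfy them.

## Evaluation

`model_rmse` compares two log₁₀-CV curves on a log₁₀-mean grid at 0.01
spacing; the study driver evaluates both the fitted variation model and the
fitted noise model against the generating model over the fitted support
[start, terminal]. `run_condition` derives replicate seeds
deterministically from a base seed, records failed replicates instead of
dropping them, and aggregates mean ± SD of α̂, β̂, both RMSEs and (optionally)
VEG counts. "Altered by at least two-fold" means |log₂FC| ≥ 1 on the
ground-truth fold changes of genes actually selected for alteration; its
expectation is round(prct·n_genes)·2·(1−Φ(1/s)) — ≈ 926 genes at
prct = 10 %, s = 2, 15,000 genes.

In five-replicate runs at these conditions the cascade recovers every
(α, β) in {0, 0.15, 0.5} × {1, 1.2, 1.5} to within ≈ 0.02 of the generating
values with model-curve RMSE ≤ 0.02 (typically ≤ 0.005), the noise model's
RMSE exceeds the variation model's in every β > 1 condition, α̂ rises with
the altered fraction at fixed s while β̂ stays within 1.2 ± 0.02, and β̂
declines as the population shrinks 500 → 100 → 50 cells (small-sample CV
underestimation). In the ideal Poisson condition every VEG called at
FDR < 0.05 is a ground-truth altered gene (observed false discovery
fraction ≈ 0 in spot checks).

## Numerical choices and limitations

- All CV–mean work is in base-10 logarithms; the subsampling interval, the
  density window and the RMSE grid all live on that scale.
- Ill-conditioned local windows (e.g. many duplicated abscissae) fall back
  from quadratic to linear to a weighted mean rather than failing.
- `estimate_null` requires ≥ 100 finite D values and errors on constant
  input (the null SD would be zero).
- Fewer than two cells is an error (CV undefined); fewer than ~50 usable
  genes is a fit error; degenerate clouds (all means equal) are fit errors.
- β is not identifiable below the support's left end: if filtering removes
  all low-expression genes, β̂ absorbs whatever the curve shows at the
  remaining left boundary.
- The method is population-level by design: it provides no per-gene
  dispersion estimates, no confidence intervals on (α, β), and no
  correction for gene–gene correlation.
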