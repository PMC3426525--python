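# Methods

## Data model

A *field* is one microscope image of a well, summarized by a descriptor
vector `x ∈ R^D`: total cell count plus proportions of cells in S, G2,
M and apoptotic states (`D = 5` by default).  Proportions are not
constrained to sum to one — a cell can be counted in more than one
state.  A *well* groups `K` fields (4 on the plates this package
emulates; any `K ≥ 1` is accepted since the well density is a plain
product over fields).  On load, proportions are clipped to
`[1e-6, 1 − 1e-6]` and zero counts replaced by 0.5 so that the beta and
gamma class densities are finite; a proportion outside `[0, 1]` by more
than `1e-6` is rejected as a data error rather than repaired.  The
G0/G1 proportion is derived as `1 − (S + G2 + M)`, clipped to `[0, 1]`,
and used only in association reporting, never as a model descriptor.
The apoptotic proportion does not enter this derivation: the cycle
phases partition the cycle, viability is a separate axis; because
states are non-exclusive the derivation is an approximation either way,
and the phases-only reading is the one adopted.

## The hierarchical mixture

Wells are i.i.d.; each well draws a latent population-phenotype class
`Z_i ~ Multinomial(π)` over `C` classes, and conditional on `Z_i` its
fields are i.i.d. from the class density.  The well density and dataset
likelihood are

    p(W_i) = Σ_c π_c Π_k f(x_ik | θ_c),        ℓ(θ) = Σ_i log p(W_i),

evaluated throughout in log space with log-sum-exp.  A zero mixture
weight contributes `−∞` to the log-sum-exp, not an error.

Three class parametrizations share this structure:

- **copula** — Gaussian copula with correlation matrix `R` and
  parametric marginals: gamma(shape, rate) for the count, beta(a, b)
  for each proportion.  Support matches the data exactly, and the free
  parameter count `D(D−1)/2 + 2D` equals the full Gaussian's
  `D + D(D+1)/2` (both 20 at `D = 5`).
- **gaussian_full** — multivariate normal with full covariance, same
  hierarchy.
- **baseline_diag** — the deliberately impoverished reference: a flat
  Gaussian mixture over *fields* with diagonal covariances.  It ignores
  both the dependence structure and the well grouping; for comparisons
  its per-well score is the sum of its fields' mixture log-densities.
  With `K = 1` the hierarchical and flat readings coincide exactly.

## Copula estimation

Density evaluation always uses the parametric marginal CDFs, so the
mixture likelihood is a proper density.  Rank-based pseudo-observations
enter only the estimation of `R` (the semi-parametric split: parametric
marginals are what is fitted and reported; the copula parameter comes
from the pseudo-likelihood, whose Gaussian-copula maximizer is closed
form — the Pearson correlation of the normal scores — avoiding the
numerical optimization exact joint ML would need).

Weighted pseudo-observations use a mid-point weighted empirical CDF,
`u_i = S_i / (Σw + w̄)` with `S_i` the weight strictly below `x_i` plus
half the tied weight, and `w̄ = Σw²/Σw` the weighted mean weight.  This
reduces to `(rank − ½)/(n + 1)` under uniform weights, is tie-safe, and
makes one-hot weights reproduce the subset estimate exactly — the
property the EM M-step relies on.  Unweighted calls use the classical
`rank/(n + 1)` with average ranks.  Estimated correlations are clipped
to `±(1 − 1e-6)`, the diagonal reset to 1, and repaired to the nearest
positive-definite correlation matrix (eigenvalue floor `1e-6`, via the
alternating-projection nearest-correlation routine) when needed.

Weighted marginal fits start from weighted method-of-moments (with a
`1e-8` variance floor on degenerate input, plus a warning) and are
refined by at most 50 Newton steps on the weighted log-likelihood
sufficient-statistic equations — the scalar `log α − ψ(α)` equation for
the gamma shape, the two-dimensional digamma system for beta — falling
back to the moment estimate if Newton leaves the parameter space.

## EM learning

Initialization is seeded k-means on per-well mean descriptor vectors
(z-scored), pushed through one M-step, with `π` smoothed by 10% uniform
mass; a degenerate clustering is redrawn up to five times.  The E-step
computes per-well (per-field for the baseline) responsibilities by
Bayes' rule in log space; a row with zero density under every class
gets a uniform row and a warning.  The M-step is weighted maximum
likelihood per class, with fields inheriting their well's
responsibility as weight.  Convergence is declared when the relative
log-likelihood change drops below `1e-6` (500 iterations maximum;
cross-validation uses 300 as its desk-scale default).

For the Gaussian parametrizations this is exact EM and the likelihood
trajectory is non-decreasing.  The copula M-step (semi-parametric `R` +
weighted marginal ML) is a generalized-EM approximation: monotonicity
is not guaranteed, so the loop tracks the best-seen iterate and returns
it, appending its likelihood as the final trajectory entry when it is
not the last.  A class whose responsibility mass falls below `10⁻³·n`
is reseeded once from the worst-fitting well; on a second collapse it
is dropped and `π` renormalized, so `C` acts as an upper bound.
Covariances get an eigenvalue floor of `1e-8` by jitter.  All
randomness flows from one integer seed through `SeedSequence`-based
child seeds keyed by (seed, repeat, fold, restart).

## Model selection

k-fold cross-validation splits *wells* (never fields): per repeat a
seeded permutation is cut into folds of near-equal size (the full-scale
protocol is 5 folds, 5 restarts, `C` from 2 to 20, 10 repeats; reduced
grids are used at desk scale).  Within each fold the restart with the
highest *training* likelihood is kept — selecting by test likelihood
would leak — and its held-out log-likelihood recorded.  Held-out copula
densities use the trained parametric marginals and `R`; nothing is
re-ranked on test data.  The selected `C` maximizes the mean over
repeats of the summed test log-likelihood ("highest test likelihood",
summarized by the mean over splits as the stable statistic); exact ties
go to the smallest `C`.  The final model refits the selected `C` on all
wells with 10 restarts.

## Downstream analyses

*Novelty detection.*  Wells are scored by their log density under a
model fitted to negative controls; sorting ascending puts the most
atypical populations first.  MAP class and full posterior come from the
E-step (for the flat baseline, the well posterior is the average of its
fields' responsibilities).

*Small-class outliers.*  Classes whose MAP membership falls strictly
below `min_fraction · n` (default 5% — real screens have shown outlier
classes in the 1.5–3% range, comfortably under this cutoff) are
flagged with their member wells for inspection.

*Dispersion.*  The multivariate dispersion of `m` points is
`(1/m) Σ_{i<j} ‖p_i − p_j‖²`, computed through the identical
centroid form `Σ_i ‖p_i − p̄‖²`; the package compares each well's own
fields against seeded random field groups of the modal `K`, sampled
without replacement, on z-scored descriptors.

*Association.*  Field-level Spearman rho (average ranks) of each
descriptor — including derived G0/G1 — against cell count, with the
two-sided p-value from the asymptotic t approximation
`t = ρ√((n−2)/(1−ρ²))` on `n − 2` degrees of freedom; `|ρ| = 1` reports
the smallest positive float, constants report a missing value with a
reason.  P-values are raw; no multiplicity correction is applied.

## Synthetic scenarios

The generator implements the model's own two-step process (class, then
fields; copula classes through `z ~ N(0, R)`, `u = Φ(z)`,
`x_d = F_d⁻¹(u_d)`).  The frozen presets in `presets/presets.yaml`
emulate a two-condition screen at 336 wells × 4 fields per condition:

- `negative_like` — three copula classes whose across-class structure
  and shared within-class correlation reproduce the qualitative
  association pattern of real negative controls (count↔G2 positive,
  count↔M negative, S flat), with skewed beta marginals for the rare
  states.  Class count means (2000/1200/600) sit ≥ 2 sd apart.
- `positive_contrast` — the cell-death control: each class's count
  mean divided by 5 (rate × 5) and apoptotic mean multiplied by 5.
- `paper_layout` — both conditions at full layout (672 wells, 2688
  fields).
- `with_outliers` — negative-like with 5% of wells (floor, so the
  injected class stays strictly below the 5% flag cutoff) drawn from a
  separated "imaging artifact" class.

These presets emulate the statistical structure the model assumes —
class-dependent marginal shapes, inter-descriptor correlation,
within-well coherence.  They do not emulate plate-position effects,
batch drift, heteroscedastic segmentation error or misspecified
marginal families, so passing recovery tests demonstrates correctness
of the estimators under the model's assumptions, not robustness of the
model on arbitrary real screens.  Gaussian-truth sampling clips into
the descriptor supports, slightly truncating tails.

## Problem sizes and numerical choices

Study-scale checks run at desk scale by design: EM soundness over 20
seeds × 3 datasets of 80 wells; recovery at 500 wells × 4 fields;
model ordering and class-number recovery on reduced CV grids
(`C ∈ {2,3,4}`, 3 folds, 2 restarts, 200 wells, 10 replicates);
Monte-Carlo normalization at 10⁵ importance samples.  Tolerances:
copula/multivariate-normal identity `1e-10`, dispersion-form identity
`1e-10`, EM monotonicity slack `1e-8` relative, CDF clipping `1e-12`.

## Known limitations

- The copula M-step is approximate; likelihood can dip between
  iterations (best iterate returned).  This mirrors the general
  trade-off that copula fitting is slower and approximation-bound
  compared to the closed-form Gaussian sufficient statistics.
- Marginal families are fixed (gamma count, beta proportions); no
  goodness-of-fit escape hatch if a descriptor violates them.
- Class labels are arbitrary (label switching across seeds); analyses
  that need aligned classes must match them, e.g. by marginal means.
- No cell-level latent layer: phenotypes are defined at the population
  level only.
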