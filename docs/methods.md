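# Methods

## Model

The package treats a dataset as `n` independent observations `x_i` of one
underlying quantity, each optionally carrying a reported 1-sigma
uncertainty `u_i`.  No distributional form is assumed for the scatter of
the `x_i`; the central estimate is Steiner's most frequent value (MFV), the
location `M_n` of the Cauchy density that minimises the Kullback–Leibler
divergence from the empirical distribution, together with its scale, the
dihesion `ε_n`.  Both are defined implicitly:

    M_n  = Σ x_i w_i / Σ w_i,          w_i = 1/(ε_n² + (x_i − M_n)²)
    ε_n² = 3 Σ (x_i − M_n)² w_i² / Σ w_i²

Because each equation involves the other's current value, the pair is
solved by fixed-point iteration.  The estimator is affinely equivariant
(`MFV(a·x+b) = a·MFV(x)+b`, `ε(a·x+b) = |a|·ε(x)`), bounded by the data
range (all weights are positive), resistant to outliers (weights decay as
the squared distance from the location), and consistent for heavy-tailed
data including the Cauchy law itself.

## Solver numerics

* **Update scheme.** Pure Jacobi: sweep `k+1` evaluates both the new
  location and the new squared dihesion from the sweep-`k` pair.  A
  Gauss–Seidel variant (scale update using the fresh location) shares the
  same fixed points; Jacobi is retained as the package's defined iteration.
* **Initialisation.** `M⁰` = arithmetic mean (default) or median;
  `ε⁰ = (√3/2)·(x_max − x_min)`.  The fixed-point system can admit several
  solutions (e.g. `{0,1,2}` has dihesion roots 1/3 and 1), so the
  initialisation is part of the estimator's definition and is echoed in the
  result metadata.  A regression test pins that replacing the range factor
  by 3/2 converges to the identical point on all packaged datasets.
* **Convergence.** Both parameters must move by less than
  `tol·max(1, |·|)` between sweeps (`tol = 1e-10` by default); the hybrid
  relative-plus-absolute form behaves the same for data in millibarn or in
  years.  The scalar solver then *polishes*: it keeps iterating until the
  fixed-point residuals themselves satisfy the tolerance, so a returned
  estimate is a verified fixed point, not a stalled iterate.
* **Degeneracy.** Samples of size one or with all values equal return that
  value with dihesion 0, flagged `degenerate`.  If the dihesion collapses
  below `1e-12 ×` the data range on heterogeneous data (possible when the
  densest "cluster" is a set of near-identical values), the solver flags
  the result degenerate rather than dividing by a vanishing weight
  denominator.  Degenerate results never raise: bootstrap resamples
  routinely collapse and must not abort a run.  Exhausting the sweep cap
  (10,000) raises a convergence error carrying the last iterate.
* **Batch solving.** The bootstrap solves all `B` replicates
  simultaneously as rows of a `(B, n)` array, freezing converged rows
  between vectorised sweeps; this is what makes `B = 10⁵` replicates cost
  seconds rather than minutes on one core.

## Hybrid parametric bootstrap

Each replicate resamples the `n` `(value, uncertainty)` rows with
replacement, then replaces every selected row by one draw from
`Normal(value, uncertainty)`; draws at or below the physical lower bound
(default 0; the bound is exclusive, zero being as unphysical as a negative
cross-section) are discarded and redrawn.  Each duplicate of a row in a
resample receives its own independent Gaussian draw.  The two layers
capture, respectively, uncertainty about which measurements represent the
population and each measurement's own stated error; with all uncertainties
zero the procedure reduces exactly to the ordinary non-parametric
bootstrap.

* **RNG.** One PCG64 stream per run, consumed in a fixed order: the whole
  `B × n` index block, then the `B × n` Gaussian block, then whole-array
  redraw sweeps over the out-of-bound cells.  This order makes runs
  bit-reproducible given the seed and preserves the zero-noise equivalence
  with the non-parametric engine (the index block comes first in both).
  A redraw sweep cap (default 1000) turns a hopeless bound — a mean far
  below it — into an error naming the offending row.
* **Intervals.** Equal-tail percentile intervals: quantile probabilities
  are computed exactly from the level (`(1−0.6827)/2 = 0.15865`), and
  quantiles use linear interpolation between order statistics
  (Hyndman–Fan type 7, numpy's default).  The interpolation rule matters at
  well below 1 mb for `B ≥ 10⁵` and is fixed for reproducibility.
* **Diagnostics.** With origin tracking on, every simulated draw is tagged
  with its source row.  Per origin, the sample mean and standard deviation
  of the tagged draws are compared with the reported `value ± uncertainty`
  as absolute percent differences.  Sample moments are used rather than a
  histogram curve fit because at ~10⁵ draws the two agree far inside the
  diagnostic band and moments are deterministic given the draws; a binned
  least-squares Gaussian fit is available behind a flag for figure parity.
  The one expected systematic is truncation bias: for an origin like
  670 ± 266 mb with a positivity bound, rejection of the ~0.6% negative
  tail shifts the simulated mean up by `σ·φ(α)/(1−Φ(α)) ≈ 4.5` mb — small
  against the 266 mb uncertainty.

## Packaged datasets and reference values

The packaged tables are the 31 published ¹⁰⁹Ag(n,2n)¹⁰⁸ᵐAg cross-section
values at 14.7 ± 0.2 MeV, the 11 re-evaluation pairs updating them to the
modern ¹⁰⁸ᵐAg half-life, and the five published ¹⁰⁸ᵐAg half-life values
(the early lower-limit estimate excluded).  Re-evaluation merging matches
on all three printed fields (energy, value, uncertainty) exactly; this is
the only rule that reproduces the published summary statistics of the
merged table (mean 718, weighted mean 728 mb), because one pair cites an
original uncertainty (721 ± 18) that the table prints as 721 ± 20 and must
remain unreplaced.  Ten of the eleven pairs apply.

Reference checks reproduced by the test suite and the `reproduce` command:
MFV 685 / mean 638 / weighted mean 399 mb (original table); 709 / 718 /
728 mb (merged); half-life MFVs 433.5 y (five values) and 439.1 y (three);
all four half-life HPB intervals to within 1.5 y; per-origin deviations
below 0.5%.

**A note on the cross-section intervals.**  The stated-level percentile
intervals computed here for the two cross-section tables are systematically
narrower than the published reference intervals: at B = 10⁵ the merged
table gives a 68.27% interval near [697, 738] mb against a published
[691, 744] mb.  Investigating the discrepancy shows that the published
cross-section bounds coincide, to within Monte-Carlo noise, with the
10%/90% quantiles of the very same bootstrap distribution computed here
(and the published "2-sigma" bounds with its 0.5%/99.5% quantiles) — eight
bounds across the two tables agree to ≲1.6 mb — while the published
half-life intervals match this package's stated-level quantiles exactly.
The package therefore keeps the percentile rule at the stated level
everywhere; the distribution-level agreement is asserted in the test suite,
and the `reproduce` command honestly reports the cross-section interval
rows as failing at the stated levels.  Alternative procedural explanations
(shared draws for duplicated resampled rows, double perturbation,
distinct-origin resampling, initialisation or tolerance variations) were
tested and reproduce neither set of bounds.

## Synthetic data

Three generators cover the regimes the method targets, all returning the
same table type as real data and deterministic given their seed:

* `contaminated_gaussian` — `(1−f)·N(μ, σ) + f·N(μ+Δ, σ)`: the classic
  outlier-contamination model; used to demonstrate that the MFV stays
  within estimator noise of `μ` while the mean shifts by `≈ f·Δ`.
  Uncertainties are set to `σ` as a placeholder.
* `cauchy` — `μ + σ·Cauchy`: heavy tails with no finite mean, for
  consistency tests of the location estimate (unit placeholder
  uncertainties, since a Cauchy law has no 1-sigma).
* `heteroscedastic_table` — `u_i ~ Uniform(range)`, `x_i ~ N(μ, u_i)`: a
  measurement table of one quantity reported at varying precision, the
  structure the HPB explicitly models.

These are statistical stand-ins: they emulate outlier contamination, heavy
tails and heteroscedastic noise, but not real measurement systematics
(energy dependence, detector efficiency, correlated corrections).  Passing
the synthetic suites therefore demonstrates the estimator's statistical
properties, not the correctness of any particular physical evaluation.

## Problem sizes and defaults

Bootstrap defaults are B = 100,000 replicates in the test suite and the
acceptance script — enough to pin 68.27% bounds to a seed-to-seed spread
under 1 mb on the cross-section tables — and B = 500,000 for the
`reproduce` command, matching the published runs.  Stochastic CLI commands
require an explicit `--seed` (or an explicit `--no-seed`), and every JSON
result embeds `{seed, replicates, method}` so any run can be replayed
bit-exactly.

## Known limitations

* The MFV presumes the densest cluster is the truth; if most of a dataset
  is biased, the estimate follows the bias.  Multimodal data are summarised
  by whichever mode the initialisation's basin selects — the initialisation
  is reported, but no mode-by-mode analysis is attempted.
* The dihesion is validated through its fixed-point and equivariance
  properties, not against published values (none are available for these
  datasets).
* Bootstrap intervals are percentile intervals; no BCa or studentised
  corrections, and no parallel execution beyond the single-stream
  determinism contract.
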