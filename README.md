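# mfvboot

Robust combination of repeated measurements with the **most frequent value
(MFV)** estimator and **hybrid parametric bootstrap (HPB)** confidence
intervals.

## The problem

When several laboratories measure the same physical quantity — a nuclear
reaction cross-section, an isomer half-life, an enzymatic rate, a biomarker
concentration — the resulting table of `value ± uncertainty` entries is
typically small, heteroscedastic, and contaminated by outliers or stale
systematic corrections.  The two conventional summaries both fail in
characteristic ways: the arithmetic mean is dragged by extreme values, and
the inverse-variance weighted mean is dominated by whichever entry claims
the smallest uncertainty, whether or not that claim is trustworthy.

## The estimator

The MFV `M_n` of a sample `x_1, …, x_n` is the fixed point of a
Cauchy-weighted average, solved jointly with its companion scale parameter,
the *dihesion* `ε_n`:

```
M_n  =  Σᵢ xᵢ wᵢ / Σᵢ wᵢ ,              wᵢ = 1 / (ε_n² + (xᵢ − M_n)²)
ε_n² =  3 Σᵢ (xᵢ − M_n)² wᵢ² / Σᵢ wᵢ²
```

`(M_n, ε_n)` are the location and half-width of the Cauchy density that
minimises the Kullback–Leibler divergence from the empirical distribution.
The Cauchy weights decay quadratically with distance from the current
location, so the estimate settles on the densest cluster of the data and is
nearly indifferent to outliers; it remains consistent even for
Cauchy-distributed data, where the mean has no finite variance.  The pair is
computed by Jacobi fixed-point iteration from the arithmetic mean and
`√3/2 ×` the data range (median initialisation is available for extreme
cases).

Uncertainty is quantified by the hybrid parametric bootstrap: each of `B`
replicates (1) resamples the `n` `(value, uncertainty)` rows with
replacement, (2) replaces every selected row by a draw from
`Normal(value, uncertainty)`, redrawing any draw at or below the physical
lower bound (0 for cross-sections and half-lives), and (3) records the MFV
of the simulated sample.  Equal-tail percentile intervals of the `B`
replicate MFVs — quantiles at `(1−L)/2` and `1−(1−L)/2` — give the
confidence interval at level `L`.

## Worked example

The packaged dataset `ag108m_xs_original` holds the 31 published
measurements of the ¹⁰⁹Ag(n,2n)¹⁰⁸ᵐAg fast-neutron activation cross-section
at 14.7 ± 0.2 MeV (in millibarn, 1969–2024):

```
$ mfvboot dataset ag108m_xs_original --out table1.csv
$ mfvboot estimate table1.csv --all-estimators
{
  "mfv": 685.3781830113337,
  "dihesion": 64.83517472851074,
  "n": 31,
  "iterations": 46,
  "converged": true,
  "degenerate": false,
  "init": "mean",
  "mean": 637.741935483871,
  "weighted_mean": 398.93265196836785
}
```

The three estimators disagree wildly — 685 vs 638 vs 399 mb — because the
table mixes a modern cluster near 700 mb with a handful of low outliers
measured under an obsolete ¹⁰⁸ᵐAg half-life.  The MFV sits in the dense
cluster; the weighted mean is pulled to 399 mb by the small uncertainties
of exactly those outliers.  After merging the packaged 2024 re-evaluation
pairs (`ag108m_xs_reevaluated`), all three estimators agree to within 3%
(MFV 709, mean 718, weighted mean 728 mb).

Confidence intervals for a small dataset — the three most recent ¹⁰⁸ᵐAg
half-life measurements (418 ± 15, 437.7 ± 7.7, 448 ± 27 years):

```
$ mfvboot dataset ag108m_halflife_3 --out hl3.csv
$ mfvboot ci hl3.csv --method hybrid --replicates 100000 --seed 11 --level 0.6827
{
  "point_mfv": 439.0680830308856,
  "dihesion": 7.562519149316957,
  "levels": [
    {
      "level": 0.6827,
      "lower": 420.30745471875554,
      "upper": 445.20146688247934,
      "lower_prob": 0.15865,
      "upper_prob": 0.84135
    }
  ],
  "replicates": 100000,
  "seed": 11,
  "method": "hybrid",
  "degenerate_replicates": 108,
  "warnings": []
}
```

i.e. a half-life of 439.1 years with a 68.27% interval of
[420.3, 445.2] years — asymmetric about the point estimate, as expected
from resampling only three heteroscedastic values.  `mfvboot validate`
prints the per-origin diagnostic table showing that the simulated draws
preserve each measurement's `value ± uncertainty` to well under 0.5%, and
`mfvboot reproduce <target>` re-derives the published reference statistics
for all packaged datasets and reports pass/fail per tolerance.

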