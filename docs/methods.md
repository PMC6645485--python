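# Methods

## Data model and ANOVA

The unit of analysis is a complete `n × k` score matrix: `n ≥ 2` randomly
sampled subjects in rows, `k ≥ 2` repeated measurements (occasions, raters)
in columns, real-valued scores. Missing cells and unbalanced designs are out
of scope. The orientation is fixed; no auto-transpose is attempted.

`compute_anova` returns the full repeated-measures decomposition: SST,
SSBS/SSWS (between/within subjects), SSBM/SSWM (between/within measurements)
and SSE, with degrees of freedom `nk−1`, `n−1`, `n(k−1)`, `k−1`, `k(n−1)`,
`(n−1)(k−1)` and mean squares SS/df. SSE is accumulated directly from the
double-centred residuals `x_ij − S_i − M_j + x̄` rather than by subtracting
sums of squares, which keeps it non-negative in floating point; the
additivity identities (`SST = SSBS+SSWS = SSBM+SSWM = SSBS+SSBM+SSE`) are
then property-tested at 1e-9 relative tolerance with plain float64
summation — at the matrix sizes this package targets (tens to thousands of
rows) compensated summation is unnecessary. A constant matrix gives all
SS = 0, a legal state; every downstream ratio guards its denominator and
raises `DegenerateInputError` rather than dividing by zero.

## Estimators and the analysis recipe

The three single-score estimators ICC(1), ICC(A,1), ICC(C,1) and the
method-of-moments variance components are ratios/linear functions of the
mean squares (README). Points worth recording:

* **Negative estimates are information.** ICC(1) can reach −1/(k−1), and
  `(MSBS−MSWS)/k` can be negative by sampling accident. Both are returned
  as-is with a flag; truncating to zero would bias averages of simulated
  estimates.
* **Two-way random vs two-way mixed.** Both models yield the same sample
  formulas; the package computes one set of two-way variance components and
  the `sigma_c2` field is read as σ_c² (random biases) or θ_c² (fixed
  biases). θ_c² uses the divisor `k−1` with the bias mean subtracted, making
  everything invariant under adding a common constant to all biases — tested
  as translation invariance of the SS.
* **Bias decision.** `IccModel.fit` runs the model-agnostic recipe: the
  F-test `MSBM/MSE` on `(k−1, (n−1)(k−1))` df at `alpha` (default 0.05) is
  the deciding criterion for the `no_bias`/`bias_present` conclusion; the
  ratio ICC(C,1)/ICC(A,1) is advisory, with a configurable threshold
  defaulting to 1.02 because simulated no-bias ratios sit within a few
  tenths of a percent of 1 while even modest bias pushes the ratio percent
  upward. ICC(1) appears in reports only under `no_bias`: substituting the
  two-way expected mean squares into the one-way formula gives
  `(σ_r² − σ_c²/k)/((σ_r²+σ_c²+σ_v²) − σ_c²/k)` (`biased_icc1_expectation`),
  which estimates neither population ICC.
* **Qualitative bands** follow the common convention poor < 0.5 ≤ moderate
  ≤ 0.75 < good ≤ 0.9 < excellent. The boundary assignment (which band owns
  0.75 or 0.9 exactly) is not standardised; the closed/open choices here are
  a documented convention.

## Confidence intervals

Analytic intervals are the standard F-based formulas: for ICC(1) and
ICC(C,1), invert `F_obs = MSBS/MS_err` against `F_{1−α/2}` quantiles with
`(n−1, n(k−1))` resp. `(n−1, (n−1)(k−1))` df; for ICC(A,1), the
Satterthwaite approximation for the denominator df ν of the linear MS
combination. A sample ICC of exactly 1 yields the degenerate interval
(value, 1) with a flag. On the worked example the three intervals reproduce
the published software output to ±0.005.

Simulation-based limits invert the empirical central range. The central
range of N simulated values at level 1−α takes the order statistics of rank
`m = floor(α/2·N)` and `N−m+1` (for N = 10000 at 95%: the 250th and 9751st),
i.e. the highest of the m lowest and the lowest of the m highest values.
`build_confidence_curve` maps a grid of population ICCs ρ (default 0.00 to
0.99 in steps of 0.01) to one-way simulations with σ_r² = ρ, σ_v² = 1−ρ
(only the ratio matters), N = 10000 matrices per grid point, and records the
ICC(1) central range; the confidence interval for ρ given an observed sample
ICC is the set of ρ whose central range contains it, read off the two curves
with linear interpolation (matching a graphical reading). Curves are cached
per parameter set. Because the ICC(C,1) sampling distribution is exactly
invariant to column bias (column shifts leave SSBS and SSE unchanged), the
same curves serve observed ICC(C,1) values; they do **not** apply to
ICC(A,1), whose interval always comes from the analytic formula, including
under `ci_method="simulated"`. Near sample ICC → 1 the curves crowd
together and a 0.01 grid limits resolution; `GridResolutionError` signals an
unbracketable query.

## Monte Carlo engine

`run_simulation` draws N matrices (vectorised, shape `(N, n, k)`): one
`r_i ~ N(0, σ_r²)` per row, one `v_ij ~ N(0, σ_v²)` per cell; model 2 adds
k column biases `~ N(0, σ_c²)` redrawn per matrix; model 3 adds fixed
biases. Sampling uses numpy's PCG64 generator behind a single integer seed;
identical seed and parameters reproduce results exactly. Defaults follow
the convention μ = 100, σ_r = 10, N = 10000 — the ICC distributions depend
only on σ_v/σ_r and σ_c/σ_r, so surveys vary those ratios. Per-replicate
ICC/F/MS arrays are kept in memory (at the default sizes this is a few MB;
no streaming mode is provided).

Two averaging conventions exist and both are exposed: `mean_icc` averages
the per-replicate ICCs (the mean of the sampling distribution), while
`icc_from_mean_ms` recomputes the ICC from averaged mean squares. They
differ because the mean of a ratio is not the ratio of means; the gap is
small relative to the central-range width in the no-bias case, but becomes
material under strong bias with small k, where the per-matrix bias spread
fluctuates strongly. Expected-mean-square substitutions (such as the
invalid-ICC(1) value above, or the EMS tables used as simulation oracles)
are therefore checked against the averaged-MS form.

Degenerate replicates (vanishing ICC denominators, possible only when all
three SDs are zero) are counted, warned about and excluded; MSE = 0 alone
still gives a valid ICC of 1, with the per-replicate F-value set to
infinity.

## What the simulations do and do not show

The generator realises exactly the Gaussian, additive, homoscedastic,
balanced models the estimators assume — that is its purpose: it maps the
sampling behaviour of the estimators under their own assumptions
(distribution shapes, central ranges, bias of ICC(1) under column bias,
the narrowing of fixed-bias ICC(A,1) distributions). Passing tests
therefore validate the implementation and the internal consistency of the
theory, not robustness to real data features the models exclude:
non-normal or heteroscedastic errors, subject-by-measurement interactions
with structure beyond exchangeable noise, missing cells, drift within a
session, or categorical scores.

## Problem sizes and numerical choices

The test suite and the acceptance script use N = 10000 replicates for
distribution-level checks (matching the convention above; Monte Carlo error
on a mean ICC is then ~0.001–0.002), N ≈ 1000–4000 for coarser
power/width comparisons, and n = 500–2000 subjects for large-sample limits;
the confidence-curve grid uses 100 points × 10000 replicates. These sizes
give comfortable statistical margins for every asserted tolerance while
keeping a full run in tens of seconds. Seeds are fixed throughout the
suite; the acceptance script takes its seed on the command line.

## Known limitations

* Single-score ICCs only; the average-score forms ICC(·,k) are not
  implemented.
* No confidence intervals for the variance components themselves.
* The simulated-CI machinery is one-way/consistency only (by construction);
  ICC(A,1) intervals are always analytic.
* CSV/TSV ingestion expects a decimal point and one of comma/tab/semicolon
  as delimiter; no locale handling.
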