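# Methods

## Rank functions

Family sizes `S_r` are ranked descending, `r = 1..n_F`.  Two rank functions
are fitted:

* Zipf / inverse power law: `S_r = c / r^a`, i.e. `log S_r = log c − a log r`.
* Beta rank function: `S_r = C (n_F + 1 − r)^b / r^a`, which bends at the
  small-size end and reduces to Zipf at `b = 0`.

Intercepts are stored as log10 values because the regressions run in log10
space; the exponents `a` and `b` are invariant to the log base.  A Zipf rank
exponent maps to the exponent of the size density `f(S) ∝ S^(−α)` by
`α = 1/a + 1` (swap axes and differentiate).

### Fitting

The default route is ordinary least squares on `log10 S_r` with regressors
`log10 r` (Zipf) and additionally `log10(n_F + 1 − r)` (beta); residuals are
minimised in log scale, and all reported MSE/R² are computed in the scale in
which the regression ran.  A nonlinear route (scipy `least_squares`,
initialised from the log-log solution) minimises residuals in the linear
`S_r` scale instead; the two can give different parameters on noisy data, and
the nonlinear fit's linear-scale SSE is never worse than the log-log fit's by
construction.  Parameter standard errors come from the usual OLS covariance
`σ̂² (XᵀX)⁻¹` (not provided on the nonlinear route).

Minimum data: 3 points for Zipf, 4 for beta.  Constant data are handled where
mathematically possible (the nonlinear Zipf fit returns `a ≈ 0, c ≈ k`; a
perfect fit reports AIC/BIC of −∞ with a warning; an undefined correlation on
constant expectations is reported as NaN, never silently 0).

### Goodness of fit and model selection

MSE, SSE, Pearson correlation between observed and expected values and its
square R² are computed in the fitting scale.  The KS distance is the maximum
vertical gap between the empirical CDFs of the observed and fitted sizes,
evaluated over the union of the two supports (both CDFs are step functions,
so the supremum is attained there).

Assuming Gaussian residuals with `σ̂² = MSE`,

    AIC = n_F ln(MSE) + 2p + const,   BIC = n_F ln(MSE) + p ln(n_F) + const,

with `p = 2` (Zipf) and `p = 3` (beta).  The dropped constant is
`n_F (1 + ln 2π)`, identical across models fitted to the same data;
`ModelScore.log_lik` retains it so `−2 log L̂ + 2p` reproduces the
full-likelihood AIC exactly.  The beta-vs-Zipf comparison therefore reduces
to `ΔAIC = n_F ln(MSE_beta/MSE_zipf) + 2` and
`ΔBIC = n_F ln(MSE_beta/MSE_zipf) + ln(n_F)`; the first term is invariant to
the residual log base, since both MSEs rescale by the same factor.  Note the
ΔBIC penalty is `ln(n_F)` — the difference of `p ln n_F` for one extra
parameter — not `n_F`.

Reported MSEs use base-10 residuals.  Only MSE *ratios* are base-invariant;
absolute log-scale MSE readouts depend on this choice, which is why it is
stated here.

## Resampling p-value

A rank plot converts directly to a cumulative plot: the fitted size at rank
`r` carries cumulative probability `r/n_F` on the upper tail.  The fitted
curve (which must be positive and strictly decreasing) therefore defines a
CDF whose inverse is taken piecewise-linear between the rank grid points and
clamped to the endpoint sizes outside the grid.

Each replicate draws `n_F` uniforms, maps them through the inverse CDF,
rounds half-up to integers, and discards values below the observed data's
minimum size (redrawing until `n_F` are retained; an acceptance rate below 1%
aborts as a degenerate CDF).  The replicate is re-ranked, refitted with the
same function family, and the KS distance between the replicate and its own
fit recorded.  The empirical p-value is the proportion of replicate distances
**at least as large as** the observed one — ties (within 1e−12) count toward
p, the conservative rule; the larger/equal counts are reported separately so
the strict variant is recoverable.  Replicates whose refit fails are dropped
and counted; more than 5% failures aborts.

Per-replicate RNG substreams are seeded by `(seed, replicate index)`
(numpy `default_rng` with a seed sequence), so results are bit-reproducible,
independent of execution order, and the first k replicates of a longer run
equal those of a shorter one.

## Split–merge dynamics

State: a multiset of set sizes.  Per round, (i) each of the `split_top_k`
largest sets (default 1) is replaced by two parts whose sizes sum to the
original, the split point uniform on `{min_part, …, S − min_part}`
(default `min_part = 1`, so singleton sets are legal — curated collections
contain size-1 sets); (ii) `m = floor(merge_fraction · n)` rounded down to
even sets (default fraction 0.06, of the *current*, post-split count) are
chosen uniformly without replacement, paired at random, and each pair
replaced by one set of the summed size.  Any set may be merged — a size
threshold would introduce a discontinuity into the distribution — including
sets created earlier in the same round.  Splitting precedes merging by
default (configurable), so a set merged this round is not immediately
re-split.

Total gene count is conserved exactly; the set count evolves as
`n_{t+1} = n_t + k_t − m_t/2`, and both `k_t` and `m_t` are recorded per
round so the bookkeeping can be audited.  Snapshots are kept at round 0,
every `snapshot_every` rounds (default 10) and the final round (default
100).  If the set count would fall below 4 (too few points to fit a beta
function) the run halts with a partial trajectory and status `"halted"`.

With the defaults the set count contracts by ≈3% per round, so a run from
n≈3500 ends near n≈200 after 100 rounds.  Started from a Zipf state in the
paralogue-like regime (a ≈ 0.39, smallest sizes 2), the final-round beta fit
robustly shows `b > a` — the splitting of the largest sets flattens the head
while merging fattens the mid-ranks.

## Synthetic data

Rank-model generators evaluate the Zipf/beta curve at ranks `1..n` and
optionally multiply by `10^(σZ)` noise, `Z ~ N(0,1)`: `noise_sd` is the sd of
the noise on `log10 S`, so a log-log regression residual sd estimates it
directly.  Alternative i.i.d. generators (uniform, absolute normal,
lognormal, chi-square) provide other initial conditions for the simulator.
All generators round half-up to integers (sizes are counts; disable with
`integerize=False` for exact-recovery checks) and floor at `min_size`.

`paralogue_like_spec()` is the default fixture regime: Zipf with `a = 0.39`,
`n = 3586`, smallest sizes ≈ 2 — the shape and scale of the human Ensembl
paralogue collection (whose rank-plot fit gives a ≈ 0.389 with the single
dominant zinc-finger family of 225 genes excluded).  What the generators do
*not* emulate: the integer-valued, heavily tied small-size bins of real
collections arise here only through rounding; multi-membership of genes
across families is invisible to a size vector; and real curated databases
drift between releases.  Passing tests on synthetic data therefore
demonstrate correctness of the machinery and calibration under the stated
noise model, not agreement with any particular database snapshot.

### A note on re-ranking noisy data

If noise is applied to a monotone rank curve and the values are then
re-sorted before refitting, the slope estimate acquires a small upward bias
(sorting stretches the extremes); at `noise_sd = 0.05`, `n = 500` the bias is
≈0.02 — small in absolute terms but an order of magnitude larger than the
nominal standard error.  Parameter-recovery checks therefore fit at the known
generation ranks (`fit_rank_curve_loglog`); the re-ranked pipeline is checked
for exact recovery in the noiseless limit, where the ordering is unchanged.

## Data readers

Column names for the Ensembl BioMart export and the HGNC family download are
arguments with sensible defaults, because dialects drift across releases.
The HGNC curation filters drop rows whose status is not approved, locus types
naming RNA classes, and (unless requested) pseudo-genes, detected by
"pseudogene" appearing in the locus-type or status text (case-insensitive).
The filters commute.  Gene labels are case-sensitive exact strings; no alias
resolution is attempted.  Size-1 families are retained by the readers —
minimum-size filtering (default 2: a family needs at least two members to be
a family) belongs to the ranking step, where it is explicit and logged.

## Problem sizes used in the test suite

Stochastic checks run at desk scale: p-value calibration uses n = 300 sizes,
200 replicates and 20 seeds per condition (null Zipf-on-Zipf median p > 0.2;
bent beta data, b = 0.8, tested against Zipf, median p < 0.05); the
split–merge emergent-shape check runs 20 seeded 100-round trajectories from
n = 3500.  These sizes make the suite fast while leaving the calibration
contrast unambiguous (observed medians ≈ 0.47 vs 0.0).

## Known limitations

* Discrete maximum-likelihood power-law estimation (Clauset-style) is out of
  scope; all fits are regressions, as is standard for rank-function work.
* The split-point law of the split operation is uniform; binomial halving
  (each gene assigned to a part by coin flip) is a plausible alternative that
  is not implemented.
* Closed-form KS p-values are not provided; the resampling route is the
  method.
* Real 2016-era Ensembl/HGNC snapshots are not recoverable, so
  dataset-specific fit values quoted anywhere are illustrative, never
  asserted by tests.
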