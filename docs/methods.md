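# Methods

## The growth-and-decline curve

Flow-cytometric counts of a batch culture rise roughly exponentially,
peak once nutrients or light become limiting, and then decline.  We
model the natural-log count directly with the Churchill/Usagi blending
form

    ln N(t) = [ (1/K1) e^(−λ1 t) + (1/K2) e^(λ2 t) ]^(−1),   t in hours.

The two terms are reciprocal asymptotes: early on the first term
dominates and ln N ≈ K1 e^(λ1 t) (exponential approach of the log count
to its rising branch); late the second dominates and ln N ≈ K2 e^(−λ2 t).
The blend is unimodal with a single interior maximum at

    t* = ln(λ1 K2 / (λ2 K1)) / (λ1 + λ2)

(obtained by setting the derivative of the two-term denominator to
zero; t* < 0 means the decline term already dominates at inoculation and
the curve is monotone decreasing on t ≥ 0).  At t = 0 the value is
K1·K2/(K1+K2), which ties K1 to the inoculation density once K2 is set
by the peak plateau.  All four parameters are strictly positive; λ1 is
reported as the *growth exponent* and λ2 as the *decline exponent*.

Assumptions worth keeping in mind: the model is deterministic and
unimodal — it cannot express diauxic growth, lag phases, or secondary
blooms — and it is fitted to each replicate independently, so no
information is shared across replicates or treatments at the curve
level.

## Fitting

The curve predicts ln N, so the objective is ordinary least squares on
ln-transformed counts, Σᵢ (ln cᵢ − ln N(tᵢ))².  Counts must be strictly
positive; zeros are rejected rather than imputed, because no pseudo-count
convention is defensible for per-µL cytometry counts near 1.

Positivity of (K1, K2, λ1, λ2) is enforced by optimizing their
logarithms — the problem stays smooth and unconstrained, which trust-
region least squares handles well.  Wide log-scale guard bounds
(K ∈ [10⁻³, 10³] ln-units, rates ∈ [10⁻⁷, 10] h⁻¹) only stop runaway
iterates; a solution pinned against them is reported as non-converged.

The objective is non-convex, so the solver is multi-started: one
deterministic start from a data-driven heuristic plus, by default, three
copies jittered multiplicatively by factors uniform in [0.5, 2] from a
seeded generator (`FitOptions.restart_seed`), keeping the whole fit
deterministic.  The heuristic sets K2 to the best 3-point sliding mean
of ln counts, solves the t = 0 identity for K1, and reads λ1 and λ2 off
the slopes of ln(ln count) versus time before and after the peak window
(each regime is log-linear on that scale), flooring rates at 10⁻⁴ h⁻¹.

Convergence tolerances are tight (relative residual/step change 10⁻¹⁰,
gradient norm 10⁻⁸, ≤ 500 iterations) since downstream reporting uses
~3 significant figures.  Standard errors come from the Jacobian at the
solution, σ²(JᵀJ)⁻¹ with σ² = RSS/(n − 4); the analytic gradient of the
curve is used both in the solver and here.

Two diagnostics mark a fit as non-converged: a parameter on a guard
bound, and an *unresolved phase* — λ·(observed span) < 10⁻³, meaning the
data contain no detectable growth or decline (constant or monotone
series).  Non-converged replicates are carried with their flag and
excluded listwise from inference, with a logged warning; they are never
silently refitted.

A pooled fit across replicates (geometric-mean counts at shared times)
is available for display purposes but is never used in inference — the
per-replicate path is canonical.

## Per-replicate responses

Each replicate contributes three responses:

- **growth** = fitted λ1 (h⁻¹),
- **decline** = fitted λ2 (h⁻¹),
- **max_abundance** = the maximum over all windows of three consecutive
  timepoints of the mean ln count (ln cells µL⁻¹), ties to the earliest
  window.

The peak statistic is computed from the data, not the fit, so a poor fit
cannot distort it.  Averaging *ln counts* within the window keeps every
analysis on the ln scale; the alternative (ln of the mean raw count) is
exposed as `method="ln_of_mean"` for sensitivity analysis — by AM–GM it
is never smaller, and the two differ only by within-window spread.
"Maximum abundance" and "carrying capacity" are used interchangeably for
this one statistic.

## Factorial inference

Per host and per response, replicate values enter a **saturated
cell-means model** over inoculum × vitamin: every design cell has its
own mean, and a single pooled residual variance
σ̂² = Σ within-cell squared deviations / (N − #cells) supplies all
standard errors.  This is the simplest linear model consistent with
conditioning comparisons on a vitamin level or on an inoculation state,
and on a balanced design its marginal means are exactly the cell means
and its two-level contrasts are exactly classical pooled two-sample t
tests (verified in the tests, including against an independent
general-purpose OLS/Tukey implementation).  Every cell must have ≥ 2
replicates so it contributes to σ̂²; unequal cell sizes (after dropping
non-converged fits) are handled by the 1/nA + 1/nB standard-error form.

Multiplicity: all pairwise contrasts among the six inoculation states
within one vitamin level form a single family of 15, adjusted by the
studentized-range (Tukey) distribution, p = P(Q_{k,df} ≥ √2·|t|); the
inoculation-vs-control rows are the five family members involving the
control, so they inherit the same family-wise adjustment.  The
replete-vs-deficient vitamin contrast within an inoculation state is a
two-level family and is left unadjusted.  Adjusted p is clamped to be at
least the unadjusted p.  The family definition is configuration, not
dogma: a Dunnett-style many-to-one family would be a defensible
alternative for the control comparisons; the all-pairs Tukey family is
the default because the strain-vs-strain comparisons belong to the same
reporting table.

Effect sizes are **percent impacts**, 100·(effector − default)/mean of
the two conditions — antisymmetric, scale-invariant, and bounded by
±200% for same-sign means.  The effector is the inoculation (against
the control), the first inoculum (against the second), or the replete
vitamin condition (against deficient).  Impacts are computed from raw
condition means of the per-replicate responses, identical to
model-adjusted means under balance.  Direction: increased growth or
peak, or decreased decline, is *beneficial*; the reverse is
*detrimental* (the decline response flips the sign convention).
Significance defaults to adjusted p < 0.05 and is configurable; both
filtered (significant-only) and full tables are emitted.

A single-factor version of the same model (with a one-way ANOVA F test)
covers comparisons such as bacterial strains grown alone in broth.

## Synthetic experiments

The generator inverts the fitted model: counts are
exp(ln N(t; θ_rep)) · ε with ε mean-one lognormal.  Defaults describe
the emulated study conditions and were fixed once:

| quantity | default | rationale |
|---|---|---|
| design | 3 hosts × 6 inoculation states × 2 vitamin levels × 3 replicates | the factorial layout under study |
| schedule | 0, 24, then every 60 h to 624 h (12 timepoints) | a first-day count, then a ~2.5-day cadence over ~26 days |
| base parameters | K1 = 1.5, K2 = 9.0, λ1 = 0.02 h⁻¹, λ2 = 0.001 h⁻¹ | initial density e^1.286 ≈ 3.6 cells µL⁻¹ (within the 1–10 inoculation window), peak near 230 h at ~10³ cells µL⁻¹ |
| count CV | 5% | typical repeat-count variability of cytometric counts |
| replicate parameter jitter CV | 5% | mild biological replicate-to-replicate variation |

Treatment effects are planted as strictly positive multipliers on the
true parameters of matching cells (wildcards allowed), so a 0.6×
multiplier on λ1 yields a closed-form expected impact of
100·(0.6−1)/0.8 = −50%.

Seeding: one master seed; each (cell, replicate) derives an independent
substream by hashing its labels (SHA-256) together with the master seed,
so editing the design never perturbs the draws of untouched cells, and
identical seeds give byte-identical pipelines end to end.

What the generator does *not* emulate: irregular per-replicate sampling
timestamps, count detection limits and gating artifacts, temporal
autocorrelation of counts within a replicate, mechanistic host–bacteria
interaction dynamics, and free-living bacterial trajectories.  Passing
tests therefore demonstrate correctness of the estimation and inference
machinery under the stated noise model, not robustness to those realities.

## Numerical choices and degenerate inputs

- Peak-time/oracle agreement is checked against a 40-digit golden-section
  minimization: in double precision the two-term denominator is too flat
  near its minimum to localize it to 10⁻⁶ h.
- Large-time curve values underflow to 0 beyond λ2·t ≈ 700; the fitting
  window never approaches this regime.
- Constant or monotone count series are flagged non-converged via the
  unresolved-phase rule rather than returning arbitrary rate estimates.
- Zero pooled variance (identical responses) yields t = 0 and p = 1 for
  null contrasts, and |t| = ∞, p = 0 for non-null ones.
- Percent impact is undefined (raises) when the two condition means
  average to zero; this cannot occur for the three positive responses.

## Problem sizes

The test suite and the acceptance script use 100 random draws for the
peak-time oracle, all 36 design cells for the noise-free round trip,
200 simulated replicates for stochastic exponent recovery (median
relative errors ≈ 1–2% at 5% count CV), 2,000 null simulations for the
type-I calibration of the vitamin contrast, and one full single-host
pipeline run (36 replicate fits) for planted-effect recovery.  These
sizes give Monte-Carlo standard errors comfortably below the margins
being tested (e.g. ±0.49% on the 5% type-I rate).

## Known limitations

- Inference assumes homoscedastic Gaussian responses across cells; the
  fitted exponents of a replicate are treated as known values, their
  fit-level standard errors are not propagated into the linear model.
- The saturated cell-means model cannot test main effects averaged over
  interaction structure beyond the marginal means it reports.
- The curve family excludes lag phases and secondary blooms; fits to
  such data will converge to a compromise unimodal shape and should be
  screened by their residuals.
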