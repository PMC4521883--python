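# Methods

## Absolute quantification

Each cDNA sample carries a known number of exogenous spike-in template
molecules (`spike_copies`, typically 2.6×10⁸ or 1.1×10⁷). Gene copies per
sample are

    copies = spike_copies × E^(Ct_spike − Ct_gene)

with a single pooled amplification efficiency `E` (default 1.9, i.e. 90%
per-cycle amplification). Primer pairs are screened against a closed
acceptance interval of measured efficiencies, default [1.85, 2.03]
(89–103%); the screen takes a measured number as input — estimating
efficiency from a dilution series is out of scope.

Technical replicates are aggregated **on the Ct scale** (arithmetic mean
Ct), because Ct is the measured quantity and the conversion formula takes
single Ct values; the sample SD (n − 1) over √n gives the Ct SEM, and a
single replicate yields a flagged (NaN) SEM. SEMs are propagated to the
copy-number scale by the delta method (|∂copies/∂Ct| = copies·ln E) and
the gene and spike contributions combined as √(SEM_gene² + SEM_spike²).
Mean Cts above a configurable cutoff (default 38) are flagged undetected
and quantified as 0; the data themselves carry no detection floor, so the
cutoff is a config knob, not biology. "Copies per embryo" is a labelling
convention tied to the amount of input RNA per sample; no rescaling is
applied.

## Activation model and initiation time

Zygotic activation is modelled on the log10 scale as

    log10(mRNA(t)) = a − b / (1 + exp(c (t − t0)))

with late asymptote `a` (log10 maximal level), early asymptote `a − b`
(basal/maternal level), rise rate `c` (h⁻¹) and half-rise time `t0`
(hours post fertilization), the operational initiation time. Note the
rise amplitude is `b`, not the basal level itself — the parameterization
is sometimes glossed otherwise, but the algebra is unambiguous.

**Zero handling.** Levels are shifted by a pseudo-level floor before the
log (default: half the smallest positive level of the profile), keeping
zeros representable while leaving the fit of an all-positive profile
essentially unchanged. The floor scales with the profile, so scaling all
levels by k shifts `a` by log10 k exactly and leaves `b, c, t0` alone.

**Fitting.** Nonlinear least squares (scipy `least_squares`, TRF, analytic
Jacobian) with bounds c ∈ (0, 10], b ∈ (0, 10], t0 ∈ [min t − 5,
max t + 5], a free. Initialization is a coarse grid over 16 t0 values ×
12 log-spaced c values; since the model is linear in (a, b) given (c, t0),
each grid cell solves (a, b) in closed form, and local refinements start
from the best three distinct-t0 cells. This multi-start scheme avoids the
sigmoid's sign-flip and edge local minima; on noiseless data all four
parameters are recovered to machine precision, and the refined solution is
never worse (in residual sum of squares) than a dense grid search. A fit
returns `converged=False` rather than raising when the optimizer fails
from every start; perfectly flat profiles return a flagged non-identifiable
fit (b = 0, t0 undefined). The full 0–30 h window is fit by default; a
per-gene window override is available for genes whose expression decays
after a peak, which the monotone sigmoid cannot follow.

**Confidence interval.** The 95% CI for t0 uses the NLS covariance
(pseudo-inverse of JᵀJ times RSS/(n − 4)) with a t quantile on n − 4 df.
Empirical coverage at measurement noise σ = 0.1 log10 units on a 1-h grid
sits in the low-to-mid 90s (checked over 500 simulations in the test
suite).

**Zygotic gate.** A gene enters timing analyses only if the fitted model
rises by ≥ 0.5 log10 units (~3.2-fold) **within the sampled window**.
Gating on the window-realized rise rather than the asymptotic `b` matters:
flat noisy profiles admit a degenerate fit with t0 pushed outside the
window and `b` inflated along the sigmoid's flat tail, which would
otherwise leak maternal genes into timing statistics. For genuine
activation with t0 well inside the window the two criteria coincide.
Gated (maternal) genes still contribute level statistics.

## Intra-species variability

Per gene: the maximal observed level per repeat (ties broken by earliest
time), the fitted maximum 10^a, and t0 per repeat. Variation is the
normalized SD (CV): 100 × sample SD / mean over repeats — sample SD
matches the small number of repeats (typically 3). Repeat pairs are
compared by Pearson correlation of maxima and of t0 and by the
zero-intercept slope Σxy/Σx² of t0 (slopes ≈ 1 mean matched developmental
rates between individuals). Correlations use raw maxima (not logs) to
match the conventional presentation; this is a documented sensitivity
choice. The coupling between variation modes is the across-gene Pearson
correlation of cv_max and cv_t0. The fold difference of maxima is the
per-gene mean over repeat pairs of max/min; the headline number averages
these per-gene means, and the pooled mean over all gene × pair folds is
reported alongside (the two differ when repeat counts vary).

## Inter-species scaling and conservation

The rate ratio ρ (species-B time per species-A time) is the zero-intercept
least-squares slope of matched initiation times, with R² computed about
the mean of the B times and the Pearson correlation reported alongside.
Genes excluded from the regression (e.g. genes whose profiles indicate
changed regulation) are an explicit input list, never automatic.

To compare dynamics, species-A times are multiplied by ρ and A levels are
linearly interpolated **on the log10(level + floor) scale** — profiles
span orders of magnitude, so linear-scale interpolation would be dominated
by the plateau — onto the species-B measured time points inside the
overlap of the two windows. Both vectors are then normalized to
percent-of-maximum over that comparison window only, and scored by Pearson
correlation per orthologue pair; the headline is the unweighted mean over
genes. The null is the same computation on non-orthologous cross-species
pairs (g_A, h_B), g ≠ h — exhaustive and deterministic by default, with a
seeded sampled mode available. On noiseless data generated with a true
ratio, aligning with that ratio maximizes the matched-pair mean
correlation.

## Synthetic data generator

`SimConfig` defaults define the study conditions: 25 genes × 3 biological
repeats per species; baseline parameters drawn uniformly with a ∈ [2, 6],
b ∈ [1, 3], c ∈ [0.5, 2.5] h⁻¹, t0 ∈ [4, 24] h (the realistic spans for
regulatory genes quantified over early development: maximal levels
10²–10⁶ copies, 10–1000-fold rises completing in a few hours); rate ratio
1.3; species A sampled 0–30 h at 1-h steps and species B over the dilated
window 0–round(30ρ) h. Species B uses t0·ρ and c/ρ, so its noiseless
dynamics are an exact time dilation of species A. Biological repeats
multiply t0 and 10^a by mean-1 lognormal factors with CV 0.08 and 0.29
respectively (lognormal keeps positivity and matches percent-SD
reporting); measurement noise multiplies levels by 10^N(0, σ) with
σ = 0.1 log10 units; 12% of genes are maternal (rise drawn below the
zygotic gate). Draws whose jittered t0 falls outside the grid are redrawn
a bounded number of times, then flagged. `to_ct_table` inverts the
quantification formula (fixed spike Ct, technical triplicates, optional
Ct noise) for end-to-end tests of the quantification stage.

What the generator does **not** emulate: post-peak decay and multi-phase
spatial re-deployment of real genes (real profiles can fall or show two
peaks; the generator's profiles saturate), per-gene inter-species
regulatory divergence beyond the global rate ratio, correlated noise
across time points, and plate/batch structure. Consequently the synthetic
zero-intercept R² (~0.96) is higher than real cross-species data shows,
and the random-pair baseline (~0.6) is somewhat higher than in real data,
where profile shapes are more diverse. Passing closed-loop tests
demonstrates that the estimators recover known truth under the stated
noise model — not that real data meet that model.

## Numerical and design choices

- Logs are base 10 throughout.
- CV estimates from 3 repeats use the sample SD, which is biased low by
  the usual c₄(3) ≈ 0.886 factor; the closed-loop recovery band of ±3
  percentage points absorbs this.
- R² of a fit is 1 − SS_res/SS_tot on the log10 scale, about the mean;
  zero-variance data yield a flagged NaN. Summary fit quality is reported
  over zygotic fits, since an activation-model R² is meaningless for flat
  maternal profiles.
- Exhaustive random-pair mode is the default for determinism;
  order-invariance is tested.
- Table readers never silently coerce: ambiguous dialects, duplicate
  (gene, repeat, time) rows, missing columns and non-numeric cells raise
  errors naming the rows. The XLSX layout (one wide sheet per repeat) is
  a mapping config, so layout drift is a config change.
- Problem sizes in the test suite (50-seed loops at 25 genes × 3 repeats,
  500 CI simulations) are chosen to bound sampling error on the recovered
  statistics while keeping the whole suite to a few minutes.

## Known limitations

- The monotone sigmoid cannot represent decay after a peak; t0 estimates
  for such genes should use the fit-window override.
- The t0 CI is a Wald interval; for rises near the window edge it can be
  optimistic.
- The rate-ratio model assumes one global ρ across territories and the
  whole window; per-territory or time-varying scaling is out of scope, as
  are nonlinear time warping and temperature-response modelling.
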