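# Methods

## The competition model

Three homogeneous firing-rate populations encode the percepts of a
bistable drifting plaid: coherent motion (C) and the two depth-orderings
of transparent motion (T_R, T_L). Each population obeys

    τ  dr_i/dt = −r_i + S(−inhibition_i − a_i + I_i + n_i),

with mutual inhibition −β₁(r_TR + r_TL) onto C, and −β₁ r_C − β₂ r_other
onto each transparent population. `S` is a logistic transducer
`S(x) = 1/(1 + base^−(x−θ)/k)` with θ = 0.2, k = 0.1 and base *e*; its
output in (0, 1) bounds the rates, and S(θ) = ½ for any base. The base is
exposed (`transducer_base`) purely for fidelity experiments with
non-standard printed forms of the sigmoid; any base < 1 makes the
transducer decreasing and the model ceases to behave as an input-output
gain, so the logistic is the only scientifically meaningful default.

Spike-frequency adaptation follows `τ_a da_i/dt = −a_i + γ r_i`
(τ_a = 2500 ms), so a population held at its maximum rate saturates at
a = γ and a silent one relaxes to 0 with time constant τ_a. Noise is an
Ornstein-Uhlenbeck process `dn/dt = −n/τ_s + σ√(2/τ_s) ξ(t)` (τ_s =
200 ms); the √(2/τ_s) scaling makes σ the stationary SD and τ_s the
autocorrelation time, which is what the anchor checks in
`scripts/acceptance.py` measure.

Default constants: τ = 10 ms, τ_a = 2500 ms, τ_s = 200 ms, θ = 0.2,
k = 0.1, σ = 0.08, γ = 0.25. The *reference operating point* used by the
sweep battery (`ModelParameters.sweep_base()`) sets β₁ = 0.9, β₂ = 0.7,
σ = 0.06, γ = 0.2, I_C = 1, I_T = 0.9 I_C — a regime of noise-driven
winner-take-all alternation in which the coherent percept dominates
slightly.

### Numerics

Integration is explicit Euler (Euler–Maruyama for the noise) with
dt = 1 ms by default — ten times smaller than the fastest time constant —
and is first-order convergent; the parameter container rejects
dt > τ/5. All state starts at zero. One seeded `numpy` generator per
trial draws the three populations' noise increments in fixed order
(C, T_R, T_L), so a (parameters, seed) pair reproduces a trajectory
bit-identically on any platform. Non-finite states abort integration with
the failing step named. The inner loop is numba-compiled; a 120-s trial
takes ~25 ms. Time is milliseconds internally; user-facing durations are
seconds.

The discretised OU recursion has stationary SD σ·(1 − dt/2τ_s)^−½ ≈
σ(1 + dt/4τ_s); at the default steps this bias is < 0.2% and invisible at
the tolerances used.

## Percept statistics

A sample is *coherent* iff r_C strictly exceeds both transparent rates;
ties (including the all-zero start) are transparent, matching the strict
reading of coherent dominance. Runs of equal labels form epochs whose
boundaries sit at the first sample of each new label.

Per trial the two dependent variables mirror the behavioural analysis:

* **switches** — label changes counted from the first transparent epoch
  (inclusive: the change into it is the first switch, the first percept
  being coherent) to trial end; a trial with no transparent epoch reports
  0 switches and an explicit flag;
* **durations** — epoch lengths per label, excluding the final
  interrupted epoch, log10-transformed before averaging.

Summaries over repeated trials use the sample SD (n − 1); flagged trials
are excluded from duration summaries and counted separately.

An optional minimum-epoch filter merges epochs shorter than a bound into
their predecessor (a short *first* epoch merges forward instead). It is
off by default in `classify_trajectory`, but the sweep engine defaults to
0.25 s: per-sample labelling produces millisecond flickers at
classification boundaries and a spurious transparent startup epoch from
the tied zero start, neither of which any observer could report, and both
of which otherwise contaminate duration means wherever genuine transparent
dominance is rare. 0.25 s is well below reportable percept durations and
below typical key-press reaction times.

## Parameter sweeps and qualitative signatures

`run_sweep` varies one of σ, γ, absolute input (I_C with I_T at the base
ratio) or relative input (I_T/I_C at fixed I_C) over a sorted grid,
summarising 30 seeded trials per point by default. Per-trial seeds derive
from `SeedSequence(base_seed, grid_index, repetition)` — deterministic,
platform-stable, and collision-free, which is why it is preferred over ad
hoc XOR/hash mixing.

`signature_report` checks the four characteristic patterns at the
reference point:

1. **noise** — switches rise and both duration means fall with σ;
2. **adaptation** — switches rise with γ and the coherent duration falls
   faster than the transparent one (compared via fitted linear slopes);
3. **absolute input** — the switch curve has an interior minimum: at very
   low input the noise dominates and the system oscillates rapidly, at
   high input adaptation-driven switching returns;
4. **relative input** — a bell-shaped switch curve whose peak lies within
   one grid step of input equality, with the longer percept flipping from
   coherent (below equality) to transparent (above).

Monotonicity is never tested as a raw inequality chain: each step may
violate the trend by up to 2 standard errors of the difference of means,
and the total change must exceed 2 standard errors — a Monte-Carlo
tolerance derived from the reported SDs. Interior extrema must beat both
endpoints by the same margin. Grids shorter than 4 points make a
signature *not testable* (reported as `None`, never as a pass).

Default grids bracket the reference point: σ ∈ {0.05…0.12},
γ ∈ {0.05…0.35}, input ∈ {0.2…2.0}, ratio ∈ {0.7…1.3}. The noise grid
starts at 0.05 because below σ ≈ 0.04 transparent dominance becomes so
rare that duration statistics rest on a handful of epochs and the duration
signature is undefined.

## Behavioural pipeline

Event logs carry one row per key press (subject, group AMB/NTE, eye
binocular/weak/strong, direction vertical/horizontal, contrast, trial
length, time, key). Parsing sorts by time, rejects duplicate timestamps,
and collapses consecutive same-key presses (a repeated key signals no
change). Trial metrics follow the rules above with two behavioural
specifics: the first percept is present from t = 0 (a late first press
does not shorten the first duration), and the switch count is the number
of events from the first *transparent press* — which, when the first press
is transparent, is itself the first reported switch. For coherent-first
logs this is provably identical to converting presses to epochs and
running the simulation-side statistics, a property the tests enforce.

Exclusions for duration analyses: subjects with a no-switch condition are
dropped; then, per group × condition × percept cell, values more than 2 SD
*above* the between-subject mean (one-sided, configurable) are flagged,
and subjects flagged in ≥ 3 cells (configurable) are dropped. Switch-count
analyses keep everyone. Fewer than 3 subjects left in a group is an error.

### Mixed ANOVA with Greenhouse–Geisser correction

No installed package runs a multi-within-factor + between-group univariate
split-plot ANOVA, so `rm_anova_gg` implements it directly for balanced
designs: per within effect, an orthonormal contrast basis (Kronecker
product of Helmert bases) maps the subject × cell matrix onto contrast
variables; hypothesis sums of squares use unweighted (Type III) group
means so unequal group sizes do not bias within effects; each effect is
tested against its own stratum error (effect × subject-within-group). The
GG ε̂ comes from the pooled within-group covariance of the contrast
variables, is clipped to [1/p, 1], and scales both degrees of freedom;
strata with one contrast variable (2-level factors) have ε̂ = 1, so the
adjustment applies exactly where sphericity can fail. `pingouin.
mixed_anova` (one within factor) and `statsmodels` `AnovaRM` (pure within)
reproduce these tables exactly on their sub-cases and serve as oracles in
the tests. Bonferroni post-hocs rerun the 2-level mixed ANOVA per level
pair and multiply p by the number of pairs (capped at 1).

Contrast regressions fit each group's across-subject condition means
against contrast (or log contrast) by OLS, reporting slope, 95% CI and R²;
the group × contrast interaction compares per-subject linear-trend slopes
between groups with a one-way ANOVA, giving F(1, N − 2). With 5 + 6
subjects this is F(1, 9); published analyses of such designs sometimes
report other denominators, and the aggregation unit is the one part of the
pipeline that is a modelling choice rather than a fixed rule. Clinical
correlations are plain Pearson r between per-subject monocular switch
counts and log acuities (weak eye ↔ weak-eye acuity, strong ↔ strong,
monocular mean ↔ stereo acuity).

## Synthetic cohorts

`generate_cohort` emulates exactly the structure the pipeline assumes — no
more. Each trial is an alternating renewal process: coherent from t = 0,
epoch lengths log-normal with per-percept log10 means (defaults 0.75
coherent / 0.55 transparent at the 30% reference contrast, i.e. ≈ 5.6 s
and 3.5 s) and within-trial spread 0.25 log10 units, truncated at the
120-s trial end. A moment-matched gamma family is available behind
`duration_family`. Between-subject heterogeneity is a normal random
intercept (SD 0.15 log10 units) shared by both percepts. Contrast enters
as a per-group linear trend on the log10 means: +0.5/unit contrast for
NTE (durations shorten, switches accelerate as contrast drops) and 0 for
AMB. The magnitude is a generator default chosen so the designed pattern
is reliably detectable at the small sample sizes of a contrast-control
experiment (5 + 6 subjects, 6 contrast levels); it is a test condition,
not a claim about human effect sizes. Clinical tables are drawn either
independently of behaviour (null) or correlated with the subject's
duration intercept (linked).

What the generator deliberately omits — reaction-time lags, misreported
percepts, eye-movement interruptions, non-stationarity within a trial,
heavier-tailed duration laws — bounds what green tests show: the pipeline
is calibrated and recovers designed effects *under its own assumptions*,
not that those assumptions hold for any particular human dataset.

## Verification scales

The test suite runs the four-panel signature battery at 30 trials per grid
point (≈ 810 simulated 120-s trials), a 1,000-replicate null calibration
of the pipeline (compact 2 × 10-subject design; group × contrast duration
interaction rejects at 0.050 at α = 0.05), and a 100-replicate
recovery check of the designed contrast effect (NTE CI excludes zero, AMB
CI contains it, in ≥ 90% of replicates). The acceptance script measures
the OU stationary SD on a 1,200-s trace and the autocorrelation time on a
2,000-s trace at dt = 0.1 ms — long enough that the Monte-Carlo spread of
the estimators (< 2% and < 6% across seeds) sits well inside the checks'
tolerances.

## Known limitations

* The ANOVA requires complete balanced designs; missing cells are an
  error, not an imputation problem it tries to solve.
* Sweeps are one-dimensional; interactions between β and the swept
  parameters are out of scope.
* The simulator is a three-population caricature: no motion-tuned
  population structure, no stimulus rendering, no fitting to data.
* The duration-law family in real data is unknown; the log-normal default
  is an assumption stated as such.
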