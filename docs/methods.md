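# Methods

This note documents the models, numerical choices and limitations of the
`supergee` package: what exactly is simulated, which knobs matter, and
what passing tests do and do not establish.

## Task engine

The trial is a 1-D point mass under rate control.  Holding the right
arrow applies acceleration `+force_accel`, the left arrow `−force_accel`;
both or neither give zero net force, so velocity is exactly conserved
while coasting.  Integration is semi-implicit Euler on the 100 Hz sample
grid (`v[k+1] = v[k] + a[k]·dt`, `x[k+1] = x[k] + v[k+1]·dt`), which is
also the logging grid; key-press onsets are quantized to samples.  The
scheme is exact for velocity under piecewise-constant input and
first-order accurate in position, which is ample at dt = 10 ms relative
to the task's 80 ms planet radius.

Timing and rules follow the deployed game where stated: 4.5 s trials
(1.5 s hold + 3 s movement window), landing = 1 continuous second within
the target radius, 75 trials per session, 16-planet chain.  The force
magnitude and geometry are not published; defaults
(`force_accel = 2 u/s²`, `planet_distance = 1 u`, `planet_radius =
0.08 u`) are feasibility-driven — the ideal bang-bang controller
(thrust τ = √(d/a) ≈ 0.707 s, then brake τ) lands every trial with
≥ 0.5 s margin — and are configuration-exposed, not calibrated to the
real game.

Design choices where the rules are underdetermined:

- **Early exit.** Leaving the start planet (|x| > r, ties count as
  inside) before the go cue resets position, velocity and the trial
  clock; the attempt is not consumed.  A timed-out movement window *is* a
  failed attempt.  Because an open-loop plan with a realized exit time
  earlier than the hold would replay identically forever, the policy
  redraws its timing jitter on each reset (each reset is a fresh
  attempt); after 50 resets pre-go presses are suppressed so a trial
  always terminates.  Only the post-reset timeline is scored.
- **Landing clock.** The continuous-landing second starts when the
  cursor *enters* the target boundary.  For the bang-bang optimum this
  is during braking (~1.13 s after the go cue), so the landed event
  fires ~2.13 s after the cue; the trial ends at that event (no
  fireworks phase) and no further samples are emitted.
- **Planet chain.** A success promotes the target to the next start
  planet and reveals a new target; ids increment without wrapping so
  every transition of an all-success session is distinct (`n_planets`
  is the game's nominal chain length; a display name would be
  `id % n_planets`).

The session core is vectorized across the 75 trials (arrays of shape
75 × 451); `run_trial`/`run_session` materialize per-trial logs from the
same arrays, and the study simulator consumes them directly.  A session
simulates in ~2 ms, which is what makes the replicated calibration
studies below tractable on one CPU.

## Metrics

Per trial, on the post-reset timeline with the go cue at 1.5 s:
SR = total left-press time over total right-press time inside the
movement window (undefined when there is no right press); TR = onset of
the first left press after the cue; TinT = cumulative sampled dwell
inside the target (it accrues on failed trials too, and is not the
longest continuous run); RT = first sample with |x| > r after the final
go cue.  RT is reported on the absolute trial clock (it includes the
1.5 s hold) because published session means exceed 1500 ms, which is only
consistent with that convention; the go-relative variant is stored
alongside (`rt_go_ms`).  Undefined metrics are excluded from session
means rather than imputed; each mean carries its defined-trial count.

## Synthetic participants

Behavior is an open-loop *bang-coast-bang* plan: exit at `t_go`, thrust
`tau_right`, brake at `t_rev` for `rho·tau_right`, with i.i.d. Gaussian
jitter (`timing_sd`) on all four realized times per attempt and a
`lapse_prob` chance of a no-press trial.  This is the simplest policy
family in which the four metrics have independent levers: `t_go` → RT,
`t_rev` → TR, `rho` → SR, `timing_sd` → TinT.  No within-session
learning is modeled by default (the analysis consumes session means
only), and there is no closed-loop feedback correction.

Population defaults (`t_go = 1.62 s`, `tau_right = 0.72 s`,
`rho = 0.75`, `t_rev = 2.32 s`, `timing_sd = 0.10 s`,
`lapse_prob = 0.02`) were set once so that session means land in the
range reported for real cohorts: simulated TinT ≈ 280 ms,
RT ≈ 1.88 s, TR ≈ 2.33 s, SR ≈ 0.78 against published cohort values of
roughly 470–650 ms, 1.6–1.9 s, 2.0–2.1 s and 0.65.  Two deviations are
structural: real players produce higher TinT with *lower* SR, which a
single open-loop press pair cannot do (braking short enough to give
SR ≈ 0.65 leaves too much residual velocity to dwell long), and real
TinT distributions are more dispersed.  Conclusions from the simulation
therefore concern the *pipeline*, not human behavior.

**Covariate link.**  Standardized covariates shift policy parameters
linearly: age degrades precision (`timing_sd += 0.02·age_z`), males are
more precise (`−0.03·male`), verbal learning couples to precision in
males only (`−0.02·pal_z·male`), and carriers plan earlier exits
(`t_go −= 0.05·carrier`); independent participant-level noise (SDs
0.05/0.02/0.04/0.02 s on `t_go`/`tau_right`/`t_rev`/`timing_sd`) keeps
effects realistic.  Magnitudes were chosen to give standardized effects
of roughly 0.5–1 SD on the session means, detectable by sign at a few
hundred participants.  Linked parameters are clamped into validity
ranges; clamping is flagged and affects well under 1% of participants
under the default link.  The published study's fitted coefficients are
*not* targets: its raw data are unavailable, so the analysis is accepted
on parameter recovery, not coefficient reproduction.

## Synthetic cohort

Marginals emulate the studied sample: age truncated-normal (mean 62.39,
SD 7.4, min 45), 39/54 female, genotype probabilities equal to the
observed counts (2/3: 2, 3/3: 29, 2/4: 4, 3/4: 16, 4/4: 3, none 2/2),
education 1/9/21/23 across the four levels, PAL generated on a latent
Gaussian (intercept 21, −2.5 per age SD, −4 for males, residual SD 7)
rounded and clipped to [0, 36], svRT log-normal (median 400 ms,
log-SD 0.19, matching the reported right skew), play hour
truncated-normal around 14:00 on the 24 h clock, and a PAL-to-gameplay
delay of 5.9 ± 1.4 years.  `sampling="exact"` reproduces the integer
margins by largest-remainder apportionment (at n = 54: exactly 23
carriers, 20 of them heterozygous, and 39 females) and is used for the
count-anchored checks; `"iid"` draws independently and is used for the
replication studies.  Sex, genotype and education are sampled
independently of one another, so joint tables (e.g. sex × carrier) match
only in expectation.

## Preprocessing

Carrier = at least one ε4 allele in an `a/b` genotype with alleles in
{2,3,4}.  Hour-of-day enters as cos(2πh/24) — midnight-adjacent hours
become numerically close — and is then standardized like every other
numeric variable (n−1 SD convention; transform parameters are stored so
standardization inverts exactly).  The delay-adjusted PAL subtracts the
expected 0.2 points per elapsed year, projecting the historical score
forward to the gameplay date; the direction of the adjustment is recorded
in output metadata since the opposite convention is defensible.
Percentile contextualization uses stratified empirical percentiles (age
decade × sex × education, midpoint tie convention, falling back to
sex × education with a warning when a stratum is empty); this
approximates, but is not, the original cohort's regression-adjusted
norms, which are not public.

## Statistical battery

Rank-sum tests use the Mann-Whitney U of the first sample (its rank sum
minus the minimum) with exact enumeration when n₁+n₂ ≤ 20 and untied,
otherwise the normal approximation with tie and continuity corrections;
all-tied data yield p = 1 with a warning.  Chi-square on 2×2 tables uses
Pearson's statistic with optional Yates correction (|O−E| reduced by 0.5,
floored at 0).  Cohen's d uses the pooled-SD (n₁+n₂−2) denominator.

The five regressions are fit by OLS (linear) or binomial GLM (logistic)
on the standardized table, with education as treatment-coded dummies
(reference: high school diploma).  Screening order: drop zero-variance
design columns, iteratively remove predictors with VIF > 5 (VIF from an
auxiliary regression of each predictor on the rest plus intercept;
perfectly collinear or constant columns rank as infinite), fit, remove
observations with Cook's distance > 1 (exact formula for OLS, one-step
approximation for GLM; leverage-1 rows count as infinite), refit once.
Note that with the studied education margins the reference category is
rare (~2%), so the dummy block is nearly complementary and the VIF rule
will often re-base it by dropping one dummy — a property of the stated
rule, not a bug; focal terms are unaffected.  Logistic odds-ratio CIs
invert the likelihood-ratio statistic (bracketed root search on
constrained refits); a side whose profile never crosses the critical
level inside a wide bracket (quasi-separation) falls back to the Wald
bound and is flagged, as is suspected separation itself.  Wald intervals
are available by flag and are used inside the replicated simulation
studies, where only p-values matter.

## Replicated validation studies (problem sizes)

Chosen once as the package's study conditions, balancing Monte-Carlo
error against desk-scale runtime:

- **Sign recovery** — 100 replicates of a fresh n = 500 cohort through
  the full pipeline; each of the four planted effects (carrier→RT −,
  male→TinT +, age→TinT −, male:TinT→PAL +) must be estimated with the
  correct sign in ≥ 80% of replicates.  Observed: 100% for each.
- **Type-I calibration** — 500 replicates at n = 200 under a link with
  all covariate effects removed (participant-level noise retained); each
  focal term's rejection rate at α = 0.05 must lie in [0.03, 0.07]
  (±2 SE of the nominal level at 500 replicates).
- **Extractor equivalence** — exact agreement (to 1e-9 ms) between the
  vectorized extractor and a naive pure-Python rescan on 500
  random-play logs, which exercise resets, lapses and undefined metrics.

## Known limitations

- The policy family is open-loop; closed-loop correction, learning
  curves and retention are out of scope, so within-session *change* is
  not simulated even though the session means it feeds are.
- Geometry and force are notional; absolute metric values are
  comparable to published ones only in order of magnitude.
- The SR–TinT trade-off of real players (low SR with high TinT) is not
  reproducible by a single press pair; SR runs high in simulation.
- Percentile norms are synthetic-reference approximations.
- Joint covariate structure beyond the stated couplings (e.g.
  education × PAL) is not modeled.
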