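# Methods

This note documents the models, defaults, and numerical choices behind
`grouplink`, and what the synthetic studies do and do not establish
about real data.

## Reactivity and the linkage regression

Observed minute-level mean IBI is decomposed as baseline level +
reactivity. Reactivity is referenced to the *final readable minute* of
the pre-session baseline; if that minute is unreadable the latest
readable baseline minute is used and the fallback is logged (strict
mode disables the fallback and excludes the person-session instead).
People with no readable baseline minute are excluded with an explicit
reason — no silent drops anywhere in the pipeline.

Each directed linkage estimate is an OLS fit of the receiver's
next-minute reactivity on the sender's and receiver's current-minute
reactivity. Only minutes where all three values are observed form
lagged triples; a session of L minutes offers L−1 lagged slots. An
estimate needs at least half of those slots (and at least 4 triples for
the 3-parameter fit) to be included. Coefficient standard errors use
the usual residual-variance estimator. A constant sender (or any rank
deficiency) marks the estimate `rank_deficient` rather than producing
an arbitrary solution.

### Artifact flagging

The original acquisition software's artifact algorithms are
proprietary, so the package uses a documented stand-in: a beat is
artifactual if its IBI falls outside 300–2000 ms, or deviates from the
running median of the prior 5 in-bounds beats by more than `rel_tol`
(default 0.3) times that median. The median is taken over in-bounds
beats only — not over beats that passed the relative test — so the set
of flagged beats shrinks monotonically as `rel_tol` grows, a property
the test suite verifies. "Readable" time within a minute is the longest
run of consecutive unflagged beats, measured as the sum of their IBIs
and truncated at minute boundaries; a minute needs a 30-s contiguous
run to contribute (two 20-s runs do not add up).

### Outlier screens

Pooling is study-wide (sessions and cohorts together). Pass 1 excludes
included estimates more than 3 SD from the pooled mean, in a single
(non-iterated) sweep. Pass 2 recomputes the pool and excludes estimates
that are simultaneously more than 8 SD from the mean and more than
2.5 SD from the nearest other estimate; requiring both conditions keeps
clusters of extreme-but-mutually-consistent estimates. A zero pooled SD
disables both passes. A winsorize mode (clip at the 3-SD bounds instead
of excluding) is available as a sensitivity option.

## The cross-classified mixed model

Fixed effects: the full 2×2×2×linear factorial of drug condition,
receiver role, sender role, and session (16 terms with intercept).
Two-level factors are effect-coded ±0.5, so "main effects" are averages
over the factorial cells — matching how condition and role effects are
usually reported — and session is centered at the study midpoint (3.5
for six sessions), so lower-order terms refer to the midpoint. Dummy
coding is available.

Random structure: crossed intercepts for cohort, cohort×session cell,
dyad (unordered pair), receiver, and sender. Labels are global: a
facilitator keeps one receiver/sender identity across the cohorts they
serve, which is what makes the classification crossed rather than
nested. "Session within cohort" is implemented as the cohort×session
cell intercept (the natural reading for a linear session predictor; a
random session slope per cohort would be the alternative and can be
added through the factor-label mapping).

### REML engine

The covariance is V(θ) = σ²ₑI + Σₖ σ²ₖ ZₖZₖᵀ. The −2·restricted
log-likelihood log|V| + log|XᵀV⁻¹X| + yᵀPy is evaluated through the
Woodbury identity in the space of random-effect levels (q = total
levels, a few hundred here), so each evaluation costs O(q³ + nqp)
rather than O(n³). The analytic score ∂(−2rl)/∂θⱼ = tr(PVⱼ) − yᵀPVⱼPy
is exact for this structure. Optimization is bound-constrained L-BFGS-B
on variance *ratios* (θ divided by the OLS residual variance, making
the problem scale-free), with a second start and a derivative-free
Powell rescue; convergence is declared only if the optimizer succeeds
or the projected gradient is small. Components at the zero boundary are
reported with a boundary flag, never hidden.

### Satterthwaite degrees of freedom and R²β

For a 1-df contrast L, ν₂ = 2f²/(gᵀAg) with f = L cov(β̂) Lᵀ, g its
finite-difference gradient in the variance parameters, and A = 2H⁻¹
from the finite-difference Hessian of the −2·REML criterion (computed
from the analytic score). The delta method runs on the variance scale
— the convention of mainstream mixed-model software that prints
fractional denominator df — and components estimated at the zero
boundary are held fixed there, because the criterion is not
differentiable across the boundary and the singular Hessian direction
would otherwise corrupt the denominator; on the Cholesky scale those
directions vanish automatically, and with this treatment the two
parameterizations agree (verified against `lmerTest` to ~3 decimals on
crossed fits, including boundary cases). Multi-row contrasts fall back
to residual df; every effect in the factorial here is 1 df.

Effect sizes are R²β = ((ν1/ν2)F)/(1+(ν1/ν2)F), the semi-partial R²
for fixed effects in mixed models; it lies in [0, 1) and is monotone
in F.

Simple effects at a session s are computed as contrasts on the fitted
model (condition means average the role factors out; the condition
difference is the drug term plus (s − midpoint) times the interaction),
which is algebraically identical to re-centering session at s and
re-reading lower-order terms; the identity is tested.

## The synthetic-cohort generator

The generator's defaults are the study conditions, chosen once:

- **Design**: 10 cohorts (four of 6, four of 7, two of 8 members, each
  including 2 facilitators drawn from a shared pool of 5 → 48
  participants), six sessions of 90, 90, 90, 90, 90, 60 minutes, 5-min
  baselines. Drug condition alternates across cohorts so each condition
  carries half the cohorts and a balanced share of the member-minutes.
- **Process**: reactivity follows a coupled VAR(1) per cohort-session —
  next-minute reactivity = stability × own current + Σ coupling ×
  senders' current + N(0, innovation_sd²). Stability is per-person
  uniform on [0.2, 0.4]; innovation SD 20 ms. The upper stability bound
  keeps the transition matrix comfortably stationary even in 8-member
  cohorts at the strongest coupling; configurations with spectral
  radius ≥ 1 are rejected before simulation.
- **Coupling**: oxytocin cohorts couple all ordered pairs at 0.08 in
  session 1, declining by 0.02 per session and floored at zero; placebo
  cohorts at 0. The published report gives the session-1/-2 contrast
  but no within-study trajectory, so the linear decline is an
  assumption of the generator, exposed as parameters.
- **Rendering**: observed minute mean = per-person baseline level
  (N(850, 70²) ms, floored at 400) + reactivity + N(0, 5²) ms
  measurement noise; non-positive rendered IBIs abort with a
  configuration error. An optional beat-level renderer emits constant-
  IBI beats per minute (plus injectable artifact beats) whose
  re-segmented means reproduce the input to < 1 ms, closing the loop
  with the processing module.
- **Attendance**: everyone attends session 1 and facilitators attend
  all sessions; participants attend later sessions with probability
  0.75, consistent with the published attendance table.
- **Missingness**: per-condition overall missing-data targets are 49.4%
  (placebo) and 38.7% (oxytocin), counting minutes lost to missed
  sessions. Real IBI loss is blocky — a failed sensor loses most of a
  session — and masking minutes i.i.d. at the target rates would push
  nearly every dyad below the 50% completeness rule, which no realistic
  study shows. The generator therefore delivers the target as
  whole-session device dropout plus scattered i.i.d. minute loss at
  0.15; the dropout rate is solved per condition from the target, the
  realized attendance, and the scatter rate, and dropout sessions are
  drawn as a fixed-count subset so the marginal rate holds for every
  seed. Defaults land at ~44% missing overall with ~4–6% of created
  estimates failing the completeness rule, both close to the published
  accounting.
- **Reproducibility**: one master seed feeds per-(cohort, session,
  purpose) derived substreams, so any subset of the study regenerates
  identically.

### What the synthetic studies do not show

The generating process has Gaussian innovations, minute-stationary
coupling, and missingness independent of the physiology. Real IBI
series have respiratory and circadian structure, coupling that waxes
and wanes within sessions, and missingness plausibly correlated with
movement (hence with arousal). Passing parameter-recovery and
calibration tests therefore establishes the estimator's correctness
under the stated model, not robustness to those violations. In cohorts
larger than two, the single-sender estimator is deliberately
misspecified relative to the multivariate generator, so group
simulations check sign and ordering, not unbiasedness — omitted-sender
inflation is a property of the per-dyad estimator itself, and recovery
acceptance uses isolated dyads.

## Calibration problem sizes

Replicated calibration runs use a scaled-down design: 10 cohorts of 4
(the smallest size that occupies every receiver-role × sender-role
cell), six sessions at the study's 90-minute length, latent reactivity
fed directly to the estimator. This keeps 500-replicate null studies to
a few minutes on one CPU while preserving the crossed structure the
mixed model must absorb.

The null study for type-I calibration keeps the population's linkage
heterogeneity and removes only the condition effect: each cohort draws
a mean coupling from N(0.04, 0.02²) and each ordered pair scatters
around it with SD 0.02, identically distributed in both conditions.
Under this null the condition test is well calibrated (rejection near
0.05, near-uniform p-values). The degenerate null with *every* random
variance truly zero is also reachable (zero the three coupling
parameters) and is measurably conservative — component estimates are
truncated at the nonnegativity boundary, so the contrast SE absorbs
only the upward half of their sampling noise (≈9% SE inflation in that
configuration). This boundary effect is a property of nonnegative
variance-component estimation, not of this implementation, which
matches the exact cohort-mean t-test (rate and df) on designs with a
genuinely positive cohort variance.

Session-1 condition differences injected at 0.08 are detected with high
power, and declining coupling yields the expected negative
within-condition slope.

## Known limitations

- The exact random-effects list and df method of the original analysis
  live in its unavailable supplement; the defaults here (five crossed
  intercepts, Satterthwaite on the variance scale) are documented
  choices, with the structure config-driven so alternatives can be
  added.
- The artifact rule is a stand-in for unpublished proprietary
  algorithms and manual editing; thresholds are exposed in config.
- Whether the 30-s readability rule counts contiguous or total clean
  time is ambiguous in the source description; the longest single run
  is used.
- The 3-SD outlier screen is applied once, not iterated; the pass-2
  (8 SD / 2.5 SD-to-nearest) parameters generalize an ad-hoc removal
  of two extreme scores and are exposed in config.
- Estimates enter the mixed model unweighted; weighting by triple count
  is available as a sensitivity option in principle but not wired into
  the CLI.
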