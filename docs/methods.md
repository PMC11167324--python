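# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `bpcoach`.

## Domain conventions

* **Sessions.** A BP session is 1–3 consecutive cuff readings; the session
  value is their component-wise mean. The protocol asks for 3 readings, but
  sessions with fewer are kept and averaged over what exists; empty sessions
  are invalid.
* **Categories.** Controlled (SBP < 130 and DBP < 80), stage 1 (SBP 130–139
  or DBP 80–89), stage 2 (SBP ≥ 140 or DBP ≥ 90), applied to real-valued
  session/window means with no pre-rounding. The three categories partition
  the plane and are monotone in both pressures.
* **Critical readings.** Strictly above 180/110 (high) or strictly below
  90/60 (low) on session means. High and low share one consecutive counter;
  the distinction only matters for messaging.
* **Study weeks.** Participant-anchored 7-day blocks from each participant's
  first study day (week w = days 7(w−1)+1 … 7w). Calendar-anchored weeks are
  deliberately not used: enrollment is rolling, and every per-week quantity
  (outcome windows, engagement, the escalation rate limit, recommendation
  cadence) is defined relative to the participant's own timeline.
* **Missingness.** Absent values are recorded as absent (blank CSV cells),
  never as sentinel numerics; imputation is a modelling concern only.

## Personal model and factor ranking

Each participant's aligned dataset pairs every BP session with features
computed strictly before the session: wearable factors (steps, active
minutes, sleep duration, resting heart rate) averaged over the trailing
`window` days (default 1, configurable to 7 for weekly aggregates), and
questionnaire factors (stress, mood, alcohol, red meat, fruits/vegetables,
salt) taken from the previous day's answer — the questionnaire covers the
prior 24 h, so the previous-day entry is the most recent answer that predates
the session. Features are standardized within participant; constant or
never-observed columns are flagged and excluded from ranking; missing
standardized values are mean-imputed (zero) at fit time. Rows with no
observed features are dropped, and a dataset can legitimately be empty
(an "insufficient data" state, not an error).

The predictor is a multi-output ridge regression (default `alpha = 1`) from
standardized features to session-mean SBP and DBP. Ridge was chosen for
determinism, robustness at the small per-patient sample sizes the weekly
cadence produces, and interpretability; the interface (fit → rank) is
model-agnostic so other regressors can be substituted.

Factor impact is permutation importance on the SBP predictions: each factor's
column is shuffled `R = 20` times and the mean MSE inflation is mapped to a
mm Hg-per-SD magnitude via `√(max(ΔMSE, 0)/2)` — exact for a linear model
with orthonormal standardized features, where permuting a coefficient-β
column inflates MSE by 2β² in expectation. SBP is the primary score (the
headline outcomes are SBP-led); the DBP magnitude breaks ties, then
alphabetical factor name. Permutation streams are keyed by factor *name*, so
rankings are invariant to dataset column order. Below `min_rows = 14` aligned
rows (about two weeks of data) the model is not fitted and the coach falls
back to a generic rotation (activity → sleep → salt → stress).

## Coach

A 37-item catalog maps every factor to concrete recommendations (counts per
factor family: steps 6, active minutes 4, sleep 6, resting heart rate 2,
stress 5, mood 2, alcohol 3, red meat 3, fruits/vegetables 3, salt 3); the
catalog is replaceable via the API. Selection picks the top-ranked factor;
within a factor, unsent items are preferred (lowest id first), then the
least-sent. A factor whose last two check-ins were refusals at difficulty
≥ 4 rests for two weeks in favour of the next-ranked factor — an
operationalization of matching advice to ability; the rule is configurable
and off when `skip_rule=False`. One recommendation per active
participant-week, delivered at week end with a BP progress summary (current
week's mean and delta versus the previous week; marked unavailable when a
week has no sessions, in which case the recommendation is still sent).

## Safety monitor

A per-participant state machine processed over chronologically ordered
sessions: non-critical resets the counter; the first critical in a row
prompts a re-measurement (which arrives, if at all, as an ordinary session);
any further consecutive critical escalates unless a notification was already
sent that participant-week, in which case the escalation is recorded as
suppressed. "In a row" counts sessions, not days, and the counter carries
across week boundaries. The machine is verified against a brute-force
simulator on all critical/normal sequences of length ≤ 6 across several
week layouts.

## Synthetic cohort generator

The generator emulates the study conditions end to end; its defaults are the
conditions every test runs under.

* **Cohort.** 141 participants, 24 weeks, baseline category mix 38/48/55
  (controlled/stage 1/stage 2), onboarding staggered over ~65 weeks.
  Baseline BP is drawn per category from normals centred at 121.4/74.2,
  128.8/82.2, and 141.9/89.4 mm Hg (SDs 6.1/4.4, 7.1/6.4, 9.3/8.0),
  rejection-sampled to stay in-category; 83.7% carry a medication flag.
* **Ground truth.** Each patient plants a linear lifestyle → BP model:
  session-mean SBP = baseline + Σ β_f·z_f(previous day) + N(0, 6 mm Hg),
  with β in mm Hg per population SD, physiologically signed (more steps/
  sleep lowers BP; more salt/stress/alcohol raises it). By default all
  factors get small magnitudes (0.1–0.8) and 2–4 salient factors get
  1.5–3.5; a recovery-test mode plants one dominant factor at ≥ 3× all
  others. DBP carries 0.6× the SBP effect. Sessions expand to 3 readings
  with ~3 mm Hg within-session jitter.
* **Behaviour streams.** Latent daily factor values always exist (steps
  log-normal around 8000; continuous features normal; ordinal questionnaire
  items discretized latent normals, the latent value feeding the BP model
  and the rounded 1–5 value being recorded). Missingness only hides
  records: weekly per-task participation Bernoullis (BP 0.93, wearable 0.94,
  questionnaire 0.88 — the observed weekly engagement rates) with daily
  subsampling inside participating weeks, and 1–2 sessions on measuring
  days.
* **Adherence.** Check-in difficulty is uniform on 1–5; follow probability
  is logistic, strictly decreasing in difficulty, with the intercept solved
  (Brent) so the marginal follow rate over the uniform mix is 63.64%. A
  followed recommendation shifts the target factor 0.4 SD in its healthy
  direction starting the following week; shifts decay by 0.85/week without
  reinforcement and saturate at ±2 SD. This yields follow-difficulty
  separation (followed ≈ 2.5, refused ≈ 4.0 mean difficulty) and a negative
  cohort SBP trend of a few mm Hg by week 12 — directionally faithful,
  smaller than real-world effects, which is acceptable because no magnitude
  claims are attached to the simulation.
* **Dropout.** Constant per-week hazards per phase, solved from cumulative
  targets (9.2% by week 12; 20.3% weeks 12→24). Withdrawn participants emit
  nothing further.
* **Safety events.** Rare 2-day hypertensive spike episodes (daily start
  probability 6×10⁻⁴, +45/+25 mm Hg) generate occasional consecutive
  criticals so the escalation pathway is exercised at roughly the observed
  frequency.
* **Determinism.** Every draw comes from a stream keyed
  `SeedSequence([seed, participant, week, stream])`: identical configs give
  byte-identical files, adding participants never perturbs existing ones,
  and the file replay draws identically to generation.

What the generator does **not** emulate: day-of-week and seasonal structure,
autocorrelated behaviour, measurement-time-of-day effects on BP,
regression to the mean (baselines are true parameters, not noisy selections),
white-coat effects, medication changes, and correlated missingness (e.g.
disengagement preceding dropout). Passing tests therefore demonstrate the
engine's correctness and the analytics' arithmetic on data with the assumed
structure, not clinical effectiveness.

## Closed loop and replay

Generation *is* the closed loop: each week the generator emits data, the
engine (dataset → ridge → permutation ranking → coach) selects the
recommendation from data observed so far, the synthetic participant answers
the midweek check-in, and the follow/refuse outcome feeds the next week's
behaviour. The `run` step replays the identical engine over the written
files — with the ground-truth file standing in for the participants when
check-ins are simulated — and reproduces the same event logs; `analyze`
depends only on files. The engine sees exactly the recorded (rounded) values
in both paths.

## Outcome analytics

* Windowed means are unweighted over all session means in the included weeks
  (morning and evening weighted equally); participants lacking a baseline or
  follow-up window are excluded from that horizon (completer analyses).
* Paired *t*: `t = mean/(sd/√n)`, `df = n−1`, two-tailed p from the *t*
  distribution, 95% CI `mean ± t₀.₉₇₅·se`. Degenerate zero-SD deltas give
  `t = ±∞, p = 0` (or `t = 0, p = 1` when the mean is also zero); `n < 2`
  is an error, and single-participant subgroups report `n` with statistics
  unavailable.
* McNemar: uncorrected `χ² = (b−c)²/(b+c)` on the discordant counts of each
  category's in/out dichotomization (1 df); exact mode is the two-tailed
  binomial `2·P(Bin(b+c, ½) ≤ min(b,c))` capped at 1; `b+c = 0` gives
  (0, 1). The exact form is the more conservative; the two can disagree only
  in a hairline band around the significance threshold.
* Responders use the inclusive rule baseline − follow-up SBP ≥ 5 mm Hg
  (the tabled form of the threshold; SBP only).
* Rounding for reporting: percentages to 1 decimal; the check-in follow rate
  to 2 decimals; stage-2 down-movement to the nearest integer. Overall
  responder rates are reported to 1 decimal and subgroup responder rates as
  integer percents, matching the precision conventions of trial tables.
  Internal computation is full precision.
* Escalation summaries count `escalate` actions only, with unique-patient
  rates over the completer population; engagement denominators are the
  participants still active each week.

## Problem sizes

The default test and acceptance runs use the full study-scale conditions
(141 participants × 24 weeks for the closed loop; 200 patients × 12 weeks
for the recovery study; exhaustive length-≤6 sequences for the safety
oracle; 1000 random draws for the paired-*t* reference check; all
discordant tables b, c ≤ 12 for McNemar). The reference-cohort analytics run
on 128- and 102-participant fixtures reconstructed from published marginal
counts; those builders live in `bpcoach.datasets` and are labelled synthetic.

## Known limitations

* The McNemar statistics printed in some published transition tables cannot
  be derived from marginals alone; the package computes the standard test
  from paired data and makes no attempt to match externally printed χ²
  cells.
* The simulated BP effect sizes are smaller than those reported for real
  cohorts; only the direction of change is asserted anywhere.
* No regression-to-the-mean adjustment, causal estimation, or
  multiple-testing correction is performed, by design.
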