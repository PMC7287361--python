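# Methods

This note records the models, parameter choices and numerical decisions
behind `dyadsync`, and what the synthetic-data studies do and do not show.

## 1. Experimental design emulated by the generator

Each synthetic experiment follows the live observational-conditioning
protocol: `n_dyads` same-sex demonstrator–observer pairs (default 69) run
four blocks. A block's **learning phase** presents six CS+ and six CS−
images in strict alternation (first valence random), 6 s each, separated by
inter-trial intervals drawn uniformly from 10–16 s; four of the six CS+
presentations, chosen uniformly without replacement, end with a shock to
the demonstrator at CS offset. The **testing phase** presents each CS seven
times in random order; only the final CS+ is reinforced (now to the
observer). Roles reverse after half the blocks; person A observes the first
half, person B the second. Strict alternation in the learning phase is an
interpretive choice (the protocol wording admits a probabilistic reading);
it is isolated in `make_schedule`.

Phases begin with a 5 s quiet lead-in (room for baseline windows) and end
with a 12 s tail (room for SCR decay and scoring windows).

## 2. The generative signal model

Phasic skin conductance is modelled as a superposition of four parts:

1. **Event-locked SCRs.** Each response is a peak-normalised difference of
   exponentials (Bateman form) with rise 0.75 s, decay 2.5 s and 1 s
   latency — the canonical phasic-EDA shape. Default peak amplitudes:
   shock 0.8 µS, CS onsets 0.3 µS (equal for CS+ and CS−, so learning-phase
   differentiation is null by construction and cannot confound the
   specificity analysis), spontaneous events 0.4 µS. Stimulus responses are
   emitted with probability 0.55 (SCR non-response is ubiquitous in real
   data) and amplitudes carry mean-one lognormal jitter (log-sd 0.4; 0.8
   for spontaneous responses, which are the more variable in vivo).
2. **Spontaneous (nonspecific) SCRs.** A Poisson process at 6 events/min.
3. **Slow drift.** A stationary Ornstein–Uhlenbeck process (sd 0.25 µS,
   timescale 10 s) standing for residual slow fluctuation that imperfect
   tonic removal leaves in phasic estimates. Without it, z-scored traces
   sit on a flat shared baseline and any two dyads produce block-like
   recurrence structure regardless of coupling.
4. **Measurement noise.** White, sd 0.10 µS *referred to the 8 Hz analysis
   band* (per-sample sd is scaled by √(fs/8) so the generation rate does
   not change the analysis-band noise level).

### Coupling: episodic mirroring

The observer's coupling to the demonstrator is governed by one dyad-level
parameter κ ∈ [0, 1]. A two-state Markov chain with stationary probability
κ and ~90 s persistence decides, event by event, whether the observer is
currently *coupled*:

* **Coupled events** copy the demonstrator's response exactly — same
  amplitude, delayed by the 1 s coupling lag with only 0.15 s timing
  jitter. All demonstrator events participate: CS-locked, shock-locked
  (the social UCS) and spontaneous arousal alike.
* **Uncoupled events** are replaced by an independent response drawn from
  the same marginal distribution: own amplitude draw, own non-response
  coin, 4 s timing jitter; uncoupled spontaneous events move to a fresh
  uniform time.

The slow drift is mirrored analogously: the observer's drift is
κ·(demonstrator's drift, read at a lag that itself wanders slowly — an OU
process with sd 1 s and 30 s timescale) plus √(1−κ²) of an independent
drift, preserving the stationary variance.

Two properties motivated this construction over simple per-event amplitude
mixing. First, mixing leaves the four CRQA metrics nearly flat in κ
(recurrence matching requires whole embedded-window agreement, which a
diluted amplitude correlation barely changes), whereas episodes of exact
mirroring create diagonal-line mass in proportion to the time spent
coupled. Second, mixing makes single-trace statistics (event density,
amplitude spread, smoothness) depend on κ, which leaks the observer's own
coupling into *pseudo*-pairings and biases the permutation null; under the
mirroring mixture the observer's marginal statistics are κ-invariant, so
coupling is visible only *between* the signals — exactly the construct.

At κ = 1 with lag, jitters, noise, drift and spontaneous processes
silenced, the observer's learning trace equals the demonstrator's sample
for sample; at κ = 0 the mean lag-0 correlation between members is ≈ 0.1
(not exactly 0: both still respond to the same stimulus schedule).

### The coupling→learning link

Observer testing-phase CS-onset amplitudes follow

    a = max(0, β₀ + (β_cs + γ·κ) · c · e^(−λ·k)) · ε,

with deviation-coded CS `c` (±0.5), within-CS presentation index `k`
(extinction rate λ, default 0.1/presentation), baseline β₀ = 0.5 µS,
κ-independent differentiation β_cs = 0.05 µS, coupling gain γ = 0.5 µS
(the default, moderate link), and mean-one lognormal trial noise ε
(multiplicative, keeping amplitudes positive; the additive reading would
only shift both CS levels equally). The reinforced final CS+ adds a shock
response. Ground-truth κ per dyad is stored alongside the signals.

All generator defaults were fixed by calibrating against the package's own
structural requirements — κ = 0 independence, monotone κ→correlation, all
four CRQA metrics increasing in κ — before any acceptance-level study was
run, and were not revisited afterwards.

## 3. Preprocessing

CRQA consumes each learning phase downsampled to 8 Hz by non-overlapping
block means (a crude anti-alias; plain decimation would fold noise) and
z-scored per signal per phase (sample sd, ddof 1). Constant traces raise a
`DegenerateSignalError` rather than emitting zeros, so broken inputs are
caught, not averaged over.

Trial scoring uses the raw µS trace: amplitude = max over 0.5–4.5 s
post-onset minus the mean over the 1 s pre-onset baseline, floored at zero,
then log(1+x) transformed. These windows and the transform are conventional
event-related EDA practice; the floor encodes that an SCR is a rise.
Observer responses to the social UCS use the same rule anchored at shock
delivery. These scoring choices are stated as package defaults, not as a
reconstruction of any particular laboratory's unpublished scoring rules.

## 4. CRQA parameter selection and metrics

* **Delay:** first local minimum of average mutual information (10
  equiprobable bins) over lags 1–40 samples, where "local minimum" means
  smallest within a ±2-lag neighbourhood (this suppresses bin-resonance
  wiggles; exactly periodic test signals additionally need dithering
  because they occupy too few distinct values for quantile binning).
  Fallback: the global AMI minimum. Dyad delay = max over the two members.
* **Dimension:** smallest m ≤ 10 whose false-nearest-neighbour fraction
  (Kennel criteria, rtol 10 and atol 2 attractor radii; distances at
  rounding-error scale count as true neighbours) drops to ≤ 2%; the atol
  test is what keeps white noise at max dimension. For series longer than
  250 points the FNN fraction is estimated from 250 evenly spaced query
  points against the complete neighbour pool. Dyad dimension = max over
  members.
* **Radius:** bisection towards the 3% midpoint of the 2–4% recurrence
  band, ≤ 60 iterations, early-stopped within 0.1 percentage points. For
  matrices above 5·10⁵ entries the bisection runs against a sorted
  deterministic subsample (~2.5·10⁵ distances) and the achieved RR is then
  verified on the full matrix, falling back to full bisection on a miss.
  An unattainable band (e.g. massive ties) raises an error carrying the
  closest achievable RR; such dyad-blocks are logged and excluded.
* **Metrics:** RR, DET (lmin 2), LAM (vmin 2), maxL (any length) and rENTR
  = ENTR / ln(#distinct diagonal line lengths ≥ 2), 0 when fewer than two
  distinct lengths occur; unnormalised ENTR is also reported. No Theiler
  window — the matrix compares two different people, so the near-diagonal
  is signal. Note the standard DET formula makes the all-ones matrix score
  slightly below 1 (corner diagonals of length 1 are excluded from the
  numerator only). Euclidean norm on z-scored signals; radius in z-units.

## 5. Synchrony component and alternative predictors

The four metrics are standardised column-wise and decomposed by PCA
(scikit-learn) over all dyad-blocks pooled; PC1's sign is fixed so its
loadings sum positive, and scores are standardised. Per-block PCA would
fragment the component, so pooling is deliberate. The three rival
predictors are the mean transformed UCS response, the learning-phase CS
differentiation (mean CS+ − CS− transformed amplitude), and the maximum
Pearson correlation over observer-trailing lags 0–10 s (the observer reacts
to what they see, so negative lags are not searched; the maximum-over-lags
reading is configurable).

## 6. Inference

The trial-level model is `amplitude_tx ~ cs_code * predictors` with varying
intercepts and CS slopes (and their correlation) by observer, fitted by
REML (statsmodels MixedLM, L-BFGS) with Wald 95% intervals; a single-level
OLS backend exists for degenerate designs and cross-checks. Continuous
predictors are standardised at fit time (zero variance is an error);
categorical regressors are deviation coded ±0.5. Rank-deficient designs
fail before fitting with the aliased terms named. Posterior-sampling
engines are not bundled: intervals plus permutation p-values carry the
inferential weight here, and Bayes-factor machinery is out of scope.

The stability model adds CS×block-within-role, CS×starting-role and
CS×synchrony×trial terms (block and role deviation coded, trial index
standardised).

**Pseudo-dyad null.** Each permutation draws a derangement over dyad ids
(an observer is never re-paired with their own demonstrator; block
structure is preserved) and re-runs CRQA → PCA → the multilevel model from
scratch — radii are recalibrated per pairing because calibration is
pair-specific, while per-signal delay/dimension selections are memoised
(they are deterministic per signal, so this is exact). p = (1 + #{null ≥
observed}) / (n_valid + 1).

## 7. Validation studies and their problem sizes

The acceptance-level studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` run at sizes chosen to exercise the full method on
one CPU:

* **Calibration:** 20 dyads at the default 32 Hz generation rate,
  full-length learning phases; mean achieved RR reported against both band
  edges.
* **Recovery:** the full 69-dyad × 4-block design (8 Hz generation,
  learning traces truncated to 160 s before z-scoring); per-dyad mean PC1
  against true κ, threshold r > 0.3.
* **Interaction operating characteristics:** 100 replicates of a
  *strong-contrast* scenario — κ ∈ {0.1, 0.9} equiprobable, γ = 3.5 µS,
  β₀ = 1.2 µS, no extinction — at 69 dyads × 2 blocks, traces truncated to
  144 s (power: CS×PC1 interval excludes zero in ≥ 80/100); and 100 null
  replicates (γ = 0, 1 block) for interval coverage (≥ 90/100). The
  contrast scenario exists because with uniformly distributed κ the
  per-block synchrony estimate is too noisy for a desk-scale power
  demonstration; the default generator remains the moderate uniform-κ
  condition.
* **Specificity:** the permutation test on 32 strong-contrast dyads × 2
  blocks with 200 derangements (p < 0.05); calibration under κ ≡ 0 with 20
  meta-replicates of 8 dyads × 100 permutations at 48 s traces using the
  OLS backend — permutation-p calibration is a property of the
  exchangeable pairing scheme, not of the trace length or estimator, which
  is why the cheapest configuration suffices there.

Truncating traces and reducing dyad counts trades statistical resolution
for runtime; the thresholds above were met with margin in pilot runs at
these exact sizes.

## 8. What passing these studies does and does not show

The generator reproduces the protocol's timing and the gross statistical
anatomy of phasic EDA (kernel shape, non-response, spontaneous arousal,
slow drift, trial-noise scale), and it embeds coupling as literal episodic
mirroring. Real interpersonal synchrony is surely subtler: bidirectional,
nonstationary across trials, entangled with respiration and movement, and
not reducible to one scalar per dyad. Passing parameter recovery here
therefore shows the *pipeline* is sound — that CRQA + PCA + multilevel
regression can detect and localise a coupling→learning link when one
exists and stays quiet when none does — not that any particular human
dataset contains such a link. rENTR is the weakest recovery channel: its
dependence on coupling is the least monotone of the four metrics and flips
sign in some generator regimes (very long dominant lines concentrate the
line-length distribution).

Other known limitations: raw-to-phasic decomposition, artifact rejection
and tonic dynamics are out of scope (the generator emits phasic signals
directly); the lagged-correlation predictor searches positive lags only;
Wald intervals at few observers (< ~30) can undercover slightly; and the
per-dyad embedding-parameter combination rule (max over members) is one of
several defensible choices and is isolated behind `pair_delay`/`pair_dim`.
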