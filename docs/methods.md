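# Methods

This note documents the models and numerical choices behind `femgpipe`: the
preprocessing chain, the inferential machinery, the power routines, and the
synthetic cohort generator, along with what the shipped tests do and do not
establish.

## Signal conditioning

The passband is specified as 30–500 Hz at a 1000 Hz sampling rate; since
500 Hz is Nyquist, only the lower edge requires a realized filter. The chain
is a 4th-order Butterworth high-pass at 30 Hz plus an IIR notch at 60 Hz
(default Q = 10, −3 dB width 6 Hz single-pass). Zero phase is essential —
mimicry latencies are on the order of a few hundred milliseconds — so the
chain is applied via its squared magnitude response (the forward–backward
equivalent) in the frequency domain, on a reflection-padded copy of the
signal (5 s each side). This confines the notch's ringing to the padding;
away from edges it is numerically identical to `filtfilt`. A note on the
notch width: a very narrow notch (e.g. Q = 30) cannot cleanly remove a
60 Hz tone from a short record — the rectangular-window leakage of a finite
tone falls outside the notch — and any linear filter leaves onset/offset
transients on a finite tone, so the filter tests assert steady-state
suppression (residual < 1% excluding 300-ms edges; measured ≈ 0.07%).

Rectification uses the magnitude of the analytic signal,
`env = |x + iH[x]|`, computed over the whole continuous recording with
reflection padding (2000 samples) so analytic-signal edge artifacts stay
out of every epoch. Unlike absolute-value rectification this preserves the
total signal energy (Σ env² = 2 Σ x² for zero-mean input, verified against
an independent frequency-domain Hilbert oracle).

## Epoching and reduction

Epochs span [−2000, +1500) ms around stimulus onset (half-open windows,
0-based sample indices throughout). Trials too close to a recording edge
are flagged unusable and reported, never silently dropped; the accounting
invariant accepted + rejected + unusable = 144 holds per participant and
channel.

Baseline correction subtracts the mean over [−2000, 0) ms per trial and
channel; after correction that mean is zero to numerical precision.

Artifact rejection slides a 250-ms window in 50-ms steps across each
baseline-corrected epoch (66 windows per epoch), pools all window means of
a channel across the participant's epochs, and rejects an epoch on that
channel when any window deviates from the pooled mean by more than 3 pooled
SDs. The stated rejection parameters give the window *step* (50 ms); the
window *length* is not stated and is set to 250 ms, matching the smoothing
scale — a 50-ms window on a rectified envelope would be noise-dominated.
The rejection statistics are pooled per channel because the reference
population of the "3 SD from the mean" criterion is not otherwise defined,
and channels are treated independently: a rejection on the corrugator does
not discard the zygomaticus trial. Increasing the SD multiplier can only
decrease the number of rejections (tested). A pooled SD of zero (degenerate
identical-constant epochs) rejects nothing and logs a warning.

Smoothing is a centered moving average forced to an odd sample count
(251 samples for 250 ms at 1000 Hz) with symmetric padding. Accepted trials
are averaged per channel × emotion, and the [0, 1500) ms post-onset course
is reduced to six 250-ms bin means with half-open edges [250b, 250(b+1)) —
this reconciles the mixed inclusive/exclusive bin labels that otherwise
appear in reports of this design. Processing order is baseline-correct →
reject → smooth → average → bin.

## Mixed ANOVA and planned contrasts

The design is one between-subjects factor (group, 2 levels, equal n) fully
crossed with two within-subject factors (emotion and time bin, 6 levels
each). The decomposition is the classical balanced univariate one, with
subjects nested in groups and three within-subject error strata
(emotion × S(group), time × S(group), emotion × time × S(group)). Balance is
required and enforced; unbalanced cohorts are an error by design, not a
fallback.

Sphericity is assessed per stratum with Mauchly's W on the within-group
pooled covariance of orthonormal contrast scores (Kronecker contrasts for
the interaction stratum), using the first-order chi-square approximation
with scaling factor (2p² + p + 2)/(6p) and error df n − k. The
Greenhouse–Geisser estimate is ε̂ = (Σλ)²/((m−1)·Σλ²) on the same contrast
covariance's eigenvalues, clipped to [1/(m−1), 1]. The df correction is
applied to a stratum when Mauchly's p < α *and* ε̂ < 0.75; otherwise
uncorrected dfs are reported (ε̂ is always reported). With fewer subjects
than contrast dimensions the contrast covariance is singular; W is then
reported as 0 with a warning and the eigenvalue-based ε̂ still applies.
Partial eta squared is SS_effect/(SS_effect + SS_stratum-error).

Each planned contrast is the 1-df group difference in one emotion's mean
amplitude (pooled over the six bins), with
SS = L²/(1/(n₁T) + 1/(n₂T)), tested against the emotion × time × S(group)
stratum mean square with that stratum's GG-corrected df; the effect size is
r = √(F/(F + df_err)). Alpha is left at 0.05 across the 12-contrast family
(no multiplicity adjustment, matching the reported analysis). P-values are
two-tailed and formatted to 3 dp with "<0.001" below that.

**Known property of this contrast construction.** The denominator is a
purely within-subject interaction mean square. The test is therefore
exactly calibrated only when binned cell values are independent given the
design effects. Two features of any realistic pipeline violate that:
the 250-ms moving average correlates adjacent bins, and any
subject-by-condition variability (e.g. stable individual differences in
mimicry strength) adds numerator variance the denominator does not see. On
simulated cohorts with no group effect the contrasts consequently reject
well above the nominal 5% (≈ 15–20% from smoothing alone; more with
realistic tonic nonstationarity), while at the level of independent binned
data the test is calibrated (measured 6.5% over 400 null simulations). The
package reproduces the method as reported rather than repairing it; treat
the contrast p-values as anticonservative for between-group inference.

## Power analyses

*Repeated-measures interaction.* Power is P(F′ > F_crit) under the
noncentral F with λ = f²·N·m·ε/(1−ρ), df₁ = (k−1)(m−1)ε and
df₂ = (N−k)(m−1)ε. ρ (correlation among repeated measures) and ε default to
0.5 and 1 — the conventional defaults of the standard power software for
this test. The search ascends in steps of k so groups stay equal. With
f = 0.25, α = 0.05, power 0.8, k = 2, m = 6 the minimum total N is 20.

*Correlation.* The exact two-tailed power integrates the density of the
sample correlation under the bivariate-normal model (log-gamma form with
the Gauss hypergeometric ₂F₁; quadrature with an explicit breakpoint at the
density peak). The rejection region |r| > r_crit comes from the t test on
n − 2 df. The bias-corrected Fisher-z approximation
(z_ρ + ρ/(2(n−1)), SE 1/√(n−3)) is available as a documented fallback and
agrees at the tested operating points. ρ₁ = 0.31 at power 0.8 requires
n = 79; the sensitivity analysis at n = 30 (bisection to 10⁻⁴, returning
the upper bracket so the reported ρ attains the target power) gives
ρ_min ≈ 0.485. A 10 000-sample Monte-Carlo check at (ρ = 0.31, n = 79)
reproduces the exact power within simulation error.

## Questionnaire scoring

OSI function items (0–4) sum into internal emotional regulation (8 items),
external emotional regulation (3), social influence (9) and sensation
seeking (3); ISAS section-II items (0–2, 39 items) sum in triples into 13
functions (0–6 each), which aggregate into the interpersonal factor
(autonomy, interpersonal boundaries, interpersonal influence, peer-bonding,
self-care, revenge, sensation seeking, toughness) and the intrapersonal
factor (affect-regulation, anti-dissociation, anti-suicide, marking
distress, self-punishment). Item identifiers are positional (`item_01`…)
with the standard ISAS layout (item k belongs to function (k−1) mod 13);
the maps are configuration data overridable from a two-column TSV. Missing
or out-of-range items are errors naming the item — no imputation.

## Synthetic cohort generator

The generator defines the study conditions all end-to-end tests run under:
60 participants (30 per group), 144 trials (24 identities × 6 emotions,
random order), onsets every 4500 ms (1.5-s stimulus + 3-s inter-trial
interval) after a 20-s neutral lead-in, 20-s tail, 1000 Hz, everything
deterministic given one seed (cohort files are byte-identical across runs).

Per channel the model is multiplicative amplitude modulation of tonic
surface EMG:

* **Carrier**: zero-mean Gaussian noise band-limited to 30–250 Hz, scaled
  to a tonic SD of 10 µV (corrugator) / 8 µV (zygomaticus).
* **Tonic nonstationarity**: a slow multiplicative wander
  `1 + s(t)`, where s is tanh-saturated low-pass Gaussian noise
  (cutoff 1.2 Hz, saturation 6, relative SD 0.6, hard-bounded at ≈ ±0.63).
  Resting facial EMG waxes and wanes with posture, respiration-coupled
  tension and spontaneous activity bursts; this term reproduces that
  nonstationarity. Its statistical role is important: the 3-SD/any-window
  rejection rule applied to *stationary* Gaussian tonic EMG rejects ~13% of
  clean epochs (66 near-Gaussian windows per epoch), far above the < 5%
  operating point reported for real data. A bounded wander widens the
  pooled rejection statistics the way real tonic variability does while its
  hard bound keeps clean epochs inside the 3-SD envelope; the saturation
  (rather than, say, lognormal modulation) is what prevents heavy tails
  from masquerading as artifacts. Its spectrum is broadband below ~1 Hz so
  it cannot phase-lock to the fixed 4.5-s trial grid.
* **Mimicry responses**: during [300, 1500) ms after each onset the local
  amplitude is scaled by a condition gain g with a 500-ms raised-cosine
  ramp (300-ms onset latency is a typical rapid-mimicry value). Defaults:
  corrugator anger 1.25 (contraction), corrugator happy 0.75 (relaxation —
  after baseline correction this yields the negative amplitudes
  characteristic of this muscle's response to happy faces), zygomaticus
  happy 1.10, all other cells 1.0. Participant gains jitter with SD 0.02.
  In the HNSSI group the corrugator anger and happy gains are attenuated
  toward 1 by α: g_eff = 1 + (1−α)(g−1), default α = 0.5, so the group's
  expected baseline-corrected response is (1−α) times the control
  response; α = 0 makes the groups identical (the null condition used in
  calibration tests) and α = 1 removes HNSSI mimicry entirely. The default
  gains were calibrated once so that the group attenuation is a
  medium-large standardized effect — reliably detected at n = 30 per group
  — while response excursions stay inside the rejection envelope, and were
  then frozen.
* **Interference and artifacts**: a 2 µV 60-Hz sinusoid with random phase,
  plus Poisson-placed (default 3 per channel per session) square-envelope
  amplitude bursts of 8–15× tonic SD lasting 100–400 ms. Bursts live inside
  the EMG band (a DC square pulse would be erased by the 30 Hz high-pass)
  and are unambiguously caught by the 3-SD rule.

Questionnaire responses for the HNSSI group are generated from latent
normal scores with target correlations to the participant's realized gain
for a linked muscle/emotion (defaults: OSI internal regulation ↔ corrugator
happy gain +0.4; OSI social influence ↔ zygomaticus happy gain −0.4; ISAS
peer-bonding ↔ corrugator anger gain −0.4), discretized through a Gaussian
copula into valid item responses; the rescored subscales preserve the
target correlation to within the copula's mild attenuation (verified at
n = 200). Untargeted subscales are independent noise. Controls receive no
questionnaires.

**What the generator does not emulate**: electrode impedance drift and
other 1/f instrumentation noise, motor-unit structure in the EMG spectrum,
emotion-specific response topographies beyond gain changes, trial-order
effects (habituation), or missing data. Passing end-to-end tests therefore
demonstrates that the pipeline recovers effects of the modeled kind at
realistic signal-to-noise, not that it is robust to every field artifact.

## Problem sizes in the shipped tests

The default test run uses scaled-down replicate counts chosen for a
desk-scale budget: the type-I calibration of the planned contrast uses 400
null simulations at the binned level (12 subjects × 36 cells each); cohort
recovery runs three full 60-participant cohorts (the session-scoped study
cohort plus two replicate seeds); the attenuation-ratio check uses 12
replicate participants per group; questionnaire-coupling checks use 200
gain-only participants; the Monte-Carlo validation of the exact correlation
power uses 10 000 samples. The acceptance script simulates one full clean
60-participant cohort.

## Known limitations

* The planned-contrast construction is anticonservative under realistic
  bin correlation (see above); it is reproduced, not corrected.
* Rejection is slightly selective against large genuine responses (the
  response adds to the window statistic), so measured group effects are
  mildly shrunk relative to the generative gains.
* The balanced-only ANOVA is a feature of the reconstructed analysis;
  missing cells or unequal groups require a mixed-model approach that is
  out of scope.
* Mauchly's p uses the first-order chi-square approximation; second-order
  corrections change p slightly for small samples (W, ε are unaffected).
* The exact-r integration assumes bivariate normality; heavy-tailed data
  would need a different sensitivity analysis.
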