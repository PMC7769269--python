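# femgpipe

Facial-electromyography (fEMG) analysis of **emotion mimicry**: when people
passively watch a face morph into an emotional expression, their own facial
muscles echo it — the corrugator supercilii (brow) contracts to angry faces
and relaxes to happy ones, the zygomaticus major (smile) contracts to happy
faces. `femgpipe` implements the complete analysis chain used to compare
this covert mimicry between a group with a history of non-suicidal
self-injury (HNSSI) and matched controls, together with a synthetic cohort
simulator so that every stage is testable without any recorded data.

It is intended for psychophysiologists who want a scripted, reproducible
version of this kind of two-channel event-related EMG study: signal
reduction, epoch statistics, the mixed-design ANOVA machinery, questionnaire
scoring, and the associated power analyses.

## What it computes

**Signal reduction.** Raw two-channel EMG (1000 Hz, µV) is band-limited
(30 Hz high-pass; the nominal 500 Hz upper edge is Nyquist) with a 60 Hz
notch, applied zero-phase, then rectified to a non-negative envelope via the
magnitude of the analytic signal, `A(t) = |x(t) + i H[x](t)|` (Hilbert
rectification, which conserves signal energy). Epochs spanning
[−2000, +1500) ms around each stimulus onset are baseline-corrected by the
2-s pre-stimulus mean, screened by a 3-SD sliding-window artifact criterion
(250-ms windows advanced in 50-ms steps, pooled per channel), smoothed with
a 250-ms moving average, averaged over the 24 trials of each of the 6
emotions, and reduced to six 250-ms bin means over the 1.5-s stimulus.

**Inference.** Per muscle, a balanced mixed ANOVA
2 (group) × 6 (emotion) × 6 (time bin) with the classical univariate
sums-of-squares decomposition, Mauchly's sphericity test per within-subject
error stratum and Greenhouse–Geisser df correction
(ε̂ = (Σλ)²/((m−1)Σλ²) on the orthonormal-contrast covariance eigenvalues)
when Mauchly p < α and ε < 0.75. Twelve planned group contrasts (one per
muscle × emotion) test the group difference in an emotion's mean amplitude
against the emotion × time × subject-within-group error stratum, with
effect size r = √(F/(F+df_err)). Questionnaire–mimicry associations are
Pearson correlations of OSI/ISAS subscale scores with each participant's
mean response amplitude.

**Power.** Repeated-measures interaction sample size from the noncentral F
distribution with λ = f²·N·m·ε/(1−ρ); Pearson-correlation sample size and
sensitivity from the exact distribution of the sample correlation under the
bivariate-normal model (bias-corrected Fisher-z available as a fallback).

**Simulation.** The `synthetic` module generates full cohorts — 30
participants per group, 144 trials each (24 identities × 6 emotions),
continuous 1000 Hz recordings — as amplitude-modulated band-limited noise
with bounded slow tonic wander, condition-specific mimicry gains
(attenuated in the HNSSI group for corrugator responses to anger and
happiness), 60 Hz line interference, burst artifacts, and questionnaire
responses correlated with each participant's realized mimicry gain.

## Worked example

```python
from femgpipe import SimulationConfig, simulate_cohort, analyze_recordings

cfg = SimulationConfig(n_per_group=30, seed=42, artifact_rate=0.0)
cohort = simulate_cohort(cfg)
bundle = analyze_recordings(
    [(p.recording, p.events) for p in cohort.participants],
    osi=cohort.osi, isas=cohort.isas)

print(f"rejection rate: {100 * bundle.rejection_rate:.2f}%")
cc = bundle.contrasts.set_index(["muscle", "emotion"])
for emo in ("anger", "happy"):
    row = cc.loc[("corrugator", emo)]
    print(f"corrugator/{emo}: F(1, {row.df_err:.2f}) = {row.F:.2f}, "
          f"p = {row.p:.4f}, r = {row.r:.3f}")
```

prints

```
rejection rate: 0.27%
corrugator/anger: F(1, 545.01) = 27.67, p = 0.0000, r = 0.220
corrugator/happy: F(1, 545.01) = 111.47, p = 0.0000, r = 0.412
```

— the simulated HNSSI group shows roughly half the control group's
corrugator contraction to anger and half its relaxation to happiness, and
both planned contrasts detect the attenuation. Fewer than 5% of clean
epochs are lost to the 3-SD artifact screen. (`df_err` here is the
GG-corrected error df of the simulated cohort; it scales with cohort size
and sphericity.)

The same pipeline runs from the command line:

```bash
femgpipe simulate cohort_dir --n-per-group 30 --seed 42
femgpipe analyze cohort_dir results_dir
femgpipe power
femgpipe score isas cohort_dir/isas.tsv isas_scores.tsv
```

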