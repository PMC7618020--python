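# Methods

## Markers

**Normalized LZ76 complexity (LZsum).**  For one channel of one 4-s epoch,
the samples are reduced to a binary sequence and parsed with the
exhaustive-history LZ76 production rule: scanning left to right, the word
starting at position *p* ends with the first symbol that makes
*s*[*p*:*p*+*m*] absent from *s*[0:*p*+*m*−1] (the copy source may overlap
the word being built); the trailing, possibly still-reproducible word also
counts.  The word count *c* is normalized as *c* · log₂*n* / *n*, i.e.
divided by the asymptotic word count *n*/log₂*n* of an equiprobable random
binary string, so the value reads as a fraction of maximal signal
diversity: IID noise ≈ 1 (the finite-*n* value can slightly exceed 1),
constant or periodic signals ≈ 0.  Per epoch, normalized values from a
random subset of 25 gradiometer channels are averaged; per subject, epoch
values are averaged over kept epochs.  The production implementation
delegates substring search to `bytes.find` with an O(1) extension shortcut;
the test suite holds it to exact agreement with a naive reference parser on
every binary string of length ≤ 12 and on random longer strings.

Binarization defaults to *hilbert-mean*: bit = 1 where the analytic-signal
envelope exceeds its epoch mean — the amplitude-based rule used in the
sleep/anaesthesia LZ literature this marker descends from.  A
*signal-median* rule (raw sample vs. channel median) is config-selectable.
Ties map to 0 — arbitrary but fixed, and immaterial for continuous data.
Both rules, hence LZsum itself, are exactly invariant to positive amplitude
scaling.  The channel subset is redrawn per epoch (a per-subject fixed
subset is available for variance studies), driven by one seeded generator
so reruns are bit-identical.  If fewer channels exist than the subset size,
all are used with a warning — the normal situation in scaled-down synthetic
runs.

**Theta–alpha ratio (TAR).**  Welch PSD per channel (Hann taper, 2-s
segments, 50 % overlap → 0.5 Hz resolution, giving five bins inside the
narrow 3–5 Hz theta band of a 4-s epoch); band power is the trapezoidal
integral over bins whose centers lie in the closed band.  TAR is
ratio-of-means: sensor-mean theta power over sensor-mean alpha power,
using **all** channels (no subsampling for this marker).  Mean-of-ratios is
config-selectable but unstable when individual channels lose alpha power;
the choice is recorded in the run manifest.  Epochs whose mean alpha power
falls below a relative floor (10⁻¹² of total power) are marked invalid and
excluded from the subject mean.  The theta band is deliberately 3–5 Hz,
not the conventional 4–8 Hz.

## Preprocessing

Polyphase anti-aliased decimation to 250 Hz (upsampling refused); zero-phase
4th-order Butterworth high-pass at 0.5 Hz; zero-phase IIR notch at 50 Hz
with quality factor 30 (the cutoffs are the standard resting-state choices;
zero-phase filtering preserves timing for epoching).  Epochs are
non-overlapping 4-s windows from sample 0, trailing partial window dropped.

Muscle-artifact rejection: per epoch, channel-mean log₁₀ band power in
55–100 Hz (above the notch, below the 125 Hz Nyquist), z-scored across the
subject's epochs; epochs with z > 3 are flagged in the kept-mask (never
deleted).  Two degenerate-case notes: a z-score over *n* epochs is bounded
by (*n*−1)/√*n*, so a lone outlier can only cross the 3-SD threshold when
the subject has ≥ 12 epochs; and a subject with a single epoch passes
through unfiltered with a warning.  Rejecting more than 50 % of epochs
triggers a loud warning.  Upstream hardware-bound denoising (SSS/MaxFilter,
head-position compensation, bad-channel interpolation, ocular artifacts)
is out of scope: the pipeline assumes such steps were applied before data
reach it.

## Statistics

Group comparison of LZsum uses Welch's unequal-variance *t* with
Satterthwaite fractional df.  TAR is checked with Shapiro–Wilk (α = 0.05);
because ratio distributions are typically right-skewed and non-normal, the
TAR group test is the Wilcoxon rank-sum.  The reported *W* is the sum of
pooled midranks of the **control** sample; *p* is exact by enumeration for
n₁+n₂ ≤ 20 without ties, otherwise the tie-corrected normal approximation
with continuity correction.  (Other software reports the Mann–Whitney *U*
under the same name; *U* = *W* − n₁(n₁+1)/2.)

The OLS battery (with intercept; categorical terms dummy-coded, reference =
control / first-alphabetical level) fits, one covariate pairing at a time:
each marker on group alone, group+age, group+site, plus LZsum on group+sex
and group+TAR — the TAR-adjusted model asks whether the complexity
difference is explained by arousal alone — and each marker on MMSE across
all participants and within patients only.  All tests are two-sided at
α = 0.05; complete-case per model; no multiplicity correction is applied to
verdicts, but Benjamini–Hochberg adjusted p values are emitted alongside
for transparency.

## Synthetic cohort

Each channel is an alpha sinusoid (frequency uniform in 8–12 Hz, random
phase per channel) plus a theta sinusoid (3–5 Hz) plus a stochastic
background: white noise spectrally shaped to 1/f^β (β = 1), passed through
an AR(1) filter with coefficient *a*, rescaled to unit SD, and multiplied
by `noise_sd`; a white sensor-noise floor at 0.1 × `noise_sd` is added.
The AR stage is the complexity knob: raising *a* smooths the signal without
changing band powers much, lowering LZsum; with `noise_sd = 0` the whole
stochastic part vanishes.  Optional muscle artifacts are Poisson-placed
0.5-s bursts of 55–100 Hz band-limited noise at 10× channel SD.  There is
no source-space forward model and no sensor geometry — all markers here are
sensor-level, channel-exchangeable statistics, so per-channel independent
oscillators suffice.

Defaults (control group): `alpha_gain` 1.0, `theta_gain` 0.55 relative to
the unit-SD background, `ar_coefficient` 0.55, `noise_sd` 1.0,
`artifact_rate` 0/min.  The patient group scales `theta_gain` by 1.5 and
shifts `ar_coefficient` by +0.06 — directions chosen so patients have
higher TAR and lower LZsum, magnitudes calibrated once so the group
difference is reliably detected at the study size of 83 subjects per group.
Demographics: ages uniform on 54–83 in both groups (age-matched design),
sexes drawn at 56 % male, sites alternating within group (near 50/50).
MMSE is Gaussian per group (control 28.88 ± 1.3 clipped to 25–30, patient
26.07 ± 2.8 clipped to 17–30, everything clipped to 0–30 and rounded), with
the subject-level deviation linearly coupled (weights 0.5/0.5 plus 0.707
noise, unit total variance) to the subject's standardized theta/alpha gain
deviation and AR deviation, so lower MMSE goes with higher TAR and lower
LZsum both between and within groups.

Seeding is a counter-based split of one master seed (subject *i* gets
`SeedSequence(master, spawn_key=(i,))`), so cohorts are bit-reproducible
and subjects independent.

**What passing tests do and do not show.**  The simulator emulates the
spectral shape, group effects, covariate links and artifact structure of an
eyes-closed MEG cohort, which is enough to validate the pipeline's
statistical behaviour (type-I error, power, sign recovery, determinism).
It does not emulate volume conduction, inter-channel correlation, site- or
age-dependent signal differences, non-stationarity within recordings, or
realistic amplitudes in tesla/meter — so passing tests certify the
*pipeline*, not any physiological claim, and the synthetic effect sizes are
larger than what real MCI cohorts show (synthetic *t* statistics and R²
values come out correspondingly larger).

## Problem sizes used in validation

Simulation-based checks run at reduced montage and duration, chosen as the
smallest conditions that leave the markers well-defined: 4 channels × 8 s
(two epochs) per subject for the type-I study (200 null cohorts, 30 per
group) and the recovery study (100 effect cohorts, 83 per group; direction
and MMSE-slope sign recovered ≥ 90 % of seeds, Welch-*t* power ≥ 80 %).
The acceptance script uses 32 channels × 60 s (15 epochs), which keeps the
25-channel subsample active.  Full-montage runs (204 channels, minutes of
data) use identical code paths — only array sizes change.

## Known limitations

- The artifact detector is a simple within-subject z-score on
  high-frequency power; it assumes most epochs are clean and cannot flag a
  lone outlier for subjects with fewer than 12 epochs.
- The Wilcoxon exact path is limited to small tie-free samples; everything
  else uses the asymptotic approximation.
- `read_fif` trusts channel-type metadata in the file; no coil-type
  inspection is performed.
- The container stores float32; round-trips are bit-exact at float32
  precision, not float64.
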