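# Methods

This note documents the models, estimators and design choices behind
`stresslab`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design emulated by the generator

Two groups of 26 participants (dynamic vs static digital interview
committee) each prepare five discourses; the preparation phase is capped at
120 s. Signals: 16 scalp EEG channels (10/20 montage) + 2 EOG, one ECG and
one EDA channel, natively 1000 Hz; eyes-open and eyes-closed baselines of
120 s precede the task. These constants are hard-coded in
`stresslab.constants` and exposed through `CohortSpec.native()`.

Three signal profiles exist because the full native cohort is ~0.5 GB and
minutes of compute: `native()` (1000 Hz, 120-s segments, all channels),
the default (250 Hz, 30-s segments — desk scale), and `fast()` (128 Hz,
12-s baselines, 10-s preparation segments, the eight analysis channels
plus EOG) used by the simulation studies, which need hundreds of cohorts.
Problem sizes in the test suite and acceptance script (200 cohorts for
direction recovery, 1000 replicates for type-I calibration, 200 segments
for SCR detection) were chosen once as the smallest sizes at which the
binomial/Monte-Carlo noise of the measured rates is well inside the margins
being checked.

## Synthetic signal models

**Response times.** Truncated normal on (0, 120], location 45 s, scale
20 s; the dynamic group gets a +10 s location shift (`EffectSpec.rt_shift`).
The paradigm's scoring table is anchored to a pilot normal distribution,
and a truncated normal with these parameters puts its mass across all five
regulation bins; no published distributional form exists for these
response times, so location/scale are calibration choices of the
generator, not claims about data. The packaged decile reference (`data/pilot_reference_synthetic.csv`,
131 profiles — the pilot sample size the scoring table was built on) is
drawn from the same model with a fixed seed; it is synthetic and labelled
as such.

**EEG.** Per channel: pink (1/f amplitude below 0.5 Hz flattened)
background at 5 µV rms plus five independent band-limited Gaussian
processes (flat in-band spectra; δ 4, θ 3, α 4, β 2, γ 1 µV rms at gain 1).
A band's injected *power* gain g scales its amplitude by √g, so measured
band power is proportional to the gain — the property the recovery tests
exploit. Synthesis is frequency-domain (complex white noise × amplitude
mask, inverse FFT), which is equivalent in distribution to filtering white
noise and much faster; per-segment gains are applied by amplitude
modulation of one whole-session process per band. Blinks are a stereotyped
biphasic 400-ms template at Poisson times (8/min), strong on EOG (150/120
µV), attenuated front-to-back on the scalp. No head model is used: the
analysis consumes only band-averaged PSD per channel, so a forward model
would add realism the feature extraction cannot see. Defaults for the
dynamic group's preparation phases: α × 0.60, θ × 0.75, δ × 0.80, γ × 1.50;
static group and baselines at 1.0. These encode the directions of the
reported group effects at magnitudes a 26-per-group design detects
reliably.

**ECG.** Sum of five Gaussian waves (P, Q, R, S, T) per beat at cumulative
inter-beat intervals drawn N(800, 50²) ms, truncated at 0.3 × mean with a
warning. The true IBI series is returned, so R-peak detection is testable
sample by sample.

**EDA.** Tonic level 2 µS with a slow sinusoidal wander and linear drift,
plus phasic events convolved with a peak-normalized bi-exponential kernel
(rise 0.7 s, decay 3 s — peak ~1.33 s after onset), measurement noise
0.005 µS. Events are Poisson per segment (dynamic 4/min, static 2/min in
preparation phases; 1/min in baselines) with a 1-s refractory: overlapping
responses are not physiologically separable, so closer draws are dropped
rather than logged as distinct ground truth. Amplitudes N(µ, (0.15 µ)²),
clipped at 0.05 µS, µ = 0.5 (dynamic) / 0.3 µS (static).

**Seeding.** One cohort seed spawns per-participant `SeedSequence`
children, each spawning per-signal streams; identical seeds give
bit-identical cohorts and RTs can be regenerated without synthesizing
signals (`cohort_prep_times`).

## Processing chain

**Band-pass.** The upper edge is an order-10 zero-phase Butterworth
low-pass at 50 Hz — chosen so a 60 Hz tone is attenuated below 5%
amplitude, the property the tests check. The 0.1 Hz lower edge cannot be
an IIR high-pass at EEG sampling rates: at a normalized cutoff of ~1e-4
the section coefficients degenerate and the filter distorts the pass-band
by several percent (measured up to 13% at 250 Hz). Instead the sub-0.1 Hz
drift is estimated on an anti-aliased, heavily decimated copy (where the
same filter is well conditioned), linearly interpolated back and
subtracted. A 50 Hz notch (Q = 30) follows.

**Ocular correction** is least-squares regression of each scalp channel on
the two demeaned EOG channels. It is deterministic and exactly testable
against the generator's known mixing weights; an ICA variant would depend
on unspecified algorithmic choices. Flat or missing EOG leaves the data
untouched (with a warning when missing).

**Epoching** cuts each marked phase into consecutive non-overlapping
2000-ms windows; a window is rejected if any non-EOG channel exceeds 100 µV
peak-to-peak or is flat. EOG channels are excluded from the criterion
because they legitimately carry blinks. The amplitude criterion replaces
the visual inspection of a human analyst and is the reproducible
operationalization of "artifact-free".

**Spectra.** Per epoch, a Hamming-tapered one-sided periodogram with
density scaling normalized by the taper energy, so the integrated density
of white noise estimates its variance; 2-s windows give 0.5 Hz bins.
Spectra are averaged over kept epochs, then binned: a bin belongs to a band
when its center lies inside the band, edges inclusive; the narrow gaps
between printed band edges (e.g. 3.5–4 Hz) belong to no band. ROI power is
the mean of the ROI's two channels; reactivity is computed at ROI level
(aggregate first, then normalize — dividing aggregated quantities is
numerically more stable than averaging ratios). Non-positive baseline
power marks the cell missing rather than dividing.

**R-peak detection**: 35 Hz low-pass, squared first difference smoothed
over 120 ms, threshold at 30% of the 99th percentile, 250-ms refractory,
refinement to the local signal maximum. On clean template ECG this is
sample-exact, which the IBI-recovery test asserts (±2 samples). RMSSD is
the headline HRV metric (robust on short segments); SDNN is always
computed alongside.

**SCR detection.** Tonic/phasic split by a first-order 0.05 Hz zero-phase
low-pass — first order because its step response is monotone; higher-order
filters ring through sparse events and leave ~0.02–0.05 µS artifact bumps
in the residual. Candidate peaks come from the 2 Hz-smoothed phasic signal;
each peak's onset trough is found by walking backward while tracking the
running minimum until the signal has risen by one detection threshold,
which skips noise micro-minima but stops at the dip between close response
pairs. An event is kept if trough-to-peak ≥ 0.01 µS (the conventional
minimum SCR amplitude), the peak lies above the phasic zero line (rejecting
bumps inside post-response undershoot), and the rise time is 0.5–5 s. The
0.5-s lower edge is the conventional minimum rise time; with a 1-s edge the
second member of closely spaced pairs is systematically rejected and
detector sensitivity drops below the package's own quality gate. The
per-discourse statistic entering the ANOVA is the mean SCR amplitude (0
when no event), with the count exported alongside; SCL is the mean tonic
level.

## Statistics

The mixed design (one between factor, one or two within factors) is
decomposed by cell-means sums of squares with participant-within-group as
the random block. Error strata: subjects(group) for the between effect;
W×subjects(group) for each within effect and its interaction with group;
W1×W2×subjects(group) for the two-way within interaction and the
three-way. Greenhouse–Geisser ε per within family is computed from the
pooled within-group covariance of orthonormal contrast scores,
ε = tr(MΣMᵀ)² / (d·tr((MΣMᵀ)²)), clamped to [1/d, 1], and applied to every
within effect unconditionally — the corrected p is the headline, with the
uncorrected df reported alongside. (pingouin computes ε from the total
covariance instead; the two agree when groups do not differ, and the
package keeps the pooled-within-groups convention of classical mixed-design
software.) Both classic η² (SS/SS_total) and partial η² (SS/(SS+SS_error))
are emitted because reported mixed-design η² values are ambiguous between
the two. Pairwise simple effects: independent t between groups inside a
cell, paired t within subjects, Bonferroni-adjusted by the family actually
tested; identical paired samples report p = 1 rather than NaN.

Degenerate inputs are explicit: zero within-group variance with unequal
means reports F = ∞ with p = 0 and a flag; zero-variance correlations are
flagged, not zeroed; unbalanced or incomplete ANOVA tables raise with the
offending subject or cell named — no silent imputation.

## Interpretation boundaries

The generator reproduces the *statistical skeleton* the analysis assumes —
stationary band-limited oscillations, template heartbeats, bi-exponential
SCRs, truncated-normal response times — not real physiology: no 1/f slope
variation, no non-stationary artifacts beyond blinks, no heart-rate/EDA
coupling, no respiration or movement. Passing recovery tests therefore
demonstrates that the pipeline correctly extracts what it models, at study
size, under known ground truth; it does not validate the pipeline against
human recordings. Type-I calibration is exercised at the behavioral level
(RT-only null cohorts), where the group test actually operates; a
signal-level null adds cost but no additional inferential content under
this generator.

Two readings of the resistance statistic are implemented
(`d45="mean"`, the default |mean(t₄,t₅) − mean(t₁…t₅)|, and `d45="diff"`,
|t₄ − t₅|); the phrasing of the source definition admits both, and the
default is the one consistent with "deviation of the acute-stress phase
from overall performance". The decile reference defaults to the packaged
pilot sample, with `reference="self"` available; which anchoring the
original analysts used is not stated. EDF files can be read (via mne) but
not written — no installed backend exports EDF — so the plain-text signal
dialect is the package's interchange format.
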