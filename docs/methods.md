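# Methods

This note documents the models and procedures `calpharm` implements, the
choices made where the analysis was genuinely open, and what the synthetic
data does and does not emulate.

## Normalization model

Two normalizations coexist because the two experiment types have different
baselines.

*Stimulation (anesthetized/slice) recordings* use
ΔF/Fo(t) = (F(t) − Fo)/(Fo − FB). Fo and FB are the means of the ROI trace
and the background trace over the pre-stimulus window. The background trace
Fb(t) is the per-frame mean of a fixed set of `n_low` (default 25,
conventionally 20–30) darkest pixels. "Darkest" is judged on the
*time-averaged* image: ranking pixels per frame would let the selected set
jump between frames and inject noise into FB, while the time average gives a
stable estimate of the non-tissue floor. The selected pixel indices are
returned so the choice is auditable. Fo ≤ FB is reported per ROI as a
`DegenerateBaselineError`, never silently dropped, since it usually flags a
mis-drawn ROI or saturated background.

*Locomotion (awake) recordings* are neuropil-corrected first,
F = F_MLI − r·F_Neuropil with r = 0.7 — the conventional contamination factor
for somatic GCaMP ROIs — and then expressed relative to the per-ROI resting
fluorescence: ΔF/F_rest = (F − F_rest)/F_rest. F_rest is the mean corrected
fluorescence over the [0, 5) s pre-motorization window of the block's
least-active recording (minimal rotary-encoder distance in that window; ties
go to the lowest recording index). Because ROIs are re-detected after drug
application, the pre-drug and post-drug recordings carry independent ROI
label sets; F_rest and the least-active recording are therefore determined
per condition block — a post-drug ROI has no trace in a pre-drug recording to
normalize against. Both normalizations are exactly invariant under a global
multiplicative gain.

All time windows in the package are half-open [start, end) seconds, mapped to
frames as floor(start·rate) … floor(end·rate) with 0-based indexing, so
adjacent windows never double-count a boundary frame.

## ROI matching across sessions

The pre- and post-drug fields of view are related by a small rigid
translation. The estimator maximizes zero-mean cross-correlation between the
two images over integer shifts within ±`max_shift` px (computed via FFT
cross-correlation; identical to exhaustive search). Ties — scores equal
within a 1e−9 relative tolerance — are broken by the smallest |dx| + |dy|,
then lexicographically, making the result deterministic. Sub-pixel
registration is deliberately out of scope: the masks being compared are
binary, and the downstream overlap criterion is insensitive below one pixel
(0.78 µm).

Two ROIs are the same soma when A_overlap/A_union ≥ 0.3, evaluated after
shifting; the comparison is inclusive at the boundary. The criterion induces
conflicts when an ROI overlaps several partners, so pairs are accepted
greedily in descending overlap ratio with ratio ties broken by the smaller
label pair; each ROI joins at most one pair and the assignment is invariant
to label permutations.

## Locomotion drug-effect pipeline

The per-ROI, per-recording summary is the **locomotion fluorescence**
L<sup>i,j</sup>: the 75th percentile (linear interpolation between order
statistics, index (n−1)·q/100) of ΔF/F_rest over the maximal-speed window
[10, 25) s. The high percentile emphasises the locomotion-locked fluorescence
increases and is insensitive to transient drops during walking.

Locomotion fluorescence declines over a session in a way shared across ROIs
and tied to the repetition count rather than wall-clock time. Accordingly a
single exponential f_j = A + B·e^(−j/C) is least-squares fitted per ROI over
the 1-based acquisition index j of the *pre-drug* recordings only
(scipy `curve_fit`, C bounded positive, initialised at A ≈ last value,
B ≈ first − last, C ≈ half the index span) and subtracted from *all*
recordings. This re-centres pre-drug values on zero and exposes drug-induced
change beyond the shared decay. Exactly constant input returns A = constant,
B = 0 with C unidentifiable and a `degenerate_constant` flag; fewer than
three points or non-convergence falls back to a straight line in j, flagged.
Adding a constant to all values shifts A by that constant and leaves the
detrended values unchanged.

**Classification.** Each ROI is tested for a drug-induced change in mean
detrended locomotion fluorescence, two-sided at α = 0.01, after dropping the
first three post-drug recordings (drug wash-in, τ ≈ 5.5 min at the 40 s +
inter-trial cadence). The pre- and post-drug recording counts differ (6–14 a
side in practice), so observation-level pairing is undefined; the default is
a Welch two-sample t-test, with a pooled-variance variant and a
truncated-pairs variant available for sensitivity analysis. Zero-variance
inputs yield p = 1 with a flag rather than a NaN. The same test on the raw
(un-detrended) values is reported alongside (`p_raw`, `label_raw`), because
which of the two the original analysis used is not decidable from the
published description; the detrended version is the primary one, consistent
with the stated aim of revealing changes beyond the general decay.

**Regression.** The per-ROI change (mean detrended post-drug L, wash-in
excluded) is regressed on the pre-drug baseline (mean *raw* pre-drug L:
detrended pre-drug means are ≈ 0 by construction, so the raw mean is the only
meaningful abscissa). Reported: OLS slope/intercept, Pearson r, R² = r², the
two-sided p for r, and n. r is checked in the tests against the direct
covariance formula.

**Movement-artifact control.** `artifact_ratio` forms per-ROI ratios of a
locomotion-window statistic (SD or 75th percentile of ΔF/F_rest) between
820 nm runs — where GCaMP fluorescence is calcium-insensitive — and 910 nm
runs, for ROIs matched by the same ≥ 30% overlap rule; zero 910 nm metrics
are flagged rather than divided by.

## Stimulation ratio analysis

The response measure is the single-frame maximum ΔF/Fo in the response
window, taken on the raw trace (no smoothing is applied by default; an
optional moving average exists but the published analysis mentions none, and
smoothing biases peaks downward). Per protocol bin, per-cell drug/control
ratios are averaged (mean ± sem, sem = sd/√n) and the paired peaks are
compared with a two-tailed Wilcoxon signed-rank test. Zero differences are
dropped before ranking (standard signed-rank convention, logged in flags).
For n ≤ 25 the exact two-tailed p is computed by dynamic programming over
doubled midranks — valid under ties, and equal to full sign-flip enumeration,
against which it is tested for n ≤ 12; above 25 the normal approximation with
tie correction and continuity correction is used (the two branches agree to
< 0.01 at the crossover). Ratios are exactly invariant to a common rescaling
of all fluorescence values.

## Immunogold annulus profiling

Each PSD sample is a simple polygon (nm) plus particle coordinates. A
particle's distance is the Euclidean distance to the polygon boundary;
particles inside or on the boundary get distance 0, are flagged interior, and
are excluded from the band densities (the profile measures the *perisynaptic*
distribution outward from the PSD edge) while being reported separately.
Bands are half-open [b·50, (b+1)·50) nm so the printed 50, 100, … distance
lines are unambiguous boundaries. Band areas are differences of buffered
polygon areas (round joins, 64 segments per quarter circle: circle
approximation error well below 1 nm at these radii), optionally intersected
with an `analysis_region` polygon when the analysable membrane face is
limited — whether the published denominators were clipped this way is not
stated, so both readings are supported. Counts always conserve:
inside + Σ bands + beyond = total; profiles are invariant under rigid motion
of the whole sample; for convex PSDs the ring areas increase strictly with
distance.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analyses assume, not
the biophysics — there is no model of receptor kinetics or calcium dynamics,
and the drug effect is purely phenomenological.

*Speed protocol.* The treadmill trace is deterministic: rest to 7 s, linear
acceleration at exactly v_max/3 = 10/3 cm/s² (printed 3.33) reaching 10 cm/s
at 10 s, constant to 23 s, symmetric deceleration to rest by 26 s, still to
40 s, sampled at 30 Hz with the position as the closed-form integral. Storing
the acceleration as v_max/3 keeps the kinematic identities exact (motorized
distance 15 + 130 + 15 = 160 cm).

*Locomotion sessions.* Per ROI the designed pre-drug locomotion fluorescence
is b ~ Normal(1.28, 0.60) ΔF/F_rest and the drug-induced change is
d = −0.65·(b − 1.28) + ε, ε ~ Normal(0, 0.597), giving a population
correlation of −0.547 between baseline and change; recordings share a decay
offset 0.1 + 0.5·e^(−j/4) over the global index j, with 6 pre- and 11
post-drug recordings. These defaults are the study conditions of the
change-vs-baseline analysis. The baseline Normal is untruncated (≈ 1.6% of
ROIs fall below zero, which the arithmetic tolerates); an optional
`truncate_baseline` redraws negatives for users who want strictly positive
resting signals, at the cost of slightly shrinking the baseline SD and hence
the planted correlation. Traces are generated at ROI level (soma + neuropil
per ROI), not as movies: the pipeline's mathematics operates on traces, and
full movies would only exercise plumbing. Within the [10, 25) s window the
trace is the designed value plus Normal jitter (SD 0.05) *re-centred on its
own 75th percentile*, so each recording's windowed percentile equals the
designed value exactly — parameter recovery is then limited by sampling of
(b, ε) rather than by percentile noise; with zero jitter the construction is
exact trivially. Ramps proportional to wheel speed connect the resting
segments (exactly at F_rest) to the window. Neuropil contamination is
generated as soma_obs = soma_true + 0.7·neuropil_obs, so the standard
correction inverts the generative model exactly. A rigid translation and a
label permutation relate the post-drug masks to the pre-drug ones. Not
emulated: imaging noise on resting frames, slow baseline drift within a
recording, ROI shape change beyond a radius perturbation, spiking dynamics.
Consequently a passing end-to-end test shows the *pipeline algebra* is
correct and the planted effect is recovered; it does not certify performance
under real imaging noise. One visible consequence: with exact percentiles the
per-ROI classifier flags nearly every ROI that has any planted change, so the
increase/decrease counts on synthetic sessions are much higher than real
data would give.

*Stimulation datasets.* Each cell's control peak is a_i·(1 + m) with a_i the
drug-insensitive component (Gamma with configurable mean and CV) and m the
drug-sensitive multiplier; the drug condition retains a_i. Every noiseless
per-cell ratio is 1/(1 + m), so printed ratios (0.47, 0.73, 0.06) correspond
to m = 1/ratio − 1 by construction.

*Particle fields.* Either homogeneous uniform points over the square field
(the null for density flatness) or counts multinomially allocated to bands in
proportion to prescribed density × band area, placed by rejection sampling
within each annulus.

All generators are bit-reproducible under a fixed seed; every source of
randomness descends from the explicit seed parameter.

## Problem sizes and numerical choices

The end-to-end recovery experiment uses 25 independently seeded sessions of
313 ROIs (6 pre + 11 post recordings, 1200 frames each) — large enough that
the seed-averaged Pearson r has a standard error ≈ 0.006 — and the null
calibration uses 10 seeds × 1000 ROIs (8 pre, 11 post values each), putting
the binomial SE of the flagged fraction near 0.001. Percentiles use numpy's
linear interpolation so test oracles agree bitwise; the decay fit is
cross-checked against a profile grid over C with linear solves for (A, B);
regressions are cross-checked against the covariance formula.

## Known limitations

- Translation-only registration; rotation or non-rigid deformation between
  sessions will degrade matching (out of scope by design).
- The exponential decay is fitted per ROI on as few as 6 points; with noisy
  real data the linear fallback will engage more often and is flagged, not
  hidden.
- ROI detection is an upstream step: masks are inputs, and their quality
  bounds everything downstream.
- The EM profile treats the PSD outline as error-free; digitisation error of
  the manually demarcated outline propagates directly into band membership
  near the 50 nm lines.
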