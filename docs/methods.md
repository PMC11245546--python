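# Methods

## Model and procedure

The analysis treats each fMRI volume as a point in coherence space. For a
run with P ROIs sampled at repetition time TR, every ROI column is demeaned
and converted to its analytic signal with the Hilbert transform; the
instantaneous phase is the angle of that signal, wrapped to [−π, π] by
construction of the four-quadrant arctangent. The connectivity
configuration of volume *t* is the vector c(t) with one entry per unordered
ROI pair (i, j), c_ij(t) = cos(θ_i(t) − θ_j(t)) ∈ [−1, 1], ordered as the
row-major upper triangle (D = P(P−1)/2; 861 for P = 42). The vectorization
is invariant to any common phase shift across ROIs at a time point, so the
carrier rhythm itself never enters the configuration — only the inter-areal
phase relations do.

Recurrent configurations ("patterns") are learned by k-means under the
Manhattan distance on the pooled resting-state vectors of all subjects.
The L1 cost minimizer of a cluster is its coordinate-wise median, so the
Lloyd iteration alternates nearest-centroid assignment (L1) with median
updates; the total within-cluster L1 cost descends monotonically and the
best of many random restarts is kept (restart initializations are k
distinct data rows sampled without replacement). An empty cluster is
re-seeded at the point farthest from its centroid. The number of patterns
is selected by the mean silhouette width (same L1 metric) of each
candidate k's final assignment over k ∈ {3, 4, 5, 6, 7}; ties go to the
smaller k. For pools beyond 3,000 vectors the silhouette is estimated on a
seeded subsample of that size. Fitted patterns are numbered by descending
mean absolute coherence, so Pattern 1 is always the most strongly
connected profile. Task volumes are labeled with the nearest rest-trained
centroid (L1; ties to the lowest index).

Two controls accompany the clustering. The circular-shift surrogate
rotates each ROI's time series by an independent random offset, preserving
every column's value multiset and circular autocorrelation while
destroying inter-areal alignment; re-running the whole pipeline on
surrogate data must produce centroids with a fraction of the original
centroid coherence. Centroid sets from two analyses are compared by the
full matrix of Pearson correlations between centroid vectors, with a
one-to-one matching by Hungarian assignment on correlation magnitude
(signed correlations are reported, so an inverted duplicate matches at
ρ = −1).

Behavioral analyses operate on subject-level cells. Detection rates per
(subject, pattern, SNR) — catch trials enter only the false-alarm rate —
are arcsine-transformed (asin √p) and modeled with a linear mixed model
with a subject random intercept, residual variance σ²/n_trials (trial
counts as weights), and fixed effects pattern, SNR, pattern × SNR, plus
optionally the previous trial's detection status. Factor significance uses
Type-II Wald χ² statistics: a main effect is tested in the model omitting
interactions that contain it, the interaction in the full model. The
variance components are estimated by REML on a two-parameter profile with
the per-subject covariance inverted analytically (Sherman–Morrison), so a
fit costs milliseconds; a boundary fit (τ² → 0) is flagged. Pairwise
pattern contrasts within each SNR are paired t-tests on the subject-level
transformed rates with Benjamini–Hochberg correction within SNR, and the
reported effect size is the paired Cohen's d (mean of subject differences
over their SD). Reaction times keep detected non-catch trials with
latency in the closed interval [0.4, 2.0] s, are inverted (1/RT), averaged
into subject cells, and modeled identically.

Threshold-stimulus (SNR −9) dynamics are summarized two ways. The
aggregate occupancy analysis computes, per trial, the fraction of the nine
volumes at onset offsets +1..+9 bearing each pattern, averages within
subject separately for detected and undetected trials, and compares
conditions per pattern with a paired two-sided Wilcoxon signed-rank test.
The time-resolved analysis computes per-offset occurrence probabilities on
the grid −3..+9 volumes (13 points at TR = 1 s) and corrects the per-offset
Wilcoxon tests with BH-FDR within each pattern's 13-offset family. All
Wilcoxon paths share one implementation: zeros dropped, V = sum of positive
ranks, exact null for n ≤ 25 without ties, otherwise the normal
approximation with continuity correction. Ratings analyses pool
subject-blocks and correlate each pattern's block occupancy with each
rating (Spearman), BH-corrected across the pattern × rating family.

## The synthetic study

The generator plants everything the analysis is supposed to find.

**States and templates.** Five coherence templates are defined through
per-ROI phase offsets ψ (template entry = cos(ψ_i − ψ_j)): antiphase
halves (strong long-range positive and negative coherence — the designated
favorable, conscious-state-like pattern), a graded globally positive
profile, three communities at 120°, three interleaved communities in
quadrature (the designated "tired" pattern), and two interleaved
communities in quadrature. Their mean absolute coherences are strictly
ordered (1.0, ≈0.85, ≈0.66, ≈0.55, ≈0.49), which pins the canonical
numbering. State dynamics are a Markov chain with geometric dwell times
(mean `dwell_scale`, default 25 s at TR = 1 s — connectivity
reconfiguration on the scale of tens of seconds), started from the
stationary distribution. Arbitrary user templates are realized by fitting
phase offsets (circular MDS initialization + L-BFGS); the residual is
reported and a template too far from any phase-offset geometry is
rejected rather than silently approximated.

**Signal synthesis.** All ROIs share one constant-modulus FM carrier
exp(iθ(t)) — a center tone at the middle of `carrier_band` plus a
band-limited Gaussian phase wander (sd 3 rad, ≈0.012 Hz) — and ROI i's
noiseless signal is √2 · Re[φ_i(t) · carrier(t)], where the envelope
φ_i(t) blends the per-state unit phasors e^{iψ_i(s)} with weights obtained
by band-limiting the one-hot state indicators below the carrier band
(Gaussian spectral gain, hard cutoff). Because the envelope has no energy
at or above the carrier's lowest frequency, the signal is (essentially)
free of negative-frequency content and the downstream Hilbert phase is
exact: away from the few-volume blend window around each state switch,
the per-volume coherence vector reproduces the active template to better
than 0.01. Gaussian white noise (sd `noise_sd` = 0.15 relative to the
unit-RMS signal) is added per sample.

Three numerical facts shaped this design, each measured during
development. A carrier with phase jumps at state switches corrupts the
Hilbert phase globally, not locally, so switches must be band-limited
cross-fades; per-volume template fidelity *inside* the blend window is
therefore impossible in principle, and fidelity tests assert the 0.05
bound at volumes ≥ 12 from a switch. A single-tone carrier survives
circular shifting as a pure phase rotation, which would defeat the
surrogate control, so the carrier must wander in frequency; making it
wander in *amplitude* instead (a broadband Gaussian carrier) creates deep
fades where phase is ill-defined and blurs the cluster geometry. And the
carrier must sit well above both the switching rate and the envelope
bandwidth, which is why the default band (0.16–0.26 Hz) is faster than
the slow rhythms that dominate real BOLD: with TR = 1 s this buys a
±2-volume transition window and crisply separable states. This is a
deliberate realism sacrifice — the generator emulates the *geometry* of
switching coherence states, not the BOLD power spectrum.

**Task and observer.** Each block holds 10 stimuli per SNR ∈ {−7, −9, −11}
dB plus 3 catch trials in random order, onsets separated by uniform
14 ± 1 s draws (198 trials over 6 blocks). Detection probability is
(1 − lapse) · logistic(β(snr + volume − α)) with β = 1 dB⁻¹, α = 0,
lapse = 0.02, plus δ = 0.12 when the favorable state is active at the
onset volume and the stimulus is at threshold, plus γ = 0.055 after a
detected previous trial, clipped to [0, 1]; catch trials detect with the
false-alarm rate 0.002. γ was calibrated so the previous-detection Wald
χ²(1) in simulated studies averages ≈ 21, the size of the reported
hysteresis effect; δ matches the reported favorable-vs-other detection gap
at threshold (≈ 0.12). Reaction times of detected trials are lognormal
with SNR-dependent means (1.02 / 1.10 / 1.20 s at −7 / −9 / −11). The
one-up-one-down staircase at SNR −9 (step 1 dB, start 13 dB) lowers the
volume after a detection and raises it otherwise, returning the mean level
over reversals after discarding the first 20%; it converges to the 50%
point of the observer. In the coupled task simulation, a detected stimulus
shifts a fraction (0.15) of the transition mass onto the favorable state
for the following 9 volumes, producing the reciprocal
detection → dynamics effect; trial state at onset uses the volume whose
acquisition interval [kTR, (k+1)TR) contains the onset. The first trial of
each block carries no previous-detection covariate and is excluded from
models that need it. Block tiredness ratings are a noisy monotone map of
the tired state's block occupancy discretized to 1..7 (noise sd 1 rating
point); success and focus are weakly anti-associated with it.

**What the generator does not emulate.** Hemodynamic convolution and its
lag, physiological noise and motion (the modeled signal is the
post-denoising ROI average), spatial structure of ROIs, inter-subject
variability in psychometric slope or threshold (the staircase absorbs
level differences), non-geometric dwell-time distributions, and the BOLD
1/f spectrum (see the carrier note above). Passing tests therefore
demonstrate that the pipeline recovers what it is designed to recover
under its own assumptions — they do not certify performance on real
scanner data, where transition sharpness, noise spectra, and state
geometry are less favorable.

## Numerical choices and degenerate inputs

Constant (zero-variance) ROI columns make instantaneous phase undefined
and raise an error naming the ROI. Assignment ties in labeling and
clustering break toward the lowest pattern index. The silhouette of an
all-singleton clustering is taken as 0 by convention; a k whose fit
collapses below two non-empty clusters is excluded from selection with a
warning. The mixed-model optimizer works on log-variance coordinates
(Nelder–Mead on a two-parameter REML profile); τ² < 10⁻⁶ σ² is reported as
a singular fit. The RT filter interval is closed at both ends. Exact
Wilcoxon p-values are used for n ≤ 25 without ties in |differences|.
FDR families are: pattern contrasts within SNR level; time-resolved tests
across offsets within pattern; ratings across the pattern × rating grid.
Catch trials never enter psychometric models. All randomness derives from
one master seed through tagged child generators (CRC32 of the purpose tag
mixed into a `SeedSequence`), so any stage can be re-run in isolation
byte-identically.

## Problem sizes used in the test suite

The paper-scale analysis (25 subjects, 1000 k-means restarts) is what the
defaults describe; the test suite scales down where the full size adds
nothing to the property under test: model-order selection uses 4 subjects
and 20 restarts (restart-starved fits occasionally hand the silhouette win
to a neighboring k, so 20 is the floor for stable selection); the
surrogate control uses 3 subjects; type-I calibration uses 200 replicate
behavior-only studies (no signal synthesis, since patterns are read from
the latent truth); power and recovery use 100. The staircase calibration
and schedule checks run at full size.

## Known limitations

Type-II Wald tests are implemented by refitting without the containing
interaction, which reproduces `car::Anova` exactly for the
highest-order term (verified against lme4 + car on identical data:
interaction χ²(8) agrees to 4 decimals) but differs slightly for main
effects. Pattern contrasts are subject-level paired t-tests rather than
model-based marginal-means contrasts. The weighted mixed model assumes
residual variance ∝ 1/n_trials, the arcsine transform's asymptotic
variance; cells with very few trials are noisier than the model believes.
The detection → dynamics coupling makes trial counts per cell weakly
outcome-dependent, which is a genuine feature of the design being
emulated (and of the original study's weighting scheme), not an artifact:
under the fully null generator (no boost, no hysteresis, no coupling) the
pattern × SNR test is calibrated at its nominal level.
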