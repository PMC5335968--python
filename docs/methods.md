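# Methods

`ppgpulse` estimates heart rate from wrist photoplethysmography (PPG)
corrupted by motion artifacts (MA), using a two-stage procedure: hybrid
artifact removal, then spectral peak tracking posed as a 3-class
classification problem. This note documents the model, the tunable
parameters, the synthetic-data generator, the numerical choices, and the
known limitations.

## Signal model and windowing

The measured PPG is modelled as `x(k) = s(k) + n(k)`: a quasi-periodic pulse
`s` whose spectral fundamental encodes heart rate, plus motion artifacts `n`
correlated with wrist acceleration. All channels are band-pass filtered to
0.4–5 Hz (zero-phase 4th-order Butterworth, forward–backward), the two PPG
channels are averaged (configurable), and the tri-axial acceleration is
consolidated to its pointwise Euclidean norm. Analysis runs on T = 8 s
windows sliding by M0 = 2 s at fs = 125 Hz (window length M = 1000
samples). Spectra are zero-padded rectangular periodograms with N = 4096
DFT points, stored one-sided; bin b maps to frequency (b−1)/N·fs, so the
bin resolution is fs·60/N ≈ 1.83 BPM.

## Stage 1 — artifact removal

**Volterra adaptive noise cancellation.** The consolidated acceleration,
delayed by 0.08 s (motion leads its optical artifact), is expanded in a
truncated second-order Volterra series: the lagged linear terms
a(i−p), p = 0..m, plus all distinct pairwise products a(i−p)·a(i−q), p ≤ q.
With memory m = 10 this gives D = 77 coefficients, adapted by
exponentially weighted recursive least squares (forgetting factor
λ = 0.999, inverse-correlation initialisation P₀ = 100·I). The denoised
sample is the a-posteriori residual s(k) = x(k) − w(k)ᵀâ(k). The quadratic
kernel matters: a squared reference term lives at twice the cadence
frequency and is invisible to a linear canceller.

Each window is processed independently, with a *burn-in* pass: the
adaptation first runs once over the window to converge the coefficients,
then runs again from that state to produce the output. This removes the
~2 s convergence transient that otherwise leaves artifact residue at the
start of every window, without coupling windows to each other.

**Strong/NotStrong gate.** A random forest (100 trees, fixed seed) decides
per window whether residual MA are still strong. Features (24): time-domain
energy; number of significant spectral peaks (local maxima ≥ δ1 = 30% of
the in-band maximum); mean and kurtosis of the in-band spectrum;
correlations of the denoised spectrum with the raw-PPG and acceleration
spectra (zero-variance inputs give 0); and energy/mean/SD of the six db4
discrete-wavelet sub-bands of a 5-level decomposition (symmetric
extension, features on coefficients). Training labels come from ground
truth: NotStrong iff the heart rate implied by the max-amplitude in-band
peak is within tol = 3 BPM of the ECG-derived truth.

**Singular spectrum analysis.** Windows gated Strong are further cleaned by
SSA: the window is embedded in an L×K Hankel trajectory matrix
(L = min(500, M/2)), the top k = 20 singular triplets are computed from the
symmetric eigenproblem of X·Xᵀ (much cheaper than a full SVD and identical
in its leading triplets), and each rank-1 term is mapped back to a series
by anti-diagonal averaging (implemented as a convolution of the singular
vector pair). Any component whose dominant periodogram bin falls within
±2 bins of a dominant acceleration frequency (peaks ≥ δ2 = 50% of the
acceleration-spectrum maximum) is attributed to motion and dropped; the
rest, plus an explicit residual term that makes the decomposition sum
exactly to its input, are summed back. If every non-negligible component
would be dropped the window is returned unchanged with a warning.
Eigentriples are treated singly (no grouping); when pulse and artifact have
nearly equal amplitudes their nearly degenerate eigenvalues mix across
components and separation degrades — a known SSA weak-separability
limitation that matters mainly when the two lines have the same strength.

## Stage 2 — spectral peak tracking as classification

Let Lprev be the previous window's heart-rate bin. The fundamental search
range is LRange1 = [Lprev−Δs, Lprev+Δs] (Δs = 2) and its first-harmonic
image LRange2 = [h(Lprev−Δs), h(Lprev+Δs)] with h(b) = 2(b−1)+1. Up to two
dominant peaks (≥ δ2 of the range maximum) are collected in each range.
Three candidates are built:

1. the fundamental of a harmonic peak-pair (|Lj1 − h(Li0)| ≤ 1 bin) if one
   exists, else Lprev stepped by σ1 = 2 toward the strongest in-range peak;
2. the candidate (fundamental-range peak or inverse-harmonic-mapped
   LRange2 peak, (b−1)/2+1 rounded) closest to Lprev, capped at a σ2 = 2
   step;
3. Lprev itself.

A second random forest classifies the window's spectrum state into Class
1/2/3 from 9 features (peak counts in both ranges, acceleration energy,
time- and spectral-domain correlations with acceleration, mean/skewness/
kurtosis of the cleaned window, and a pair-present flag); the candidate of
the predicted class becomes Loc, and HR = (Loc−1)/N·fs·60. Training labels
are the class of the candidate nearest the true bin (ties to the lower
class), with the tracker teacher-forced from the previous window's true
bin during training.

Harmonic-range peaks that coincide (±4 bins) with a dominant acceleration
bin are vetoed before pair detection: such a "harmonic" is almost always
the cadence line or its cancellation residue, and accepting it as pair
evidence locks the tracker onto half the cadence frequency.

**Initialisation.** The tracker is seeded from the first five windows'
cleaned spectra. Each window votes for its significant HR-band peaks
(50–180 BPM) with score amp + min(harmonic amp, amp) — capping harmonic
support at the fundamental's own amplitude prevents a spurious
half-frequency peak from claiming the true fundamental as its harmonic —
normalised so every window votes equally, and with votes within ±4 bins of
a dominant acceleration frequency down-weighted ×0.25. The pulse persists
at a consistent bin across windows while cancellation residues wander, so
the accumulated vote concentrates on the pulse. A user-supplied initial
BPM bypasses the vote.

**Track-loss recovery.** A NotStrong gate decision is, by the definition of
its training label, an assertion that the window's in-band argmax is near
the true heart rate. If five consecutive NotStrong windows show a stable
argmax (spread ≤ 2 bins) more than 2Δs bins from the tracker and away from
the acceleration frequencies, the tracker has lost the pulse and Lprev is
re-anchored to that argmax. This bounds the damage of an early wrong lock;
it never fires while windows are gated Strong.

## Synthetic data generator

The generator emulates treadmill-style wrist recordings with known truth:

- **Pulse**: phase-continuous sum of 3 harmonics with amplitude ratio 0.5,
  fundamental following a reflected random walk (default step 1 BPM per
  2 s) inside a BPM band; per-window truth is the windowed mean of the
  instantaneous rate — the per-window ECG-truth convention.
- **Cadence**: a step oscillation (default 2 Hz plus a 0.2-amplitude second
  harmonic) with 1% AR(1) frequency jitter (correlation 4 s). The jitter is
  load-bearing: real step timing varies, and without it a pulse whose rate
  coincides with the cadence is fully coherent with the reference over a
  window and gets cancelled along with the artifact, even in clean data.
- **Accelerometer**: gravity offset plus the cadence oscillation projected
  onto the three axes (scale `accel_osc_amp`) plus white noise. The
  gravity offset keeps the triaxial norm linear in the oscillation, as for
  a real worn sensor.
- **Coupled artifact**: delayed (0.08 s) linear + quadratic transform of
  the cadence signal — deliberately the same family the Volterra canceller
  models — multiplied by a slowly drifting coupling gain (lognormal AR(1),
  sd 0.5, correlation 2 s) representing varying sensor contact pressure:
  the drift changes how strongly motion leaks into the PPG without
  changing the accelerometer, which is what leaves residual artifact after
  a within-window canceller, as on real wrists.
- **Accel-independent artifact**: band-limited (0.5–3.5 Hz) noise bursts
  with a telegraph on/off envelope (mean episode 20 s, half-second ramps),
  representing episodic arm movements and contact transients with no
  accelerometer signature. These are what make a window irrecoverably
  "Strong": no reference-based canceller can remove them.

The canonical training grid (`make_training_grid`, 3 recordings × 180 s per
condition, seeded) covers: clean (rest — no cadence, no artifact), moderate
(walking-level coupling g = (1, 0.5) plus bursts), strong (running-level
coupling g = (4, 2) plus bursts), and overlap (running with the heart rate
started at the cadence — the canonical hard case, included so the stage-2
classifier learns that holding the previous location is correct when the
spectrum is untrustworthy).

What the generator does *not* emulate: real PPG pulse morphology (dicrotic
notch, amplitude variability), baseline wander, sensor saturation,
arrhythmia, and broadband gait harmonics beyond the second. Passing tests
on this generator therefore demonstrate the mechanics of the method —
cancellation of model-matched artifacts, gate fidelity, tracking logic —
not clinical-grade accuracy on real recordings, which requires the original
wrist datasets.

## Evaluation

Average absolute error AAE = (1/W)·Σ|BPMest − BPMtrue|; Bland–Altman
limits of agreement μ ± 1.96σ of the per-window differences with the
sample (W−1) standard deviation; Pearson correlation between truth and
estimates; and an OLS fit of estimate on truth for scatter plots. The
no-tracking baseline used for comparisons is the per-window band-limited
spectral argmax of the raw (band-passed, consolidated) PPG.

## Numerical choices and degenerate inputs

- RLS inverse-correlation matrix is re-symmetrised every 128 samples;
  with λ = 1 and large P₀ the recursion reproduces the direct
  normal-equation solution to ~1e−8 (P₀ scales of ~1e7 balance
  regularisation bias against cancellation error; much larger scales lose
  precision in the P update).
- A zero acceleration reference leaves the window exactly untouched
  (coefficients start at zero).
- Peaks are strict local maxima (left neighbour smaller, right neighbour
  not larger); array endpoints are never peaks; plateau ties break toward
  the lower bin. Thresholds are relative to the maximum over the searched
  range.
- Zero-variance inputs yield 0 for all correlation features and for
  skewness/kurtosis; an all-zero first-window spectrum starts the tracker
  at the band edge with a warning.
- SSA components with energy below 1e−10 of the window energy are treated
  as numerically negligible (they neither count as motion nor block the
  all-dropped guard).
- bpm↔bin conversion rounds to the nearest bin and is an exact round trip
  on integer bins.

## Problem sizes

Defaults throughout are chosen so a full study — training grid (12 × 3 min
recordings), clean and strong evaluation sets (5 + 6 recordings), and the
canceller ablation — runs in a few minutes on one core: 180 s recordings
(87 windows each), 3 recordings per training condition, 10/6 evaluation
recordings in the clean/strong regimes of the built-in analyses.

## Known limitations

- Sustained coincidence of heart rate and step cadence (several tens of
  seconds) is not trackable: the artifact and the pulse occupy the same
  bin, the canceller damages the pulse, and the best available behaviour
  is to hold the previous location until the rates separate. Transient
  crossings are handled; long collisions inflate the error for the
  affected stretch, as on the hardest subjects of published wrist
  benchmarks.
- The Strong/NotStrong boundary is intrinsically noisy near the label
  threshold (windows whose argmax error is close to 3 BPM), which caps
  gate CV accuracy on mixed-condition data around 0.9.
- SSA weak separability for equal-strength lines, as noted above.
- The stage-2 classifier is trained with a teacher-forced tracker state;
  at inference the state is the tracker's own estimate, a standard
  exposure-bias compromise.
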