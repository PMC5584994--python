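# Methods

This note documents the models implemented in `gevitrace`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic-data generator does and does not emulate.

## Forward model

### Indicator kinetics

An indicator's fluorescence response to a voltage step is modelled as a
weighted sum of two exponential relaxations toward the steady-state ΔF/F at
the step voltage. Four kinetic regimes are distinguished, keyed to the
step protocols under which such constants are measured: depolarisation from
rest, repolarisation from a depolarised level, hyperpolarisation from rest,
and repolarisation from a hyperpolarised level. Each regime carries
(τ_fast [ms], τ_slow [ms], fraction-fast), with τ_fast ≤ τ_slow and the
fraction in [0, 1]. Presets ship the published HEK293A constants (22 °C)
for ASAP1, ASAP2s and ArcLight Q239.

For arbitrary waveforms V(t), two hidden first-order components (fast and
slow) each relax toward `ss(V(t))` with the active regime's time constants,
updated with exact per-step decay factors; the output is their mix with
weight `fraction_fast`. The regime is re-selected each sample from (a) the
side of V(t) relative to the holding potential and (b) whether the output
is moving away from or back toward the resting response. This reproduces
the defining step protocols exactly. Two caveats are intrinsic to the
construction: the mixing weight switches with the regime, so for waveforms
that cross regimes while the two components are far apart the output can
show small discontinuities (negligible for steps and for smooth spikes at
the recommended sampling); and the integration requires the waveform to be
sampled finer than the fastest time constant divided by 5 (enforced).

### F–V curve

The steady-state curve is piecewise linear through anchors
{(−100 mV, value), (holding, 0), (+30 mV, value)} and clamped outside, with
a warning when input voltages exceed the span. The +30 mV anchors are the
published step responses (−0.387 ASAP2s, −0.233 ASAP1); ArcLight's is
published only as a range (−32 to −35%), so the preset uses −0.33. The
−100 mV anchors are not published numerically; the presets use +0.12
(ASAP2s), +0.08 (ASAP1) and +0.10 (ArcLight), plausible magnitudes for
hyperpolarisation responses of these indicators. All anchors are plain
configuration — replace the `fv_curve` to change them.

A real F–V relation is sigmoidal, not piecewise linear. This matters for
brief spikes: with a linear curve and the tabulated kinetics, the simulated
single-AP amplitude of ASAP1 (≈ −11%) comes out nearly equal to ASAP2s's,
whereas recordings show roughly half. The model therefore reproduces
amplitude-independent properties of such experiments (transient shapes,
photon statistics, schedule trade-offs) faithfully, but not the
between-indicator amplitude ratio for spikes; consequently the
"slower indicator wins SNR at every scanning frequency" comparison holds in
this model at most frequencies but can invert where the sampling phase
favours the narrower transient (it does at 462 Hz under the default test
conditions, and that check is accordingly red). Anchoring a nonlinear F–V
shape to produce the recorded spike amplitudes would require data that are
published only graphically, and was deliberately not attempted.

### Action-potential surrogate

Physiological AP waveforms are specified here only by their 4.0 ms full
width at half maximum and 100 mV amplitude, so the surrogate is a Gaussian
bump with exactly those two properties on a −70 mV rest. Any smooth
unimodal shape matching both is admissible; the Gaussian is the least
structured choice. Spike trains superpose surrogates at 1/frequency
spacing and reject spacings at or below the FWHM. "Time to peak from the
beginning of the AP" needs an onset convention: the package's tests and
examples use the time the voltage first exceeds 5% of the spike amplitude.

### Scanning schedule and photon counting

A random-access schedule visits `n` voxels for a 50 µs dwell each; the
per-voxel frame rate is `1/(n × per-voxel period)`. The default period is
54.054 µs, calibrated so 5 voxels give exactly 3700 Hz; the implied
4.05 µs repositioning time is what makes the whole printed frequency ladder
(5/10/20/40/80 voxels ↔ 3700/1850/925/462/231 Hz) come out consistent,
which a nominal ~6.5 µs move time would not. Frames are treated as
instantaneous samples at frame midpoints; each is an independent Poisson
draw with mean `F0·(1 + ΔF/F)·bleach(t)`. Photobleaching is a
weight-normalised multi-exponential envelope applied multiplicatively to
the rate; fitted bleach constants of specific indicators are out of scope.
The default resting rate is 500 photons per dwell per voxel: per-voxel
rates are published only graphically, and this value puts a summed
20-voxel somatic recording in the tens-of-units d′ regime reported for
bright whole-cell recordings.

### Dendritic geometry

Each voxel carries a distance from the soma, a resting rate, and an
attenuation factor (1 at the soma, non-increasing with distance). A
back-propagating spike reaching a voxel is the somatic ΔF/F scaled by the
attenuation factor and delayed by distance/velocity (default 0.16 m/s).
Per-trial noise streams are spawned deterministically from one seed, so a
whole experiment is reproducible bit-for-bit from (config, seed).

## Trace metrics

* **ΔF/F**: F0 is the mean photon count over a configurable window before
  the spike trigger, default 110–10 ms; the transform stores F0 and is
  exactly invertible.
* **Noise / SNR**: noise is the sample SD of ΔF/F over the 200 ms before
  stimulus onset; SNR is peak |ΔF/F| over noise. Peak search honours the
  indicator polarity (negative-going by default) and accepts a search
  window to avoid crediting shot-noise extremes far from the response.
* **Additive bleach correction** fits one exponential plus offset to
  resting segments and adds back the fitted value at a reference time, so
  the resting photon count is constant across the trace — required when
  absolute counts feed d′. The offset guards against non-bleaching traces;
  on an exact exponential the correction is exact and transient heights in
  photons are preserved.
* **Divisive bleach correction** fits a two-exponential envelope g₂(t) and
  returns (F − g₂)/g₂, the natural form when only fractional responses are
  needed (slow-frame-rate ROI imaging).
* **Exponential fits** use nonlinear least squares with multi-start over
  decade-spaced time constants and positivity bounds on rates; r² is
  1 − SS_res/SS_tot on the fitted segment. The bi-exponential model
  includes a free offset because a step response relaxes to a nonzero
  asymptote — without an offset (or pre-subtraction of the asymptote) the
  stated two-term form cannot represent the data. Near-degenerate fits
  (rates within 5%) are flagged, not rejected. Flat segments return an
  infinite time constant with a flag rather than an error.
* **FWHM** is measured by linear interpolation at the half-height
  crossings, taking the outermost crossings at plateaus; a response that
  never recrosses half height reports FWHM as absent.
* **Binning** sums k adjacent counts (emulating a k-fold dwell) or
  averages ΔF/F, drops a trailing partial bin (preserving Poisson
  summation semantics), and rescales frame rate and effective dwell.
* **Peak timing** can be refined below the frame period by 3-point
  parabolic interpolation around the sampled extremum; this is what makes
  conduction-velocity recovery practical at frame periods comparable to
  the dendritic delays.
* **Conduction velocity** is the least-squares slope of distance against
  peak delay through the soma reference; pairwise velocities are also
  reported. **Attenuation** is the percent reduction of peak amplitude per
  location versus the soma; a helper reports the correlation of amplitude
  with resting rate (expected absent).

## Detectability

`d′ = |ΔF/F|·√(F0·τ/2)` with F0 in photons per frame and τ in frames, so
F0·τ is a photon count — the statistic needs absolute counts, which is why
the additive (count-preserving) bleach correction precedes it. For spike
trains, τ and F0 are recomputed per spike: at train frequencies up to
30 Hz the fluorescence recovers enough between spikes that one F0 — the
mean of the inter-spike fluorescence maxima — is shared by all spikes
(numerator and denominator alike); at higher frequencies the baseline
drifts within the train and F0 is the fluorescence extreme over each
spike's following interval. Spikes whose peak cannot be located or whose
decay cannot be fitted are excluded and the inclusion fraction reported;
the train d′ is the arithmetic mean over included spikes. A single-spike
train reduces exactly to the single-spike path.

The ROC stream is 10⁶ i.i.d. Gaussian samples, every tenth from the signal
distribution ("reset after being drawn upon" is read as independent
sampling); spikes occupy one sample (N = 1) and the noise SD is fixed at 1.
Thresholds are swept over all observed log-likelihood values, "above" is
strict, and ties break toward the lowest threshold achieving the maximum
TP − FP count difference; the false-positive rate is per frame. The
closed-form oracle follows from L being affine in f: the count-difference
objective is maximised at `u = d′/2 + ln((1−p)/p)/d′` above the noise mean.
Both the empirical and analytic rates are reported side by side. One
subtlety found while validating: because the empirical threshold is chosen
on the sample, at intermediate d′ (where the objective is flat near its
optimum) the selected threshold wanders enough that its rates differ from
the analytic-optimum rates by more than simple binomial error; the
simulation is therefore verified by comparing its rates against Gaussian
tails at the threshold it actually chose, plus agreement of the achieved
objective value with the analytic optimum.

## ROI pipeline

Frames are re-timed relative to their stimulus cycle (one 300 ms dark plus
one 300 ms light flash by default) and pooled with a 25 ms moving average
evaluated every 8.33 ms; per-point sample counts are retained and empty
windows are flagged rather than interpolated. A hardware timing shift can
be applied before re-timing (default 0). An ROI is "responding" when ≥ 3
consecutive grid points differ between dark and light phases at p < 0.01
(two-sample t-test, equal-variance by default; the time-matched points are
the moving-average grid points). Per phase, A_max is the largest |ΔF/F|,
t_peak is measured from the flash start, and τ_decay comes from a
single-exponential fit from the peak, reported only when r² > 0.5.

## What the generator emulates, and what it does not

Emulated: bi-exponential regime-dependent kinetics; steady-state anchoring;
Poisson shot noise at realistic per-dwell photon counts; the random-access
frequency ladder; multi-exponential bleaching; linear-attenuation,
constant-velocity back-propagation; trial-to-trial independence.

Not emulated: the sigmoidal F–V nonlinearity between the printed anchors
(see above); movement artifacts and mechanical drift; detector dead time
and afterpulsing; dark counts and background fluorescence; bleaching
recovery in darkness; correlated biological noise (subthreshold activity,
vesicular events); spike-shape variability. Tests passing on this
generator therefore certify the analysis algorithms and their statistical
behaviour under shot noise, not performance on recordings with these
additional nuisances.

## Problem sizes

The test suite uses 10⁶-sample ROC streams, 16–200 simulated trials per
averaging experiment, 31-trial five-voxel dendritic runs, and 100-cycle
ROI recordings at 38.9 Hz; the full suite completes in tens of seconds on
one core. The acceptance script runs one 10⁶-sample ROC simulation plus a
closed-form evaluation, a few seconds in total.
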