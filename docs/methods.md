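# Methods

This note documents the models, numerical choices and known limitations of
`munet`.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The quantity at the core of the package is the imaginary part of the
phase-locking value between the source-space signal at the stimulated left
primary motor cortex (lM1, MNI [−45.9, −9.9, 54.6]) and every other source,
at the individual μ peak frequency f_μ ∈ [9, 13] Hz:

    iPLV(S, T) = | Im ⟨ exp(i·(φ_S − φ_T)) ⟩ |

where φ are Hilbert phases of signals band-passed at f_μ ± 1 Hz.  Retaining
only the imaginary part makes the measure exactly zero for any
instantaneously (zero-lag) mixed copy of the seed, the signature of volume
conduction in EEG; the package tests assert this identity to machine
precision.  Two averaging scopes are implemented:

* **per-trial** — time average within each 1 s pre-stimulus epoch; used for
  the median splits, which need one value per trial;
* **coherent** — joint average over time and trials; used for subject and
  group connectivity maps and cROI extraction.

The scopes are not interchangeable.  A 2 Hz-wide signal observed for 1 s
carries ~5 independent phase samples, so the per-trial |Im ⟨·⟩| has a null
floor of ≈ 0.4 regardless of coupling; the coherent average drives the
independent-pair floor down as 1/√(n_trials) and is the only variant with
enough contrast to threshold maps.  Both are exposed via the
`trial_average` flag of `seed_map`.

Single-trial MEP amplitude (log, two-muscle PC1) is then modelled by five
nested robust regressions — constant, one-cROI, motor-network, phase
(a + c·cos φ + d·sin φ), and network + phase — ranked by
AIC = n·ln(RSS/n) + 2(k+1).

## The synthetic generator

`munet.synthgen` emulates the study conditions of a single-session
suprathreshold EEG–TMS experiment: 1000 biphasic pulses (configurable), EEG
epochs of 1000 samples at 1 kHz covering −1004…−5 ms, two-channel EMG
(−500…+499 ms, synthesized at 5 kHz and decimated), and a smooth
current-dipole lead field on a 64-sensor hemispheric array (the in-vivo
reference used a 128-channel cap; 64 keeps the inverse well-conditioned at
desk scale).

**Phase dynamics.** Each μ oscillator's phase is 2π·f_μ·t plus a stationary
Ornstein–Uhlenbeck deviation (SD 1.2 rad, relaxation 0.12 s), giving a μ
linewidth of a few Hz.  Coupling target T is entrained to the seed as

    φ_T = (1 − κ_k)·φ_indep + κ_k·(φ_seed(t − d) + offset)

with per-trial κ_k ~ Beta (defaults: mean 0.5/0.4, SD 0.2 for the
lSMA/rM1 roles), a constant phase offset (±π/2), and an optional delay d
(−10 ms for lSMA, i.e. SMA leads).  κ is the per-trial coupling ground
truth; its monotone link to measured iPLV is a tested invariant (Spearman
ρ ≈ 0.54 median across seeds at 800 trials, oscillator level).

**Backgrounds.** Every source — oscillator nodes included — carries 1/f
activity (unit RMS against a unit-amplitude oscillation), plus independent
white sensor noise (0.5 µV SD).  Per-source background is essential for the
frequency-control behaviour: without it, the only content of a coupled
voxel outside the μ band is the oscillator's own spectral tail, which is
phase-coupled and would make theta/beta control maps non-null.  With it,
the theta (5 Hz) map at coupled voxels is at the background null and the
beta (21 Hz) map is attenuated several-fold relative to the μ map; the
residual beta elevation reflects the finite μ linewidth of the OU model and
would shrink further for narrower lines.

**Orientation.** Dipoles are simulated along each voxel's dominant-gain
orientation — the component the sensor array actually sees and the one an
SVD orientation-reducing inverse reconstructs.  Random orientations would
make the generated scalar mixing inconsistent with the reduced lead field
and the resolution matrix non-diagonal-dominant.

**MEPs.** log A_k = β0 + β_SMA·κ_k(SMA) + β_M1·κ_k(rM1) +
β_phase·cos(φ_k − φ*) + ε, ε ~ N(0, 0.5²); defaults β = (0, 0.5, 0.3, 0.2),
φ* = 0.  No effect-size ground truth in physical units exists for this
link, so the defaults were calibrated once, at design time, to produce
effects detectable at 800 trials (a ≈ 14% HC_network–LC_network modulation
difference, comparable to in-vivo reports).  The EMG trace adds a 5 mV
exponential stimulus artifact (τ = 5 ms), a biphasic
difference-of-Gaussians MEP (width 5 ms, latency 25 ms, unit peak-to-peak
normalization), 10 µV baseline noise, and a small per-muscle log jitter so
the two-muscle PC1 explains ~99% of the variance, as observed in vivo.

**Fast path.** Cohort-scale studies (power, null calibration) use
`simulate_trial_metrics` / `simulate_mep_amplitudes`, which run the same
phase dynamics and MEP model but skip lead-field mixing and EMG synthesis.
The full sensor→inverse→connectivity chain is exercised end-to-end on
single sessions in the test suite; the cohort studies characterize the
statistical machinery at the oscillator level, where the truth is exact.
Passing cohort tests therefore demonstrate the estimators and tests, not
sensor-level robustness at cohort scale.

## Numerical choices

* **eLORETA.** Kernel W = diag(w_j) with fixed point
  w_j = sqrt(l_jᵀ (L W⁻¹ Lᵀ + αH)⁺ l_j), filter rows w_j⁻¹ l_jᵀ M, H the
  average-reference projector; α defaults to 0.05 × mean eigenvalue of the
  weighted Gram matrix, tolerance 1e−6, max 100 iterations.  With matching
  W in kernel and filter, Cauchy–Schwarz in the M metric gives exactly zero
  localization bias; the acceptance study verifies 100% of voxels over
  random lead fields.  Mixing the w and w² conventions silently destroys
  the property.
* **Analytic signal.** Order: AR(30)-pad → band-pass → Hilbert → trim.  The
  impulse response of the 2 Hz-wide two-pass Butterworth decays over more
  than a second, so the forecast runs 64 + 1536 ms per side; the retained
  window never sees the filter transient.  AR coefficients come from a
  least-squares (covariance-method) fit: the lag-windowed Yule–Walker
  estimate of a near-pure sinusoid carries a frequency bias of up to
  ~0.5 Hz, which corrupts both padding and phase forecasting; Yule–Walker
  remains available (`method="yw"`) and serves as the fallback, with
  reflection padding for degenerate (constant/explosive) cases, flagged.
* **Phase at the pulse.** FIR order 64 (zero-phase), trim 64 ms, AR(30)
  forecast from −64 ms across the pulse; the Hilbert transform is applied
  to the trimmed signal plus a 256 ms forecast so its edge stays clear of
  the t = 0 readout; cosine convention (0 = peak, ±π = trough).  Measured:
  < 0.03 rad noiseless worst case, ~0.14 rad circular MAE at 10 dB SNR.
* **MEP scoring.** Per trial and muscle: pre-pulse linear detrend, then the
  exponential artifact fit (A·e^(−t/τ) + B on 2–15 ms, subtracted for
  t ≥ 0), then the 50 Hz notch, then peak-to-peak in 20–45 ms.  The
  artifact fit must precede the notch: the notch's transient response to a
  multi-mV step leaves a ~0.13 mV residual otherwise.  Recovery is within
  ~3% (the notch removes genuine MEP energy near 50 Hz) for amplitudes
  ≥ 0.05 mV noiseless and ≥ 0.2 mV at 10 µV noise; below that the
  peak-to-peak statistic is biased by the noise's own extrema (expected
  max−min of 10 µV noise over the window is ~40 µV), an intrinsic property
  of range-based scoring, not of the implementation.
* **Median split ties.** Values equal to the median are assigned to the
  currently smaller set, alternating (HC first) when equal — deterministic
  and guaranteeing | |HC| − |LC| | ≤ 1 under arbitrary ties.
* **MPSI.** Hann-windowed 1 s segments, 1 Hz native resolution, frequencies
  f_μ−2…f_μ+2; whitening by regularized inverse matrix square roots
  (diagonal loading 1e−8 × trace/n; scalar blocks inverted exactly so the
  bivariate case reduces to the textbook coherency PSI with zero error).
  Sign convention: positive ψ ⇒ first argument leads, fixed by constructed
  delays in tests.  Jackknife SDs at machine-epsilon scale (identical
  segments) are treated as degenerate rather than divided by.
* **Robust AIC.** Models are fitted by IRLS with Tukey bisquare weights
  (c = 4.685, tol 1e−8, ≤ 50 iterations).  AIC uses the *unweighted* RSS of
  the converged robust coefficients: comparing each model's own weighted
  RSS is biased toward larger models (their smaller scale estimates shrink
  the weights), measured as a collapse of null constant-model recovery from
  ~0.7 to ~0.37.  Even so, argmin-AIC retains one junk predictor with
  asymptotic probability P(χ²₁ > 2) ≈ 0.157, capping constant-model
  recovery near 0.75 against four larger candidates — a property of AIC
  itself, visible in the acceptance numbers.
* **Plausibility bands.** Preferred = min AIC (ties → fewest coefficients);
  ΔAIC ≤ 7 plausible, beyond not plausible; margins < 2 annotated as mildly
  preferred.  The bundled eight-subject reference AIC table reproduces the
  published preference counts (4/8 network+phase, 2/8 network) under these
  rules; its published plausibility labels are internally inconsistent
  around Δ ≈ 4.5, so per-cell label agreement is not a supported contract
  and the threshold is configurable.

## Limitations

* The lead field is a smooth analytic kernel, not a boundary-element head
  model; positions are inputs and no realistic skull conductivity profile
  is modelled.
* Per-trial iPLV measured through the full sensor → eLORETA chain tracks
  the per-trial truth phase-locking (ρ ≈ 0.4) but tracks κ itself weakly
  (ρ ≈ 0.2): the f_μ ± 1 Hz filter removes part of the phase-wander
  sidebands that carry the κ signature.  This attenuation is physical —
  1 s, 2 Hz-band epochs — and is why cohort-scale power statements are made
  at the oscillator level.
* ICA on fully synthetic sessions separates the motor oscillators poorly:
  OU-phase-diffused sinusoids mixed with Gaussian backgrounds are close to
  Gaussian, so FastICA has little contrast to work with.  The μ-component
  selection rules are therefore validated on constructed components, and
  the source-space pipeline does not require the ICA cleaning step on
  artifact-free synthetic data.
* Trial-order effects (habituation, ISI structure) are not simulated beyond
  bookkeeping; the control splits are calibrated on stationary MEPs and
  their sensitivity is demonstrated with an injected linear drift.
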