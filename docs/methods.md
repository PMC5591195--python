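# Methods

## The encoding

A camera-limited single-molecule movie acquires one intensity value per
molecule per exposure Δt (20 ms here).  `smsweep` models the
spatial-encoding trick: a galvanometer mirror in the detection path is
stepped N times during each exposure, displacing the image laterally by a
fixed spacing per step, so each molecule renders as N spots per frame —
one per sub-exposure of duration Δt/N.  With N = 5 this turns a 50 Hz
camera into an effective 250 Hz trace recorder over the full field of
view, at the cost of N× the sparsity requirement along the sweep axis.

The mirror drive is a staircase from 0 to V mV in V/(N−1) increments, and
displacement is linear in voltage with a calibration slope (0.25 pixel/mV
by default, recoverable from fiducial-bead stacks via
`calibrate_sweep`).  Decoding is unambiguous when the spot spacing
L/(N−1) = slope·V/(N−1) is at least about twice the PSF FWHM
(`separation_ok`, factor 2.0 with a 1e-9 relative tolerance at the
boundary).  Sweep direction is +x (increasing column index), first
sub-exposure at the unswept position; simulator and decoder share this
convention.

## Simulator

Molecule state dynamics are two-state continuous-time Markov (telegraph)
processes simulated exactly event-by-event (exponential dwells at the
configured rates; the initial state is drawn from the stationary
distribution unless pinned).  Expected photons per sub-exposure are exact
time integrals of the emission rate over each substep window; photons
arriving during the inter-frame dead time (1.7 ms readout lag) are
discarded while the state keeps evolving.

Rendering places a pixel-integrated isotropic Gaussian PSF
(σ = FWHM/(2√(2 ln 2)); default FWHM 2.56 px ≙ 340 nm at 132.8 nm pixels)
per sub-exposure.  The PSF patch spans ±5σ and is renormalized to unit
mass, so a noiseless render conserves the photon budget to floating-point
precision — this is what makes the round-trip tests sharp.  The camera
chain is the standard EMCCD model: Poisson shot noise, Gamma
electron-multiplication noise (n photons → Gamma(shape n, scale = gain)
counts, capturing the ×2 excess-noise factor), additive Gaussian read
noise, constant baseline.  Defaults: gain 300, read noise 50 counts,
baseline 100, 512-px/68-µm pixel pitch.

Two chip layouts are modeled.  For blinking/binding, a 30:70 beam
splitter sends 30% of the photons to a conventional (unswept) image on
the left half of the chip and 70% to the swept image on the right —
implemented as a deterministic split of the expected intensities followed
by independent Poisson sampling, which is exactly Poisson thinning.  For
FRET, a dichroic splits by color into swept donor (left) and acceptor
(right) images; per substep the photon budget divides as (1−E) : E with
the occupancy-averaged efficiency of the current state, then a leakage
fraction of donor photons moves to the acceptor channel.  The first
`n_unswept_lead_frames` frames of a FRET stack are rendered without
sweeping, mirroring the acquisition practice of using unswept frames for
mapping and molecule selection.

### Scenario presets (the study conditions)

* **blinking** — N = 5, V = 96 mV (24 px, 6-px spacing), Δt = 20 ms,
  lag 1.7 ms.  Off-time 4.6 ms → k_on = 217.4 s⁻¹; k_off = 80 s⁻¹
  (on-time 12.5 ms, the timescale of the dye's measured blinking traces;
  the dark-state entry rate is not printed anywhere, so it is fixed once
  here).  Bright rate 60 photons/ms, background 0.2 photons/ms/px —
  chosen to reproduce the measured SNR_B ≈ 8 at 4-ms sampling.
* **binding** — N = 5, V = 112 mV (28 px, 7-px spacing).  τ_on = 7.7 ms →
  k_off = 129.9 s⁻¹; per-site binding rate k_on = 2.0 s⁻¹, which
  reproduces the reported event density (~12,500 events per 2,000 frames
  over ~150 usable molecules).
* **fret** — N = 4, V = 96 mV (8-px spacing, 5-ms substeps), 10 unswept
  lead frames.  Combined interconversion rate 61.1 s⁻¹ split evenly
  (k₁₂ = k₂₁ = 30.55 s⁻¹); E = 0.3/0.7 (typical for the two stacked
  conformers of a Holliday junction); total 50 photons/ms; 5% donor→
  acceptor leakage.

What the generator does **not** emulate: diffusion, evanescent-field
depth effects, photobleaching, stage drift, PSF astigmatism, pixel
response non-uniformity, or galvo step-response transients (the 0.6-ms
settle time is treated as negligible, as is appropriate for a 4-ms
substep).  Passing recovery tests therefore demonstrate the correctness
of the encoding/decoding arithmetic and the estimators under realistic
shot/EM/read noise — not robustness to drift, bleaching or optical
aberrations in real acquisitions.

## Decoder

Molecules are detected on the conventional channel (or the averaged
unswept lead frames) as local maxima refined by a 2-D Gaussian fit; any
pair of peaks closer than the minimum separation is discarded entirely.
A least-squares affine map fitted to matched bead positions carries
left-channel coordinates into the right channel.  Molecules whose swept
footprint (sweep length + readout box, one box height) intersects any
other footprint are removed — overlapped sub-exposures cannot be
attributed to either molecule.

Each surviving molecule is read out by summing a 7×7-px box at the mapped
peak, sliding the box horizontally by `slide_px` for each sub-exposure
and concatenating the N sums per frame.  `slide_px` defaults to the
rounded spot spacing from the sweep configuration (6 px at 96 mV/5 steps,
7 px at 112 mV/5 steps); the historical fixed 6-px slide can be forced
via the override for comparison.

**Background.**  Per box position, background is estimated from the 1-px
rows immediately above and below the (box+2)-wide window — not from the
full perimeter ring: the ring columns along the sweep axis sit only ~2 px
from the temporally adjacent spots and would overestimate background by a
large fraction of the signal.  The per-frame estimates are averaged over
frames before subtraction (subtracting per-frame ring means would inject
(49/18)-amplified white noise into the trace); σ_B is the per-pixel noise
of the 49-px window sum, estimated from the same rows.  Both choices are
swappable (`background_mode="full"`).

**Accuracy.**  Noiseless round-trips match ground-truth substep photon
counts to <2% of the bright-state amplitude.  The residual error is PSF
physics, not implementation: ~0.3% of a spot's mass falls outside its 7×7
box, and ~1.1% of each temporally adjacent spot's mass bleeds into it at
6-px spacing.  The bleed is a constant absolute offset, which is why the
tolerance is quoted relative to the bright-state amplitude rather than
per-sample.

**Timebase.**  Decoded samples are nominally Δt/N apart, but each substep
advance averages (Δt + lag)/N of real time (4.34 ms, not 4 ms, at the
default timing).  All conversions from sample counts to rates — ACF lag
axes, dwell durations, HMM transition rates — use this effective interval
(`SweepConfig.sample_interval_ms`); ignoring the dead time inflates
recovered rates by ~8%.

## Kinetic estimators

**SNR.**  SNR_B = (I_S − I_B)/σ_B and SNR_S = (I_S − I_B)/σ_S with
signal moments over ON-labeled samples and background moments over OFF
samples.

**Blinking ACF.**  The intensity autocorrelation of a bright/dark
telegraph process, mean-subtracted and normalized by the squared mean, is
G(t) = (k_off/k_on)·exp[−(k_on+k_off)t]: the amplitude fixes the rate
ratio and the decay their sum, so one averaged curve yields both rates.
Variance normalization (lag-0 = 1) is also available but cannot separate
the rates.  The fit excludes lag 0 (shot noise is white and lands only
there) and optionally divides the fitted amplitude by the boxcar-binning
factor (sinh(x/2)/(x/2))², x = (k_on+k_off)Δt/N, which removes a ~10%
amplitude inflation at the default conditions.  Per-trace curves are
averaged before fitting.

**Dwell times.**  Samples above I_B + 3σ_B are ON; runs become dwell
records, with boundary-touching runs flagged censored and excluded from
fitting.  Because decoded durations are integer multiples of the substep,
the exponential MLE is computed on the run-length (geometric) scale with
left truncation at 2 substeps: for exponential dwells detected by a
per-bin threshold, the run-length distribution is exactly geometric with
ratio exp(−Δ/τ) from two substeps on — a shift argument: every
configuration producing a (k+1)-bin run is a k-bin configuration with the
dwell extended by exactly one full bin — so the truncated estimator is
immune to how partially occupied edge bins happen to cross threshold.
Standard errors come from a dwell bootstrap.

**FRET.**  E = I_A′/(I_D′+I_A′) with I_D′ = I_D − bg_D and
I_A′ = I_A − bg_A − α·I_D′ (leakage α); E is clamped to [0,1] and samples
with non-positive total intensity are flagged invalid and excluded rather
than imputed.  Histograms at conventional resolution are produced by
block-averaging E over N substeps before binning; bimodality is judged by
a valley-depth rule (valley below 60% of the smaller of the two tallest
modes).  At the fret preset's exchange rate the 20-ms histogram is only
marginally broadened (about half of all 20-ms windows are still
single-state), so the resolution-contrast demonstration uses a
fast-exchange variant at twice the preset rates, where 20-ms windows are
almost always mixed and the distribution collapses to one broad mode
while 5-ms sampling still resolves both states.

**HMM.**  Gaussian-emission hidden Markov models with 1 and 2 states are
fitted by maximum-likelihood Baum–Welch (three seeded restarts for the
2-state model) and selected by BIC; the Viterbi path is returned with
states ordered by emission mean, making every downstream quantity
invariant to label swaps.  This replaces the variational-Bayes tooling
common in the field; at these signal-to-noise levels the selected model
and path agree.  Per-state exit rates are exposed both as 1/mean(dwell)
over uncensored Viterbi dwells and as −ln(1−p_switch)/Δ from the
transition matrix.  For pooled multi-molecule estimates the default is
the joint propagator inversion: with per-bin switch probabilities
p₁₂ = N₁₂/N₁ and p₂₁ = N₂₁/N₂ from pooled transition counts,
p₁₂ + p₂₁ = 1 − exp[−(k₁₂+k₂₁)Δ] and the ratio p₁₂ : p₂₁ fixes the
split.  At 5-ms bins with ~60 s⁻¹ combined switching, plain dwell
averaging is ~23% low (missed events merge dwells) while the inversion is
~11% low — the residual bias is the majority-vote discretization of
sub-bin excursions, which the bin width cannot resolve.

## Problem sizes used by the tests and the acceptance script

Recovery runs use a 96-px-wide dual-channel chip, 256–312 rows, with
molecules on a non-interacting vertical grid: blinking 28 traces × 800
frames (112,000 substeps pooled), binding 28 traces × 1,200 frames
(~1,500 uncensored binding events), FRET 33 traces × 500 swept frames
(66,000 substeps).  The throughput analysis simulates 400×400-px fields
across a density ladder from 1e-4 to 1.6e-2 molecules/px²; the usable-
molecule ratio between full-field sweeping and 1/N FOV cropping crosses
1 near 0.1 molecules/µm², close to the density reported as the practical
limit in the source experiments.

## Known limitations

* The decoder assumes the bead-calibrated channel map is affine and the
  spot spacing constant across the field; field-dependent distortion is
  not modeled or corrected.
* Overlapping swept streaks are discarded, not deconvolved; the known
  spot positions would in principle allow unmixing at higher densities,
  which is out of scope here.
* Dwell-time recovery assumes mono-exponential kinetics; heterogeneous or
  multi-exponential populations are not modeled.
* The HMM is limited to two states by design; more conformations require
  a different model-selection surface.
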