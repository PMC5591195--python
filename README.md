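# smsweep

Spatially encoded fast single-molecule fluorescence imaging: simulation,
decoding, and kinetic analysis.

Camera-based single-molecule fluorescence (TIRF + EMCCD) is limited to
~50–100 frames per second, and cropping the field of view to go faster
sacrifices the number of molecules observed — a real problem for weakly
interacting systems where events are rare.  A simple optical trick breaks
the trade-off: a galvo mirror in the detection path is stepped N times
*during* each camera exposure, so every molecule renders as N laterally
offset spots per frame.  One 20-ms frame then carries N = 5 time points at
Δt/N = 4 ms resolution, over the full field of view.  Decoding is just
photometry at N known offsets, provided the spot spacing
(slope·V/(N−1) pixels for drive amplitude V) is about twice the PSF FWHM
and molecules are sparse enough that swept streaks do not overlap.

`smsweep` provides, for people building or validating such an instrument
and for analysts of its data:

* **simulator** — swept (and conventional) dual-channel EMCCD movies from
  exact two-state telegraph kinetics: photoblinking, transient DNA
  binding, and two-state FRET (Holliday-junction-style), with
  Poisson/EM-gain/read-noise camera statistics and ground truth for every
  substep;
* **decoder** — spot detection, bead-based affine channel mapping,
  overlap filtering, and sliding-box extraction of background-subtracted
  traces at sub-frame resolution;
* **kinetics** — SNR metrics, blinking autocorrelation fitted with
  G(t) = (k_off/k_on)·exp[−(k_on+k_off)t], threshold dwell detection at
  I_B + 3σ_B with truncated exponential MLE (τ_on = 1/k_off), FRET
  efficiency E = I_A/(I_D+I_A) with background/leakage correction, and
  two-state Gaussian HMM (Baum–Welch + BIC) transition-rate estimation;
* **calibration & I/O** — voltage→pixel slope fitting from fiducial-bead
  stacks, multi-page TIFF + JSON-sidecar stacks, CSV/HDF5 traces, and a
  `smsweep` command-line interface with seeded, provenance-tracked runs.

See `docs/methods.md` for the model details, estimator derivations and
default parameter rationale.

## Worked example

Simulate a blinking experiment (5 steps, 96 mV, 20-ms exposure; off-time
4.6 ms, on-time 12.5 ms), decode it, and recover the rates from the
averaged autocorrelation:

```bash
smsweep simulate --scenario blinking --n-frames 400 --n-molecules 8 \
        --seed 42 --out movie.tif
smsweep decode --stack movie.tif --out traces.csv
smsweep analyze-blinking --traces traces.csv --substep-ms 4 \
        --interval-ms 4.34 --out acf.json
```

which prints

```
wrote movie.tif (400 frames, 8 molecules)
decoded 8 traces -> traces.csv
k_on=218.9/s k_off=86.2/s off-time=4.57 ms
```

The decoded 4-ms traces pool 16,000 substeps; the fitted dark→bright rate
k_on = 218.9 s⁻¹ corresponds to an off-time 1000/k_on = 4.57 ms,
recovering the simulated 4.6 ms, and k_off = 86.2 s⁻¹ approximates the
simulated 80 s⁻¹ (the amplitude of the ACF is the rate ratio, its decay
the rate sum).  `--interval-ms 4.34` is the real time per substep,
(20 + 1.7)/5 ms, accounting for the camera's inter-frame dead time.

The same pattern runs the other two experiments: `--scenario binding`
(τ_on = 7.7 ms DNA duplex, analyzed with `analyze-binding`) and
`--scenario fret` (Holliday-junction dynamics at 61.1 s⁻¹ combined
exchange, analyzed with `analyze-fret`).

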