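# Methods

This note documents the models, default parameters, and numerical choices
implemented in `hdmea`, along with the scope and limitations of the
synthetic generator. Defaults follow the published analysis conventions for
high-density CMOS-MEA recordings wherever such a convention exists; where
the convention is unstated, the choice made here is called out explicitly.

## 1. Geometry and containers (`hdmea.grid`)

Electrodes form a regular row-major lattice of 11.22 µm squares separated
by 0.25 µm (pitch 11.47 µm). All distances are Euclidean center-to-center
distances in µm; neighborhoods are Moore (8-connected). The full-array
electrode density is `100 · N · side² / area` = 91.9% for N = 236,880 over
5.5 × 5.9 mm.

Recordings are `(n_electrodes, n_samples)` float32 voltage matrices in µV.
The HDF5 container stores `/voltage` (electrode-major, chunked per
electrode), grid geometry and sampling rate as root attributes, and
free-form metadata as a JSON string; round-trips are bit-exact. Malformed
containers raise `FormatError` naming the missing field.

## 2. Signal conditioning (`hdmea.preprocess`)

- **Detrending**: independent least-squares line removal per 500-sample
  block (`scipy.signal.detrend` with breakpoints).
- **Spike band**: causal 2nd-order Butterworth high-pass at 100 Hz cascaded
  with a 2nd-order magnitude-normalized Bessel low-pass at 3000 Hz
  (`sosfilt`). If the low-pass corner exceeds 0.45 × rate it is clipped
  there with a warning.
- **Zero-phase band filters** (gamma 30–100 Hz, ripple 150–250 Hz, etc.):
  odd-length Hamming windowed-sinc FIR applied forward-backward
  (`filtfilt`), so band events keep their timing.
- **Morlet scalogram**: `W(b,a) = (1/a) ∫ f(t) G((t−b)/a) dt` with
  `G(x) = (πF_B)^{−1/2} exp(−x²/F_B) exp(2iπF_C x)`, `F_B = 5`, `F_C = 1`,
  scales `a = 1/frequency` on a log grid (default 120 points over
  0.1–250 Hz). The wavelet is truncated at |x| = 8 (envelope < 4·10⁻⁶) and
  applied by FFT convolution; a cone-of-influence mask flags frames closer
  to an edge than the truncated half-support. This transform is implemented
  directly (rather than via a library CWT) because of the `1/a` — not
  `1/√a` — prefactor; it is verified against direct numerical integration
  of the defining integral.
- **SNR**: global max |v| divided by the standard deviation of a
  user-specified quiet window (≥ 0.1 s), matching the rms convention of the
  hardware noise figure (9.43 µV rms).

## 3. Units (`hdmea.units`)

Spikes are threshold crossings of |v| (default ±80 µV after filtering; ±100
or ±200 µV for high-amplitude preparations), timestamped at the excursion's
absolute extremum, with a 1-ms dead time. Electrodes are merged into units
by: 1-ms firing histograms per electrode, cosine similarity ≥ 0.3 between
8-adjacent electrodes, connected components over those edges, then pooling
and 1-ms deduplication of the component's spikes. The unit centroid is the
mean electrode position.

DRG-style soma maps average the cosine similarity between each interior
electrode's waveform and its 8 neighbors (borders are NaN); somata are
called as connected components above mean + 2 SD of the map. Firing-rate
bands are `0`, `(0,0.1)`, `[0.1,0.5)`, `[0.5,1.0)`, `[1.0,2.0)`,
`[2.0,5.0)`, `[5.0,10.0)`, `≥10.0` Hz. Activity summaries report spikes,
active electrodes within a contact mask, and firing electrodes per 5-ms
bin.

## 4. Bursts (`hdmea.bursts`)

Network bursts (4 steps): pool unit spikes; split where ISI > 100 ms; merge
adjacent groups separated by < 300 ms; keep groups with ≥ 5 spikes from ≥ 2
units. Single-neuron bursts maximize the Poisson-Surprise
`S = −ln P(N ≥ n)` over candidate windows (runs of below-mean ISIs),
keeping bursts with S ≥ 10 and ≥ 3 spikes. `P(N ≥ n)` is evaluated via the
regularized incomplete gamma identity (`scipy.special.gammainc(n, µ)`),
falling back to a log-sum-exp of Poisson log-pmf terms when the tail
underflows double precision; both paths agree with 60-digit arbitrary-
precision sums to better than 10⁻⁸ relative.

The 12-parameter table: total spikes, burst count, mean IBI
(onset-to-onset), mean duration, mean spikes/burst, mean max frequency (MF:
peak 10-ms-bin rate within a burst), mean inter-MF interval (between
successive bursts' MF bin centers), and the CVs of IBI, duration,
spikes/burst, MF, IMFI. Quantities needing ≥ 1 (or ≥ 2) bursts are NaN.
Vehicle normalization reports each parameter as percent of the vehicle
value.

## 5. Connectivity (`hdmea.connectivity`)

For a directed pair ref → target, the synchronized-spike count is the
number of target spikes in `(t, t + 100 ms]` summed over reference spikes
`t` (a target spike inside two reference windows counts twice; the
surrogate normalization removes any bias this convention introduces). The
null is 100 surrogates that keep the target's first spike and permute its
ISIs, conserving count, span, and ISI multiset. `Z = (real − mean)/SD`
(sample SD, ddof = 1); degenerate surrogates (SD = 0) give Z = 0 when the
real count equals the surrogate value and NaN otherwise. Z ≥ 3 is called
excitatory, Z ≤ −3 inhibitory; ECR is `100 · |Z ≥ 3| / (n − 1)` partners
per unit. Calibration on independent Poisson pairs yields < 2.5% excitatory
calls at Z ≥ 3.

## 6. Axonal conduction (`hdmea.axon`)

- **Electrode selection**: the recording is cut into 50-ms frames; each
  electrode is summarized by its max-|v| time per frame, and it scores one
  synchronous firing when ≥ 4 of its 8 neighbors peak within < 1 ms.
- **Soma**: the largest 8-connected component of electrodes above the
  amplitude threshold (default 200 µV); its spike train is detected on the
  component's peak electrode.
- **STA**: soma-spike-triggered average in a ±3 ms window (triggers too
  close to the edges are skipped).
- **Front tracking**: noise level σ is the median per-electrode SD of the
  earliest sixth of the STA window; an electrode "fires" when its STA drops
  below −5σ. In each 0.1-ms frame the firing electrode farthest from the
  soma centroid is selected; its firing time is the time of its negative
  STA extremum on that side of the trigger (the max-amplitude convention,
  which is independent of per-electrode amplitude). Frames that re-select
  the previous electrode add no front motion and are dropped.
- **Velocity**: ordinary least squares of cumulative distance (mm) on time
  (ms) — the slope is m/s directly — with R² reported; plus the endpoint
  estimate distance/time.
- **Backpropagation**: a trigger backpropagates when ≥ 5 path electrodes
  farther than 35 µm from the soma cross −3σ in the 3-ms pre-soma window
  with distal-to-proximal timing (Pearson r(distance, time) ≤ −0.5).

## 7. Evoked responses (`hdmea.evoked`)

Per-unit post-administration histograms (100-ms bins over 10 s, raw
counts) are clustered with Ward-linkage agglomerative clustering
(`scipy.cluster.hierarchy`, default k = 5). Cluster summaries report the
peak of the cluster-mean rate, its bin-center time, the 10-s mean rate, and
per-condition cluster percentages.

## 8. LFP propagation (`hdmea.lfp`)

An event in a region is a maximal run of frames where ≥ 3 region
electrodes exceed the amplitude threshold (default 5 × the median quiet-
period SD, a documented choice). Propagated area is the distinct-electrode
footprint × pitch² (cell area), so it is invariant to sampling rate; areal
velocity is area/duration. Region synchrony counts cross-region event
pairs with onsets within 50 ms. Region masks are user-supplied electrode
sets (JSON).

## 9. Synthetic generator (`hdmea.synthetic`)

Scope: the generator produces *plausible, ground-truth-labeled* recordings
for validating the analysis stages — it is not a biophysical simulator.

- **Trains**: homogeneous Poisson, or burst trains (Poisson burst onsets,
  dense intra-burst Poisson). Excitatory couplings add a follower spike in
  `(0, 100 ms]` with probability p; inhibitory couplings delete target
  spikes in the window.
- **Waveforms**: biphasic negative-first template (1 ms + 1 ms half-sine
  lobes, positive lobe at half depth), timestamp at the negative peak,
  spatial decay `1/(1 + d/λ)` with λ = 1 pitch over the footprint.
- **Axons**: a polyline path lights a lateral corridor of 1.2 pitches;
  latency = arc length / velocity; amplitudes decay with perpendicular
  distance; backpropagating events mirror the latencies with probability
  `backprop_p`.
- **Evoked templates**: cluster-specific gamma-bump rate profiles solved
  (by root finding on the profile integral) to match target peak rate, peak
  time, and 10-s mean exactly over a 1 Hz baseline; spikes are drawn by
  thinning.
- **LFP waves**: radially expanding oscillatory waves (activation time
  `onset + πd²/expansion_rate`).
- Gaussian noise at 9.43 µV rms is generated directly in float32; the whole
  simulation is a deterministic function of `rng_seed`.

Limitations: no electrode-level gain/offset variation, no spike-waveform
jitter or bursting adaptation, no overlapping-spike collisions, no volume-
conduction crosstalk between units, and LFP waves are kinematic rather than
current-source-derived. These are deliberate: each stage's estimator is
tested against exactly the structure it claims to recover.

## 10. Numerical and testing choices

- All acceptance-style checks run on one CPU in seconds to a couple of
  minutes; problem sizes (e.g., 9 × 120 grids at 10 kHz for conduction,
  500 Poisson pairs for calibration) are package choices balancing
  statistical power against runtime.
- Independent oracles used in the tests: 60-digit `mpmath` tail sums for
  Poisson-Surprise, direct Riemann-sum evaluation of the CWT integral,
  O(n·m) brute-force synchronized-spike counting, and hand-computed
  arithmetic for burst tables, areas, and densities.
- Seeds: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; derived seeds stay below 2³¹.
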