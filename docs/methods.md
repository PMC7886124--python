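# Methods

This note documents the models, conventions and numerical choices behind
`rgctypes`, and what the synthetic benchmark does and does not demonstrate
about recorded data.

## Stimuli

All stimulus programs are evaluated in linear display units (black 0, grey
128, white 255; the projector is assumed linearized) on a configurable
grid, default 1 kHz, matching the 1 ms response binning so stimulus and
response share one time base for the FFT-ratio computation.

* Gratings: the 24-stimulus grid is the Cartesian product of spatial
  periods {100, 200, 500, 1000, 2000, 4000} um and temporal frequencies
  {1, 2, 4, 8} Hz, full contrast, 12 s per presentation, one direction.
* Frequency-ramp chirp: `I(t) = 128 + 128 sin(pi (t^2 + t/10))` over ~8 s.
  The analytic instantaneous frequency of this phase is `t + 0.05` Hz —
  0.05 Hz at onset, reaching 8 Hz at t = 7.95 s. The nominal description of
  the ramp as starting at 0.5 Hz is inconsistent with the formula; the
  package implements the formula exactly as given and exposes
  `chirp_instantaneous_frequency` for inspection rather than guessing a
  corrected phase.
* Contrast ramp: 2 Hz carrier with amplitude growing linearly 0 → 128 over
  8 s (the linear ramp shape is this package's choice), preceded by a 2 s
  grey lead-in that the analysis uses as the local background window.
* Bars: 1000 um extent, black or white on grey, speeds {1, 2, 4, 8, 16}
  mm/s with 3 s gaps. A bar's response epoch lasts
  `(extent + receptive-field span)/speed`; the span (default 300 um) is a
  simulator parameter, not a stimulus property.
* Flashes: grey → black → grey → white → grey, 2 s per step. Weber
  contrasts at these display levels are −1 (grey→black) and +0.992
  (grey→white, 255/128); the asymmetry is kept as computed.
* Unit conversions: 266 um on the retina per degree of visual angle;
  spatial frequency = 266/period (cyc/deg), speed in deg/s =
  1000·(mm/s)/266.

## Response representations

**Binary binning and trial averaging.** Responses are per-trial binary
vectors at 1 ms resolution (a bin with one or more spikes is 1). All
Fourier analyses operate on the trial-mean binary vector; trial averaging
always precedes the transform.

**Firing rates.** Rates are sums of unit-area Gaussian kernels (default
sigma 40 ms) evaluated on the 1 ms grid; the kernel is renormalized on the
grid so a trace integrates to the spike count to better than 1e-4.

**Grating F1 strength and validity.** The trial-mean vector is zero-padded
to the next multiple of 8 s so the FT grid has exactly 0.125 Hz resolution
and all stimulus frequencies lie on-grid; no taper is applied. Strength is
the amplitude (2/N scaling) at the stimulus frequency. The response is
*valid* only if the spectrum has a strict local maximum within one bin of
the stimulus frequency and no higher local maximum elsewhere — excluding
DC ± 2 bins and harmonics of the stimulus frequency ± 1 bin ("peak" is not
defined by the source description; strict three-point local maxima are this
package's reading, with harmonics excluded rather than compared). Invalid
entries carry strength 0 in the 6×4 map; maps are normalized so the best
valid entry is 1. Zero-padding leaks a small Dirichlet skirt around strong
components; the DC exclusion zone and the harmonic tolerance absorb it in
practice, and very weak responses whose leak-level peaks dominate are
(conservatively) marked invalid.

**Chirp FFT ratio.** Response and stimulus are transformed on the same
8 s / 0.125 Hz grid; both amplitude spectra are max-normalized on the
analysis band [0.5, 8] Hz and divided pointwise, so the ratio is O(1) and
common factors cancel in every downstream index. Outside the band the
stimulus spectrum vanishes and the ratio is undefined; stimulus amplitudes
below 1e-6 of the band maximum raise an error. The displayed ratio is
smoothed with a centered 3-point (0.375 Hz) moving average; the chirp
frequency index applies its own 0.3 Hz smoothing to the raw ratio
independently, as the two smoothings are described separately.

**Flash PSTH and the response criterion.** The trial-averaged sigma = 40 ms
rate trace covers one 10 s flash sequence. Spontaneous statistics come
from the 2 s grey window before the first contrast step; the SD is pooled
over *single-trial* rate samples, not taken on the trial-averaged trace.
This choice matters: the expected maximum of the averaged baseline over a
2 s search window sits near 2.8 of its own SDs, so a "mean + 2 SD"
criterion applied with the averaged-trace SD would flag noise in
essentially every Poisson-spiking cell, while the pooled SD keeps the
stated rule usable (false-positive rate under 1% at 10 repeats in direct
measurement). Each transition's peak is searched in its 2 s step window
with two causal guards: the final 3 sigma are trimmed (the kernel bleeds
the *next* transition's response backward), and when the trace enters a
window non-increasing across the boundary, the initial non-increasing run
is skipped (a decaying leading edge is the *previous* transition's smoothed
tail — without this, genuinely sustained cells are systematically labeled
ON-OFF). Positive-contrast transitions are grey→white and black→grey;
negative are grey→black and white→grey.

## Per-cell indices

* Polarity: ON if only positive transitions exceed spontaneous mean +
  2 SD, OFF if only negative, ON-OFF if both, none otherwise.
* Transiency: time from the strongest responding transition's peak to the
  first sample at or below baseline + 2 SD, capped at the 2 s step.
* Median speed: first speed (ascending, no interpolation) at which the
  cumulative sum of per-speed peak responses reaches 50%; cells responding
  to both bar polarities report the higher of the two medians. Per-speed
  peaks are background-subtracted, and a bar response must exceed
  spontaneous + 4 SD (single sweeps are noisier than averaged responses).
* CPI: sums of |rate − background| over the first vs last thirds of the
  contrast ramp, background estimated from the 2 s grey immediately before
  the ramp; `(high − low)/(high + low)`.
* CFI: mean 0.3 Hz-smoothed FFT ratio over 6–7.2 Hz vs 0.7–3 Hz, same
  index form.
* Gaussian fit: weights are the valid map entries normalized to sum 1 (an
  unnormalized dot product has no centroid interpretation), axes in native
  linear units (um, Hz) by default — consistent with reported cluster
  preferences in the few-thousand-um / few-Hz range — with a log2-axis
  option behind a flag. The centroid is reported as the spatial/temporal
  preference; being a convex combination it cannot leave the grid, and a
  map whose maximum sits on the grid border is flagged (`edge_peak`), since
  preferences at the extremes cannot be localized further.

## The typing cascade

Step 1 applies the five assignment rules with transiency threshold 400 ms and
the sustained-ON margin `(high − low) < 0.2`, where high/low are the median
FFT ratios over [4.25, 8] Hz and [0.5, 4.25) Hz (the band midpoint; edges
configurable). Step 2 measures similarity on the chirp segment only (the
cells in this step have no flash response to compare), both cell trace and
template max-normalized on a shared 10 ms time base; a cell is assigned to
the best cluster whose threshold mean_c + std_c (statistics of the step-1
assignees) it meets. Step 3 groups leftover chirp responders by flash
polarity (ON → 6, OFF → 7, none → 8; an ON-OFF cell here — never observed
in the reference data — is routed to 6 or 7 by its larger transition peak
and logged). Step 4 runs k-means (squared Euclidean, default 1000
restarts, seeded) on the normalized 24-entry maps for k = 2..12 and picks
the k minimizing the sum of the Calinski-Harabasz rank (descending) and
Davies-Bouldin rank (ascending), smaller k on ties. The candidate k is
additionally capped so each cluster could hold at least two cells
(k ≤ n/2): on small pools both indices monotonically favor near-singleton
clusterings (DB → 0 as clusters shrink to points), which over-fragments
pools far smaller than the ~125-cell pool the defaults were designed for.
Step 5 assigns chirp-unprobed cells to the nearest cluster-mean map,
accepted within the 95th percentile of member similarities ("within the
95%" read as the 95th percentile rather than mean ± 1.96 SD); clusters
with fewer than two members have no percentile and are excluded.

A unit that fails every gate (no chirp probe and no valid grating map, or
a chirp non-responder without grating responses) is reported as dropped;
every unit receives exactly one of {cluster, unassigned, dropped}.

Chirp responsiveness itself — the gate between steps 1–3 and step 4 — is
not defined by the source description (responding cells were identified by
inspection); the package uses peak of the trial-averaged chirp rate above
spontaneous mean + 3 pooled SDs.

## Synthetic populations

Cells are linear–nonlinear–Poisson cascades. The full-field drive is the
intensity deviation from grey passed through a first-order high-pass
filter with time constant `kinetic_tau` (a step becomes `exp(−t/tau)`:
small tau transient, large tau sustained) and half-wave rectified by
polarity (ON keeps positive, OFF negative, ON-OFF both). Gratings enter
through their F1 drive only — a half-rectified sinusoid at the stimulus
frequency scaled by separable Gaussian tuning in (log2 period, log2
frequency); the half-rectified carrier is used for every polarity because
a full-wave |sin| drive would put an ON-OFF cell's grating energy entirely
into the second harmonic, which the F1 analysis cannot see. Contrast acts
through Naka-Rushton saturation `c/(c + c50)`; bars through Gaussian speed
tuning on log2 mm/s; all tuning lives on log2 axes because the stimulus
grids are octave-spaced. Rates are clipped to [0, max_rate]. Spikes come
from inhomogeneous-Poisson thinning with a 1.5 ms absolute dead time
(greedy keep-first), so simulated trains satisfy the refractory QC the
analysis enforces; constant-rate trains are mildly sub-Poisson (Fano
~0.95 at 20 Hz).

Ten archetypes cover the families the cascade must separate: transient
ON/OFF (broad spatial tuning, high temporal preference, high contrast
gain), sustained ON/OFF (tau = 4 s so the response genuinely outlasts the
2 s step; low contrast gain, flat temporal tuning), transient ON-OFF,
low-temporal-frequency ON/OFF full-field responders, and three
grating-only archetypes with narrow spatio-temporal tuning that ignore
full-field stimuli. Defaults: 3 grating repeats, 5 chirp repeats of each
kind, 10 flash sequences, 1 bar sweep per speed and polarity. Ten flash
repeats (rather than five) keep the 2-SD polarity rule's Poisson
false-positive rate below 1%; with five repeats the rule mislabels a
substantial fraction of sustained cells ON-OFF, which is a property of the
criterion, not of its implementation. Population noise (default 0.3)
applies additive jitter of 0.5·noise octaves to tuning centers and
multiplicative log-normal jitter of sigma 0.3·noise to gains and time
constants, on top of Poisson spiking.

What the generator does *not* emulate: spatial receptive-field structure
(no center-surround, no position-dependent grating phase), adaptation and
slow drift, correlated noise across cells or trials, direction
selectivity, and the real reference templates for the five dominant
clusters (the bundled templates are the noiseless flash+chirp traces of
the synthetic archetypes; external template files can replace them).
Passing recovery benchmarks therefore shows the pipeline is correct and
well-conditioned under the stated statistical structure — not that real
recordings will cluster this cleanly.

## Benchmarks computed by the test suite

* Tuning recovery: 100 noise-free (jitter-0, Poisson-spiking) cells with
  tuning centers on the stimulus grid; ≥ 95% recover spatial and temporal
  preference within one octave, and ≥ 95% their polarity. On deterministic
  rate traces polarity recovery is exact for every archetype.
* Model selection: 3 well-separated map archetypes, 30 cells each, map
  noise sigma 0.05 — chosen k = 3 with ARI 1.0; k-means with 1000 restarts
  matches the brute-force 2-partition optimum on 10 points.
* End-to-end: 8 archetypes (5 dominant + 3 grating-only) × 25 cells at
  default noise, protocol without bars, seeds 1–5 — ARI ≥ 0.8 against
  ground truth for every seed (measured 0.96–0.98).
* Determinism: identical seeds give byte-identical pipeline outputs.

These problem sizes are the package's benchmark conditions; larger
populations only improve the statistics.

## Known limitations

* The peak-validity rule inherits zero-padding leakage conservatism: weak
  but genuine responses near the noise floor may be marked invalid.
* Transiency is a first-crossing statistic on a noisy trace and is biased
  short near the threshold; the sustained/transient rule boundary at
  400 ms is sharp, so cells with borderline kinetics can change step-1
  cluster between repeats.
* Step-2 thresholds depend on the step-1 population; with very few step-1
  assignees the mean + SD gate is poorly estimated (clusters with none are
  skipped with a warning).
* The CPI background window assumes a grey lead-in before the contrast
  ramp; protocols without one must supply their own background estimate.
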