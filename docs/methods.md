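# Methods

This note documents the models implemented in `synapsync`, the design
choices made where the underlying physiology leaves the implementation open,
and what the synthetic-data tests do and do not establish about real
recordings.

## The correlation → synchrony model

Two postsynaptic cells (A17-like) sample a common presynaptic population
(RBC-like) such that a shared presynaptic cell contacts each postsynaptic
cell at a *different* synapse. If release at different synapses of one
presynaptic cell covaries with strength `β_sync` (the cross-synaptic
synchrony, 0 = independent, 1 = perfectly synchronized), the zero-lag
correlation of the two recorded currents is

    CC(0) = β_sync · Σ_r P_shared(r) n_r w(r) / Σ_r n_r w(r),
    w(r) = exp(−2 (r + r0) / γ)

where the sum runs over concentric rings of the connectivity table. The
numerator is the electrotonically weighted shared input, the denominator the
total input; their ratio (`css_slope`) is a purely anatomical
proportionality, so measurement reduces to `β = CC_peak / slope`.

Assumptions worth keeping in mind:

- **Complete dendritic overlap** of the two recorded cells. Real pairs
  overlap partially, which biases the model towards *underestimating* the
  synchrony needed for a given correlation. For this reason estimates above
  1 are reported with a warning, never silently clamped.
- **One synapse per shared presynaptic cell per postsynaptic cell.** A
  shared cell contributing multiple synapses to one recorded cell would add
  within-cell coherence not described by the model.
- `w(r)` weights *variance*: current amplitude attenuates as
  `exp(−(r+r0)/γ)` along the dendrite, and variance is amplitude squared.
  The synthetic generator applies the amplitude factor to its kernels so
  that its variance weighting matches the inference exactly.
- Per-lag normalization of the correlogram uses full-trace variances (the
  shared variance over the geometric mean of the two total variances), so
  `CC(0)` equals the Pearson correlation of the sample vectors and all
  values lie in [−1, 1].

**Slice correction.** Slicing truncates distal dendrites; `apply_slice_
correction` halves `n_r` in every ring after the first. On the default
table this moves the slope by ≈3 %, so conclusions are robust to the exact
treatment of distal contacts.

**Fixed slopes.** Published anatomical slopes (0.64 slice, 0.67 whole
mount) are available as `SLICE_SLOPE` / `WHOLEMOUNT_SLOPE` alongside
table-derived slopes.

**Default ring table.** `default_ring_table()` is a documented toy with the
canonical shape: four 20-µm rings at mean radii 10–70 µm, contact counts
(6, 12, 18, 24) growing with ring area, shared fractions (0.70, 0.62, 0.54,
0.46) declining with distance, `r0 = 40 µm`, `γ = 32.3 µm`. Its slope is
≈0.642. It is *not* digitized anatomy; it exists so that every stage of the
pipeline has a concrete, self-consistent input.

**Averaging convention.** Published per-condition synchrony values
correspond to dividing a mean correlation peak by the population slope
(ratio of means); per-pair estimates averaged afterwards give slightly
different numbers. The pipeline reports per-replicate estimates and their
mean ± SEM, so both reductions are available from the rows.

## The synthetic-data generator

The generator emulates the statistics the inference assumes, with a known
ground-truth dial:

1. Time is discretized into release-opportunity bins (`bin_width`, default
   2 ms — shorter than the kernel rise-to-peak). Each presynaptic cell has
   a *master* Bernoulli stream (`p_master` per bin).
2. Each synapse follows each master event with probability `q_follow` and
   releases independently at `r_async` per bin. Two synapses of one
   presynaptic cell therefore have per-bin correlation

       β = p q² (1 − p) / (p q (1 − pq) + r (1 − r))

   (`stream_correlation`; the `r = 0` case is `effective_css(p, q) =
   q(1−p)/(1−pq)`). `calibrate_q_follow` inverts this numerically so a
   scenario can request `target_css` directly; unattainable targets (the
   asynchronous floor caps the correlation) raise instead of clipping.
3. Wiring: within each ring, each of cell A's contacts is shared with cell
   B with probability `P_shared(r)` (independent Bernoulli draws); B
   receives fresh private cells for unshared slots so both cells see `n_r`
   contacts per ring. This per-pair wiring noise is the dominant source of
   replicate-to-replicate scatter in recovered synchrony (per-seed SD
   ≈ 0.17·β on the default table), which is why recovery experiments
   average ≥ 20 (typically 40) replicate wirings.
4. Events are rendered as a difference-of-exponentials quantal kernel
   (`τ_rise` 0.25 ms, `τ_decay` 2 ms, local amplitude −45 pA) scaled by
   `exp(−(r+r0)/γ)`, plus Gaussian instrument noise (`noise_sd`, default
   0.5 pA).
5. **Event timing.** Each event is placed uniformly within its bin rather
   than at the bin centre: aligning all events to bin centres on a shared
   sample grid imprints a deterministic 2-ms comb on the mean current of
   *both* traces, which measurably inflates their cross-correlation (an
   artifact of discretization, not of synchrony). Synapses following the
   same master event share that event's timing offset, so synchronized
   release still coincides exactly across cells; asynchronous events are
   jittered independently.
6. All randomness derives from one scenario seed through named substreams
   (`wiring`, `master`, `jitter`, `events/a`, `events/b`, `noise`), so
   fixed seeds give bit-identical traces and stages are independently
   reproducible.

An optional slow AR(1) modulation of the master rate (`tau_drive` 50 ms,
`modulation_depth`) emulates the broad temporal correlations of presynaptic
voltage noise in darkness. It defaults to **off** in quantitative
scenarios: shared rate drift contributes fully correlated covariance tails
that are not described by the per-bin dial above, so enabling it decouples
the ground-truth label from what a correlation measurement returns. It is
exposed for qualitative experiments (e.g. broadening autocorrelations).

Default rates were chosen once from the physiology being emulated: with
`p_master = 0.10` per 2-ms bin and a dark follow probability near 0.85, a
per-synapse event rate of ~40 Hz and the default anatomy give a somatic
trace variance of ≈72 pA² (Campbell's theorem), the scale recorded from A17
cells in darkness, with somatic event amplitudes of ~1.5–10 pA across rings
— consistent with a −2 pA detection threshold. `r_async = 0.005` per bin
provides a small asynchronous floor. The convergent-trace generator
(`generate_convergent_trace`) reuses the same machinery with many synapses
per presynaptic cell sharing one master stream, reproducing the quadratic
(coherent) versus linear (incoherent) growth of variance with synapse count
that distinguishes AII-like from A17-like noise.

**What passing tests show — and don't.** Parameter recovery on these
synthetics validates the *inference chain* (generation → correlation →
slope inversion) under the model's own assumptions: stationary rates, white
instrument noise, exponential attenuation, independent wiring, no
gap-junction coupling between the recorded cells, no 1/f noise, no vesicle
depletion. Real recordings violate several of these (drifting baselines,
partial dendritic overlap, electrical coupling, depression), so passing
tests certify the estimator, not the biology.

## Correlation analysis

- `cross_correlation` optionally averages correlograms over consecutive
  epochs (pipeline default 2 s), which bounds the influence of slow drift;
  whole-record analysis is the single-call default.
- The reported `peak` is the maximum over lags within ±`max_lag` (default
  ±200 ms). Under the null this statistic is positively biased (the max of
  a noise field; ≈ +0.02 at 120 s records), which is why a zero-synchrony
  scenario recovers ≈0.02–0.04 rather than 0. The bias shrinks with record
  length and is negligible once a genuine peak exists.
- `fwhm` interpolates half-maximum crossings linearly and raises when the
  function never crosses half maximum within the lag range.
- `noise_variance` subtracts a running-average baseline (window in ms; 0 =
  mean only) before computing variance.

**mEPSC detection** (`detect_mepscs`) detrends with a running median
(100 ms window — robust to fluctuating baselines), smooths lightly
(Gaussian σ 0.2 ms), and keeps contiguous sub-threshold excursions lasting
≥ 0.3 ms, merging excursions separated by < 1 ms (noise re-crossings during
a decay). The 10–90 % rise time is measured by walking back from the peak
through the 90 % and 10 % amplitude crossings with linear interpolation;
the event onset is the 10 % crossing. Events slower than `max_rise`
(default 1 ms) are *reported but flagged* non-mEPSC rather than dropped.
Defaults follow the standard criteria (threshold −2 pA, rise ≤ 1 ms). On
injected-kernel fixtures at SNR ≥ 6 the detector achieves ≥ 95 % recall at
≤ 5 % false discovery.

## Release model

- `β = 1/(1+CV²)` and its inverse `CV = sqrt(1/β − 1)` are exact
  arithmetic; a synchrony of 0.8 pins single-synapse CV at 0.5.
- The binomial CV `sqrt((1−Pr)/(N·Pr))` assumes `N` independent release
  sites with fixed vesicle availability and no quantal-amplitude
  variability; with `N = 10`, CV = 0.5 requires `Pr ≈ 0.286`.
- Monte Carlo trials draw one uniform number per site (`simulate_release`);
  saturation clips the vesicle count at a threshold. Two presets are kept
  deliberately — saturation at 2 and at 5 — because both appear in the
  source physiology and the choice trades dynamic range against
  reliability; neither is privileged.
- Empirical CV uses the sample (n−1) standard deviation over the mean. The
  population convention differs by `sqrt(n/(n−1))` — negligible at the
  conventional 200 trials, but the convention is fixed and documented.
- `cv_saturated_exact` computes the saturated CV from the binomial pmf
  (scipy); tests additionally verify it against an independent
  direct-enumeration oracle.

## Numerical choices and problem sizes

- Correlograms are FFT-based; values are clipped to [−1, 1] to absorb FFT
  round-off at the Cauchy–Schwarz boundary. Ties in peak location resolve
  to the most negative lag.
- Zero-variance traces, empty ring tables, non-positive slopes, and
  probabilities outside [0, 1] raise `ValueError` rather than propagating
  NaNs.
- Recovery experiments in the test suite use 120-s records at `dt` 0.1 ms
  and 40 replicate wirings per synchrony level, sized so that wiring noise
  (SE ≈ 0.02 at β = 0.8) sits comfortably inside the ±0.05 validation
  band; Monte Carlo release checks use 10⁵ trials with bootstrap standard
  errors.
- The pipeline names every output file by a SHA-256 hash of the fully
  resolved configuration and logs all defaults explicitly, so any number in
  a report can be regenerated byte-identically from its log.

## Known limitations

- No biophysical cable model: attenuation is a single exponential factor,
  and the two generated cells share no gap junction.
- No vesicle-pool depletion, replenishment, or presynaptic depression; the
  generator's rates are stationary within a record, and luminance series
  are modeled as independent stationary conditions (no adaptation
  transient).
- Instrument noise is white; real recordings carry 1/f and line components
  that inflate low-frequency correlations.
- The estimator consumes a single anatomical table per experiment; per-pair
  anatomical variability beyond the Bernoulli sharing model (e.g. soma
  distance) is not represented.
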