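# synapsync

Tools for quantifying **cross-synaptic synchrony (CSS)** — the degree to which
transmitter release covaries across the output synapses of a single neuron —
from paired postsynaptic current recordings, together with a quantal model of
what that synchrony implies about single-synapse reliability.

The motivating system is the mammalian retinal rod bipolar circuit. A rod
bipolar cell (RBC) releases glutamate from ~50 ribbon synapses; two A17
amacrine cells with overlapping dendritic fields receive input from many of
the same RBCs, each typically at a *different* ribbon of each shared RBC. The
correlation between the two A17s' excitatory currents therefore reports how
synchronously the ribbons of one RBC release — something that cannot be
observed at a single synapse under physiological conditions. The same
machinery applies to any circuit where two cells sample disjoint synapses of
a common presynaptic population.

## The model

With connectivity tabulated in concentric rings around the soma (mean radius
`r`, contact count `n_r`, shared fraction `P_shared(r)`), electrotonic
attenuation `exp(−2(r+r₀)/γ)` of each contact's variance (`r₀` = descending
dendrite length, `γ` = electrotonic length factor), the zero-lag
cross-correlation of the paired currents is proportional to the synchrony
`β_sync ∈ [0, 1]`:

    CC(0) = β_sync · Σ_r P_shared(r) n_r e^(−2(r+r₀)/γ) / Σ_r n_r e^(−2(r+r₀)/γ)
          = slope · β_sync

so `β_sync = CC_peak / slope`, where the slope is purely anatomical
(≈0.64 for slice recordings). Synchrony in turn bounds single-synapse
variability through

    β_sync = 1 / (1 + CV_single²),    CV_single = sqrt((1 − Pr) / (N·Pr))

for a ribbon with `N` active zones releasing with probability `Pr`
(optionally clipped by postsynaptic receptor saturation).

The package provides:

- `synapsync.synthetic` — a generator of paired A17-like traces (and
  convergent AII-like traces) with a *known* ground-truth synchrony dial,
  built from per-RBC master event streams thinned per synapse;
- `synapsync.correlation` — normalized cross-/autocorrelation, FWHM,
  running-baseline noise variance, and mEPSC detection (−2 pA threshold,
  ≤1 ms 10–90 % rise);
- `synapsync.connectivity` — the ring-table model, slope extraction, slice
  correction, and the CC → CSS inversion;
- `synapsync.release` — the binomial release model, Monte Carlo simulation
  with saturation, and exact pmf-based CVs;
- `synapsync.pipeline` / `synapsync` CLI — reproducible generate → correlate
  → infer experiments with mean ± SEM reporting.

## Worked example

Recover a known synchrony from synthetic paired recordings (20 replicate
wirings, 120-s records):

```python
import synapsync as ss

config = ss.ExperimentConfig(
    scenario=ss.PairScenario(duration=120.0, target_css=0.8),
    replicates=20,
)
report = ss.run_experiment(config)
s = report.summary
print(f"beta_hat = {s['beta_hat']['mean']:.3f} ± {s['beta_hat']['sem']:.3f} SEM")
print(f"cc_peak  = {s['cc_peak']['mean']:.3f} ± {s['cc_peak']['sem']:.3f} SEM")
print(f"trace variance = {s['var_a']['mean']:.0f} pA²")
```

prints

```
beta_hat = 0.810 ± 0.026 SEM
cc_peak  = 0.521 ± 0.017 SEM
trace variance = 73 pA²
```

The mean correlation peak (~0.52) divided by the default anatomical slope
(~0.64) recovers the dialled-in synchrony of 0.8 within its SEM; the trace
variance (~73 pA²) is in the range recorded from A17 amacrine cells in
darkness. Individual replicates scatter substantially because the shared
wiring itself is resampled each time — exactly as different recorded pairs
sample different anatomical overlaps.

The same chain from the shell:

```sh
synapsync generate --target-css 0.8 --duration 30 --seed 7 --out pair/
synapsync xcorr pair/trace_a.csv pair/trace_b.csv      # -> CC peak ...
synapsync css 0.51 --slope 0.64                        # -> CSS 0.797
synapsync release --n-sites 10 --saturation 2          # Pr sweep, CV table
synapsync sweep --levels 0.8,0.5,0.36 --replicates 20  # luminance-style series
```

`synapsync css 0.51 --slope 0.64` prints `CSS 0.797 (slope 0.640,
fixed_slope)` — the dark-adapted operating point; a peak of 0.23 (bright
light) maps to 0.36. Estimates above 1 are flagged rather than clamped,
since they indicate the anatomical model's assumptions (e.g. complete
dendritic overlap) are violated.

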