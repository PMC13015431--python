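# edgecrit

Criticality dynamics of pre-response EEG.

`edgecrit` asks whether the brain's position relative to the *edge-of-synchrony*
critical point — the transition between an asynchronous-irregular regime
(excitation-dominated, highly variable) and a synchronous regime (rigid,
reliable) — changes in the seconds before slow behavioral responses, and
whether groups (e.g. adults with and without ADHD) differ in the same way.
It is written for EEG researchers studying sustained attention, reaction-time
variability and critical brain dynamics.

## What it computes

For each 10-s pre-stimulus window (−10 s to −0.005 s relative to stimulus
onset), four families of criticality-sensitive metrics:

* **Long-range temporal correlations** via wavelet-leader multifractal
  analysis.  With leaders L(j,k) (suprema of L1-normalized Daubechies
  detail coefficients over dyadic neighborhoods and all finer octaves), the
  cumulants of log-leaders grow linearly across octaves,
  `C_m(j) ≈ c_m · j·ln2 + const`.  The first log-cumulant **c₁** indexes the
  dominant regularity (Hurst-like) exponent — maximal near criticality;
  **c₂ ≤ 0** indexes multifractality.
* **Aperiodic spectral exponent χ** (PSD ∝ f^−χ) from the same discrete
  wavelet transform (`log2` mean coefficient energy regressed on octave) and,
  independently, from an iterative aperiodic + Gaussian-peak decomposition of
  the Welch spectrum.  Steeper slopes indicate synchronous-ward,
  inhibition-dominated dynamics; flatter slopes asynchronous-ward.
* **Theta (4–7 Hz) and alpha (8–12 Hz) power over the aperiodic fit**
  (integrated fitted peaks).
* **Oscillatory variability**: the coefficient of variation of the
  band-averaged 3-cycle Morlet power time course.

Responses are typed per subject and modality by RT quartiles — *fast*
(rt ≤ Q1), *slow* (rt ≥ Q3), *average*, plus *passive* stimuli sampled from
no-response runs.  Electrodes are collapsed into thirteen six-electrode
Delaunay clusters (centroids F3, FCz, F4, C3, C1, C2, C4, P3, Pz, P4, O1,
Oz, O2), then to scalp level (all clusters for auditory analyses, occipital
only for visual).  Event types are compared across groups with a
2 × 4 mixed ANOVA (Greenhouse–Geisser correction when Mauchly's test
rejects sphericity, Holm post-hocs within, Tukey–Kramer between), and the
resulting direction pattern is classified against the edge-of-synchrony
prediction table (LRTCs index distance from criticality; slope indexes
direction; power and variability move inversely under the model).

A synthetic-data module supplies every input with known ground truth:
Kuramoto–Sakaguchi oscillator networks
(`dθᵢ/dt = ωᵢ + (K/N)·Σⱼ sin(θⱼ − θᵢ − α)`) whose order parameter R(t)
exhibits the asynchronous→synchronous transition as the coupling K grows;
power-law, fractional-Gaussian-noise and multifractal-cascade surrogates;
composite oscillation-plus-background epochs; bimodal
continuous-performance-task schedules (40-s runs, 25 stimuli per stream,
ISIs uniform on 700–2000 ms adjusted to ≥350 ms cross-stream separation);
and ex-Gaussian reaction times with an inflatable slow tail.

## Worked example

```python
import numpy as np
from edgecrit import synth, LapseDynamics, simulate_study

# 1. the oscillator model: sweep the coupling across the transition
base = synth.transition_demo_config(seed=1, n_oscillators=200, duration=30.0)
traces = synth.sweep_coupling(base, np.arange(0.5, 5.01, 0.25))
for K in (1.0, 2.0, 2.5, 3.0):
    print(f"K={K:<4} mean R = {traces[K].mean_R(discard=5.0):.3f}")
print("critical coupling ~", round(synth.summarize_transition(traces, 0.5, 5.0), 2))

# 2. a small simulated study through the full pipeline
table = simulate_study(n_control=3, n_adhd=3, n_per_event=2, seed=42)
res = LapseDynamics(table).fit()
print(res.anovas["dwt_slope"].table[["source", "F", "p"]].round(4))
print(res.regime_verdict(("slow", "fast")).report())
```

prints (exact numbers from this seed):

```
K=1.0  mean R = 0.092
K=2.0  mean R = 0.365
K=2.5  mean R = 0.749
K=3.0  mean R = 0.858
critical coupling ~ 2.13
        source         F      p
0        group   54.8926 0.0018
1       within  594.9365 0.0000
2  interaction   15.4915 0.0002
verdict=inconsistent_with_edge_of_synchrony; agreement: lrtc_c1:ok, spectral_slope:ok, lf_power:x, lf_cv:x
```

The order parameter stays near the finite-size floor (≈ N^−1/2) at weak
coupling and crosses toward phase locking between K = 2 and 2.5 for this
configuration.  In the simulated study, epochs preceding slow responses were
generated with a steeper aperiodic exponent and (in the clinical group)
deeper amplitude modulation; the pipeline recovers a strong event-type
effect on the wavelet slope, and the combination "LRTCs up, slope steeper,
variability up" is flagged as inconsistent with the edge-of-synchrony sign
table — the same qualitative pattern the metrics are designed to detect.

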