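# Methods

This note documents the models, estimators and design choices behind
`edgecrit`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic data
do and do not establish.

## Oscillator model

The Kuramoto–Sakaguchi network

    dθᵢ/dt = ωᵢ + (K/N) Σⱼ sin(θⱼ − θᵢ − α)

is the didactic model of edge-of-synchrony criticality: the phase-lag α
acts as an effective coupling delay, and the order parameter
R(t) = |N⁻¹ Σⱼ exp(iθⱼ)| moves from a finite-size floor (≈ N^−1/2) to
phase locking as the control parameter K crosses its critical value.
Integration is fixed-step RK4 (the mean-field identity keeps each step
O(N)); Euler at dt ≤ 0.5 ms gives indistinguishable R̄ but RK4 is the
default because the cost is negligible at these sizes.  Defaults: N = 200,
ωᵢ uniform on 2π·(8–12) rad/s (the alpha band), α = 0.4 rad, dt = 1 ms,
60 s with the first 5 s discarded as transient.

With the default 4-Hz-wide uniform frequency spread the mean-field critical
coupling K_c = 2/(π g(0) cos α) lies near K ≈ 16, far above the often-cited
2–2.5 window; that window is specific to much narrower frequency
dispersions.  `transition_demo_config` therefore provides a configuration
(Gaussian ω, 10 ± 0.2 Hz, α = 0.4) whose predicted K_c ≈ 2.4, so coupling
sweeps over [0.5, 5] display the transition where readers expect it.  The
transition estimate (`summarize_transition`) is the first threshold
crossing of R̄(K) with linear interpolation; with N = 200 and 30-s runs it
is stable to ±0.2 across seeds.  Tests and the demo use N = 150–200 and
24–30 s — sizes chosen so a full sweep finishes in tens of seconds while
keeping finite-size scatter in R̄ below the interpolation step.

## Surrogate signals

* **Power-law noise** — spectral synthesis with complex Gaussian
  coefficients shaped by f^(−β/2) at all positive frequencies, unit
  variance.  Used to calibrate both slope estimators.
* **Fractional Gaussian noise** — Davies–Harte circulant embedding; its
  cumulative sum is the fBm-like monofractal reference (c₁ = H, c₂ = 0).
* **Multifractal cascade** — a log-normal multiplicative cascade placed
  directly on the wavelet coefficients: each refinement multiplies child
  magnitudes by W with ln W ~ N(−c₁ ln2, −c₂ ln2), making the theoretical
  log-cumulant slopes exactly (c₁, c₂); signs are Rademacher and the signal
  is the inverse DWT.  c₂ = 0 degenerates to an exactly monofractal
  cascade.  Because synthesis and analysis share the wavelet domain, the
  recovery tests also check an independent structure-function oracle
  (ζ(q) at q ∈ {1, 2}; c₂ = ζ(2) − 2ζ(1), c₁ = ζ(1) − c₂/2).
* **Composite epochs** — power-law background plus narrowband sinusoids
  whose variance is set from the requested log10 band-power ratio over the
  background and whose envelope is a 0.5-Hz sinusoid with modulation depth
  in [0, 1].  These give joint ground truth for band power and Morlet CV.

## Task schedule and reaction times

Two independent onset streams with ISIs uniform on 700–2000 ms are adjusted
until (a) every pooled inter-onset gap is ≥ 350 ms and (b) every
within-stream ISI lies in 850–2300 ms — the documented post-adjustment
range of the task design.  The adjustment is rejection resampling of the
ISI preceding the earliest violating stimulus (bounded at 10⁴ retries, then
a deterministic shift-forward repair capped by the ISI ceiling), which
keeps the accepted ISI marginal uniform on the feasible set.  Reaction
times are ex-Gaussian (Normal(μ, σ) + Exp(τ)); with probability
`lapse_rate` the exponential scale is inflated (default ×4), reproducing
the heavy slow tail that drives reaction-time variability.  Defaults
(μ, σ, τ) = (400, 50, 100) ms give a 500-ms mean, matching typical
continuous-performance-task responding.

## Event typing and epochs

Quartiles use the linear-interpolation ("type 7") convention — the default
of mainstream numeric stacks — with inclusive ties (fast: rt ≤ Q1; slow:
rt ≥ Q3), computed per subject and modality, pooled across blocks.  Only
correct, responded trials enter the quantiles; omissions and errors are
unlabeled.  Windows are −10 s to −0.005 s (4998 samples at 500 Hz); windows
reaching before the recording start or into inter-run breaks are dropped
and counted.  Overlap between windows of nearby trials is deliberate — the
10-s history of one trial necessarily contains earlier trials.

## Wavelet scaling analysis

Daubechies-1 (Haar, one vanishing moment) decomposition with periodized
boundaries; boundary-affected coefficients (one per end per octave for
db1) are excluded from the statistics.  Analysis octave j maps to dyadic
scale 2^(j+1) samples, so the default octaves 2–7 on 500-Hz data have
lower band edges ≈ 31 … 0.98 Hz — the conventional 1–30 Hz working range
(`octave_frequencies` prints the table).  Leaders take the supremum over
the 3-neighborhood cone across all finer octaves, computed bottom-up from
octave 1 regardless of the analysis range.  (c₁, c₂) are slopes of the
scale-wise mean and variance of log-leaders against j·ln2, weighted by
leader counts (the standard weighting in the multifractal literature;
unweighted regression is a config switch).  Degenerate inputs: zero or
non-finite leaders yield NaN sentinels; zero within-scale variance (exact
deterministic scaling) legitimately yields c₂ = 0.  Epochs with
|c₂| > 0.04 are flagged as multifractal but retained — c₁ remains the
quantity of interest either way.  The DWT slope χ regresses log₂ mean
L2-coefficient energy on octave (for PSD ∝ f^−β the energy grows as
2^(jβ), so χ estimates β directly); calibration recovers β ∈ {0, 1, 2}
within ±0.1 at n = 2^16.

## Spectral decomposition

Welch PSD (2-s Hann segments, 50% overlap; 0.5-Hz resolution on 10-s
epochs); a multitaper variant (DPSS, NW = 4) is available.  The
aperiodic/oscillatory split fits log10 P = offset − χ·log10 f on 1–45 Hz
(no spectral knee over this range), with a robust first pass that discards
the top 15% of residuals so peaks do not tilt the line; Gaussian peaks
(center in range, σ 1–6 Hz, up to 6 peaks, threshold 2 residual SDs with
an absolute floor of 0.05 log10 units) are fit iteratively, largest first,
and the aperiodic line is refit on the peak-removed spectrum.  Band power
"above the aperiodic" is the closed-form in-band integral of peaks whose
centers fall inside the band; no peak in band means exactly zero.  The two
slope routes (DWT and aperiodic fit) agree within ±0.15 on peak-free
surrogates, which is the package's internal consistency check.

Theta is 4–7 Hz by default (3–7 Hz appears in parts of the literature; the
band is a config field).  Morlet variability uses 3-cycle complex atoms at
1-Hz-spaced centers, unit energy, truncated at ±5σ_t; power is averaged
across centers first and the CV taken of the band-averaged time course
(one value per band per epoch), after trimming one wavelet half-length of
the lowest center frequency from each edge.

## ROI clusters

Electrode positions are projected by the azimuthal-equidistant map from
the vertex and Delaunay-triangulated; each cluster is its centroid plus
the five nearest triangulation neighbors (3D distance, id tie-break).
Centroids with fewer than five neighbors (sparse or hull cases) fall back
to overall nearest electrodes with a warning.  Metric-then-average is the
default order (each metric computed per electrode, then cluster-averaged);
the alternative mean-first order (average the cluster channels, then apply
the metric) is not the default because averaging first changes the scaling
properties the leaders measure.  A cluster missing any member is skipped
wholesale (NaN), and scalp aggregation averages the surviving clusters —
all thirteen for auditory analyses, O1/Oz/O2 for visual.  The bundled
256-channel montage is a synthetic Fibonacci-lattice stand-in (true
geodesic-net coordinates are proprietary), so cluster membership matches
the construction rule, not any specific net.

## Mixed ANOVA

Classical two-stratum split-plot decomposition.  Between stratum: subject
means regressed on effect-coded group plus optional centered covariates
(Type III sums of squares via residual-sum differences); the residual is
the subjects-within-groups error.  Within stratum: deviations from subject
means regressed on level and level×group terms; the residual, with
(N−G)(k−1) degrees of freedom, is the subject×level error.  Balanced
designs reproduce pingouin's mixed ANOVA exactly; in unbalanced designs
the within main effect uses Type III (effect-coded) estimation, which can
differ from unweighted-means implementations.  Covariates enter the
between-subjects stratum only — they are subject-level quantities, and
both with- and without-covariate tables can be produced so the report
layer can choose.  Subjects missing a within cell are dropped listwise and
counted.

Sphericity: Mauchly's W on the pooled within-group covariance with the
standard chi-square approximation (k = 2 returns p = 1);
Greenhouse–Geisser ε from the trace formula, clipped to [1/(k−1), 1].
When Mauchly rejects at α = 0.05 the within and interaction p-values use
ε-scaled degrees of freedom; the corrected p is floored at the uncorrected
p so the correction is always conservative (the raw formula can invert for
F < 1).  Post-hocs: Holm step-down on paired t-tests for within-factor
pairs; Tukey–Kramer (studentized range with unequal-n harmonic weighting,
reducing to Tukey HSD at equal n) for group comparisons.

Calibration: under a balanced Gaussian null (n = 20/group, k = 4) the
empirical size of every effect is 0.05 ± 0.01 over 2000 seeded replicates,
and a 0.8-SD within-level shift is detected with power > 0.8.

## Regime classification

The prediction table encodes: LRTCs rise only toward the critical point
(from either side); slope steepens toward synchrony and flattens toward
asynchrony; under edge-of-synchrony, low-frequency power and variability
move inversely (synchronous-ward: power up, variability down).  A metric
counts as moved only when the mixed ANOVA's within (or interaction) effect
is significant *and* the Holm-corrected post-hoc for the requested contrast
is significant — mirroring how such patterns are read in practice.  An
observed pattern whose LRTC/slope match a candidate shift but whose
power/variability contradict it (notably LRTC↑, slope steeper,
variability↑) is classified "inconsistent with edge-of-synchrony"; this
inconsistency rule is a package convention, since the boundary cells of
the prediction table are not standardized.  Patterns missing power/cv are
classified on the available metrics with a lowered confidence flag.

## Study simulator

`simulate_study` runs the production pipeline on composite surrogates with
event-type and group effects injected through the surrogate parameters:
slow/passive epochs carry a steeper aperiodic exponent (2.15–2.25 vs 1.90),
the clinical group carries extra low-frequency power (+0.10 to +0.15 log10)
and, before slow responses and at rest, deeper amplitude modulation (0.60
vs 0.30).  These effect placements emulate the qualitative pattern the
metrics target; they are not fitted to any dataset.  What passing tests
show: the estimators recover injected scaling, power and modulation
effects through ROI averaging and the ANOVA detects them at small n.  What
they do not show: performance on real EEG with artifacts, nonstationary
arousal, volume conduction, or channel dropout beyond the skip rule.

## Known limitations

* Leaders (not p-leaders) are used; signals must have positive uniform
  regularity, which holds for EEG-like 1/f^χ with χ ∈ (1, 3) but not for
  blue/white spectra — the slope estimator covers those.
* The aperiodic model has no knee; fits above ~45 Hz or at very low
  frequencies need a different fit range.
* The mixed ANOVA offers no random-slope (linear mixed-effects)
  alternative, and the Mauchly/GG machinery assumes multivariate
  normality.
* EDF I/O is not provided; continuous signals move through arrays,
  CSV/NPZ, or `mne.io.RawArray`.
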