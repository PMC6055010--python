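# Methods

## Recording model and conventions

A recording is a set of triggered sweeps sharing one time base. Sample `i`
of a sweep occurs at `t = i / fs` (0-based, first sample at the acquisition
trigger); the stimulus is delivered `artifact_onset` ms after the trigger.
Defaults reflect a typical evoked-EMG setup: `fs = 40 kHz`, 20 ms sweeps
(800 samples), artifact onset 1.0 ms, stimulus 2.0 mA, ten trials per
recording at a 5 s inter-trial interval. Voltages are millivolts from
ingestion onward (`voltage_scale` converts exports written in volts).

Evoked potentials are displayed inverted relative to the raw electrode
polarity so the main CMAP deflection points up; `polarity_inverted` records
whether stored samples already follow that convention, and
`normalize_polarity` enforces it before measurement.

## Conditioning

1. **Polarity normalization** — sign flip iff the sweep is in raw
   orientation.
2. **Baseline subtraction** — subtract the mean of `[0, artifact_onset)`,
   the only interval guaranteed free of stimulus and response energy. The
   operation is idempotent and shift-invariant.
3. **Averaging** — pointwise mean over the selected trials. Trials hit by
   pulse-like contamination (e.g. ECG pickup, with spectral content around
   300–600 Hz) are handled by exclusion from the average, not by filtering,
   matching how stable trials are selected at the bench.
4. **Mains removal (optional)** — least-squares fit and subtraction of
   `a_k sin + b_k cos` at the line frequency and its harmonics
   (`harmonics=2` covers 50/60 Hz hum and 100/120 Hz ripple). A 20 ms sweep
   spans at most one 50 Hz cycle — far shorter than the settling time of any
   usefully narrow notch filter — whereas sinusoidal regression removes a
   pure tone essentially exactly, is zero-phase (no latency bias), and
   removes only a 2·`harmonics`-dimensional projection from 800 samples, so
   broadband content loses well under 1 dB. The worst-case effect on the
   CMAP itself is the projection of a ~1 ms transient onto the fitted
   sinusoids, below 10% of the peak for physiologic amplitudes (validated in
   the tests); an `exclude` window can protect the response region entirely.

## Parameter extraction

On the conditioned trace, with artifact onset `t_a`:

- the **peak** is the maximum sample in the search window
  `[t_a + blanking, sweep end]`; the 0.3 ms blanking default keeps the
  stimulus artifact (100 µs pulse plus amplifier recovery) out of the
  search, as an operator's cursors would;
- **amplitude** is the peak value (baseline is zero after subtraction);
  positive peak only — negative lobes are used only for the falling
  crossing;
- the **rising crossing** is the last zero up-crossing before the peak from
  which the trace stays positive up to the peak (robust to small baseline
  oscillations that create spurious earlier crossings); **latency** is that
  crossing minus `t_a`;
- the **falling crossing** is the first zero down-crossing after the peak;
  **duration** is falling minus rising crossing;
- crossings are linearly interpolated between the two straddling samples —
  the reproducible analog of cursor placement by eye, exact on
  piecewise-linear traces.

**Response criterion.** A trace whose peak does not exceed the noise
threshold (default 3 × the sample SD of the pre-stimulus baseline) is
flagged `no_response` with latency/duration undefined. The threshold is
configurable so that deliberately weak responses (e.g. early reinnervation
with a small CMAP of long latency and duration) can still be measured.
Additional flags: `clipped` (response not back to zero by the window end)
and `noisy_baseline` (rising crossing could not be anchored, or threshold
exceeds 20% of the peak).

**Numerical accuracy.** Each interpolated crossing is accurate to better
than one sample period; latency therefore is too. Duration is the
*difference* of two crossings, so its worst-case error is two sample periods
(0.05 ms at 40 kHz); empirically the worst observed error on random
off-grid ground truths is ≈1.3 samples. With additive noise σ on the
averaged trace, the crossings sit where the waveform (locally quadratic
around its zeros for smooth CMAPs) emerges from the noise, giving onset/
offset localization errors of order `D·sqrt(σ/A)`; at the default noise this
biases cohort-mean latency/duration by a few percent while amplitude stays
unbiased to ≪1%.

**Artifact onset** is normally taken from configuration (the stimulator
delay is known). An automatic mode exists for unlabeled exports: the
earliest first-difference jump exceeding 8 robust SDs (1.4826 × MAD) of the
pre-window differences, sustained by two deviant samples; it raises a
detection error on flat traces so callers can fall back to the configured
value.

**Recruitment.** Given measurements at strictly increasing intensities, the
supramaximal intensity is the lowest intensity from which every subsequent
amplitude increment stays below `plateau_tol` (default 5%) of the running
maximum amplitude; a series that never settles has no plateau. Under the
default simulator recruitment model the plateau is reached at or below
1.0 mA and 2.0 mA is comfortably supramaximal.

## Simulator

Each sweep is artifact + response + noise:

- **artifact**: rectangular pulse at `t_art` (default 1.0 ms), width 100 µs,
  height 5 mV;
- **response kernel** (default `raised_cosine`): positive lobe
  `A/2·(1 − cos(2π(t − t_on)/D))` on `[t_on, t_on + D]`, followed by a
  negative lobe of the same width scaled by `undershoot` (default 0.2).
  The lobe starts at zero exactly at `t_on = t_art + L`, peaks at exactly
  `A`, and crosses zero exactly at `t_on + D`, so the cursor definitions of
  (A, L, D) hold by construction and the noise-free simulate → measure round
  trip is the identity up to discretization. A `gaussian_derivative` kernel
  is provided for morphology robustness checks (onset truncated at 1% of
  peak, so its nominal parameters are approximate);
- **trial-to-trial latency jitter**: Gaussian, default SD 0.02 ms — the
  small onset variability of supramaximal stimulation;
- **noise modes** (defaults in parentheses): white Gaussian per sample
  (0.05 mV SD, a typical clean-recording noise floor two orders below a
  mV-scale CMAP), random-phase line hum at 50/60 Hz (0.02 mV), ripple at
  twice the line frequency (off), ECG-like biphasic pulse train at ~6 Hz
  with wavelet width 0.4 ms, i.e. spectral energy near 400 Hz (off), and DC
  drift in mV/s accumulating over the 5 s trial interval (off). An injected
  hum of amplitude *a* raises expected pre-stimulus power by a²/2.

Randomness is counter-based: sweep `i` draws from
`default_rng([seed, stream, i])`, so any subset regenerates identically
regardless of order.

**Recruitment model.** Effective amplitude at intensity `I` is the
saturating amplitude times a logistic `expit((I − I₅₀)·s)` rescaled to be
exactly 0 at `I = 0`; defaults `I₅₀ = 0.3 mA`, `s = 8 /mA` put the curve at
≥99% of saturation by 1.0 mA.

**Cohorts.** Subject-level true (A, L, D) are drawn independently from
normals truncated at the physiologic floor (0). The pre-truncation (µ, σ)
are solved numerically so the *post-truncation* mean and SD equal the
requested group parameters — naive truncation of a high-CV parameter (e.g.
amplitude mean 4.12, SD 2.13) would otherwise inflate the realized mean by
~3%. Presets `RAT_COHORT` and `MOUSE_COHORT` carry typical intact-animal
values (amplitude 4.12 ± 2.13 and 5.02 ± 1.43 mV, duration 1.17 ± 0.33 and
0.97 ± 0.17 ms, latency 1.41 ± 0.37 and 1.11 ± 0.34 ms).

What the generator does **not** emulate: polyphasic/dispersed CMAPs,
electrode-interface drift and movement artifacts, amplifier saturation, or
correlated noise between trials. Passing tests therefore demonstrate
correctness of the measurement conventions and calibration of the
statistics, not robustness to every pathology of real recordings.

## Statistics

Group summaries are n / mean / sample SD (divisor n − 1); rounding (2
decimals) happens only at report rendering. Two-group comparisons are
two-tailed: pooled-variance Student t (default), Welch t, or Mann–Whitney U
(exact when combined n ≤ 20 without ties, otherwise normal approximation
with tie correction). `summary_t_test` computes the same t-tests from
(n, mean, sd) alone and agrees with the raw-data test to machine precision
on moment-matched samples, enabling verification of printed summary tables.
Multi-group comparisons are one-way ANOVA with Tukey HSD, or Kruskal–Wallis
with Holm-adjusted pairwise Mann–Whitney tests. Because published tables
rarely state whether "unpaired t-test" pooled variances, both variants are
first-class and the bundled group-table check passes under both. With both
group variances zero and equal means, p = 1 by convention (flagged);
zero variance with unequal means is a degenerate-input error. Test
selection is explicit — no automatic normality-based switching.

## Validation problem sizes

The validation suite uses: a 5 × 5 × 5 grid over A ∈ [0.5, 10] mV,
L ∈ [0.5, 3] ms, D ∈ [0.5, 2] ms for noise-free round-trip recovery
(amplitude within 2%, latency/duration within one sample period, with a
separate off-grid property test asserting the per-crossing sub-sample
bounds); 200 Monte-Carlo cohorts per species for cohort-mean amplitude
recovery within 5%; 100 repeats for the σ/√10 averaging law (±30%); 2000
null replicates for type-I error calibration of the default test
(within [0.03, 0.07] at α = 0.05); and a ten-point intensity series for
plateau detection. The acceptance script reruns the cohort computation at
the same sizes from a user-supplied seed.

## Known limitations

- Single-positive-lobe measurement: polyphasic responses report only the
  dominant lobe; no turns/phases analysis.
- No conduction-velocity or motor-unit-number estimation (single
  stimulation site).
- Duration accuracy is bounded by two sample periods even noise-free (see
  above); under noise, crossing localization adds a bias of order
  `D·sqrt(σ/A)`.
- Proprietary acquisition formats are out of scope; ingest text exports.
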