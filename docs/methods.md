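# Methods

`pulsecam` implements a camera-photoplethysmography (PPG) heart-rate
pipeline of the kind used by early smartphone HR applications — a fingertip
pressed over the LED and camera lens, raw nv21 video frames reduced to a
scalar transmitted-light signal, pulse peaks detected, and heart rate
reported as a 4-beat rolling average — together with the method-comparison
statistics used to validate such monitors against ECG and pulse-oximeter
references, and a synthetic study simulator that exercises the entire chain
without hardware or human recordings.

## Signal model and pipeline

Blood-volume change in the capillary bed modulates the opacity of the
fingertip, so the spatial mean of the luma (Y) plane of each nv21 frame
tracks the cardiac cycle. The pipeline is, in order:

1. **Extraction** (`extract`): per-frame mean of the Y plane (the V chroma
   plane is available as an option; transmitted red light puts most
   pulsatile variance in luma, which is also free of chroma subsampling).
   A per-frame finger-presence flag combines a bounded mean
   (40 ≤ mean Y ≤ 250) with a spatial-uniformity requirement
   (SD ≤ 40 on a regular 1-in-4 pixel subsample): a covered lens is
   mid-bright and smooth; an uncovered one is dark or highly structured.
2. **Conditioning** (`pulse`): a centred moving-average detrend
   (window 1.5 s) followed by a zero-phase order-3 Butterworth band-pass,
   0.67–3.0 Hz (40–180 bpm with headroom over the resting-to-mild-exertion
   range this class of device targets). Forward–backward filtering
   preserves peak timing and roughly doubles stop-band attenuation
   (~36 dB one octave outside the band).
3. **Beat detection**: local maxima whose prominence exceeds
   `prominence_frac` (default 0.3) times a rolling interquartile-range
   amplitude envelope (4 s window — robust to residual drift), separated
   by a refractory period of 0.33 s (≈180 bpm ceiling, suppressing
   dicrotic-notch double counting). Each peak time is refined by a
   parabolic fit through the peak sample and its two neighbours. At 20 fps
   the raw grid quantises beat times to ±25 ms; without sub-frame
   interpolation that quantisation alone would dominate the sub-bpm error
   budget of the validation statistics.
4. **HR reporting**: HR at beat *i* is 60·k/(t_i − t_{i−k}) with k = 4,
   matching the rolling-average displays of the reference devices; the
   beat-wise series is sampled-and-held once per second, and per-minute
   HR is the mean of quality-true seconds in each minute. Minutes with
   fewer than 30 valid seconds (half the minute) are flagged invalid
   rather than averaged, to avoid biased partial-minute means. Quality is
   false before the first 4-beat window completes — the monitor shows no
   number yet — and during signal-loss events (maximal finger-absent runs
   ≥ 2 s).

## Validation statistics (`agreement`)

Pooled per-condition subject-minutes (14 subjects × 5 minutes = 70 pairs
per condition at full scale) feed:

* **Pearson r** between the two devices' per-minute HRs.
* **SEE**, the residual SD of the OLS fit of the comparison device on the
  criterion: √(Σe²/(n−2)). The regression-based estimator was chosen over
  SD·√(1−r²); they differ only by the (n−1)/(n−2) factor. The criterion
  device is the regressor, and the conventional validity rule is
  r ≥ .90 and SEE ≤ 5 bpm.
* **Repeated-measures Bland–Altman limits.** With several minutes per
  subject the differences are not independent; the limit variance is
  σ²_between + σ²_within from a one-way ANOVA of the differences grouped
  by subject: σ²_within = MSW, σ²_between = max(0, (MSB − MSW)/m₀),
  m₀ = (N − Σm_i²/N)/(S−1). Limits are d̄ ± 1.96·√(σ²_b + σ²_w). The
  negative-component truncation at zero is standard. Containment
  (`pct_within`) uses inclusive bounds so identical devices report 100%.
  Difference sign convention: criterion minus comparison.

## The synthetic study

The simulator emulates a three-device validation session: per-subject base
HR ~ Normal(72, 12) bpm (matching the between-subject SDs such studies
report), condition offsets sitting +0 / reading +5 / video game +2 bpm,
five minutes per condition, RR jitter SD 20 ms, slow sinusoidal HR
modulation (±2 bpm, 30 s period) standing in for vasomotor/attentional
drift. Video is rendered at the acquisition settings bundle — 20 fps,
176×144 — with an asymmetric beat waveform (cosine rise over 30% of the
beat, cosine decay over 70%; a sinusoid would under-exercise the peak
interpolation), baseline luma 170, pulse amplitude 8, illumination drift
±5 over 30 s, and per-pixel Gaussian sensor noise SD 2. Dropout spans
replace frames with high-variance uncovered-lens content so the
finger-presence rule fires. The oximeter emulator delays the rolling HR by
1 s, adds Normal(0, 0.5 bpm) noise and rounds to integer bpm.

**Integer display quantisation.** In the kind of study this simulator
emulates, each device's HR is read off its display (whole bpm) and
transcribed; fractional HR never reaches the analysis. `simulate_study`
therefore rounds the camera and ECG per-second HRs to integers before
minute-averaging (`display_rounding`, default True; the oximeter emulator
already rounds). This matters for the Bland–Altman containment behaviour:
quantised, bounded differences are light-tailed, and light tails are what
make ~95% containment cells reproducible. A Monte-Carlo aside (kept in the
test suite as a property check): with *continuous* Gaussian differences,
a 70-pair cell lands at ≥95% containment only about two-thirds of the
time, so near-universal cell passage is itself evidence of quantised
difference distributions.

What the simulator does **not** model: motion artifacts beyond on/off
dropouts, exposure/focus dynamics, skin-tone and perfusion variability,
ambient-light leakage, arrhythmias, and any biophysical light transport.
Passing tests therefore show the *software chain* is correct and
self-consistent at realistic signal scales — not that the method is robust
to real-world capture conditions.

## Numerical and design choices

* Beat schedule: RR_i = 60/HR(t_i) + Normal(0, jitter), floored at 0.3 s;
  configurations whose peak HR already implies RR ≤ 0.3 s are rejected.
* Detection edge cases: streams shorter than 2 s are refused; beats inside
  finger-absent spans are suppressed; after parabolic refinement a final
  pass drops any beat that lands within the refractory gap of its
  predecessor (keeping the earlier one).
* Per-second sample-and-hold keeps the last rolling value indefinitely
  between beats; staleness is bounded in practice by the signal-loss
  quality flags, but seconds immediately after a loss event reflect the
  first window spanning the gap — a known limitation shared with real
  rolling-average displays.
* The one-way ANOVA components are computed from sums of squares directly
  (grouped means), with the m₀ weighting handling unbalanced replicate
  counts; a single subject, or no subject with ≥2 replicates, is a
  degenerate design and raises.
* Determinism: every stochastic component draws from a
  `numpy.random.SeedSequence` tree spawned from the study seed, so study
  outputs are bit-identical across runs and chunked rendering is
  independent of how the chunks are consumed (fixed 200-frame chunks).
* Problem sizes: the bundled study fixture in the test suite runs 4
  subjects × 3 conditions × 5 minutes at full video rate, a size at which
  the agreement statistics are already stable; `scripts/acceptance.py`
  runs the full 14-subject study.

## Known limitations

* The finger-presence rule is threshold-based on two summary statistics;
  structured occlusions that happen to be smooth and mid-bright would
  evade it.
* v-chroma extraction is implemented but the detection defaults are tuned
  for luma amplitudes.
* No confidence intervals on the limits of agreement, and no
  proportional-bias (regression-based) Bland–Altman variant; both are
  deliberate non-goals.
* HR variability metrics and arrhythmia handling are out of scope; the
  beat detector assumes a quasi-periodic pulse.
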