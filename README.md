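# pulsecam

Camera photoplethysmography (PPG) turns an ordinary smartphone camera into
a heart-rate monitor: a fingertip pressed over the lens and LED transmits
light whose intensity pulses with capillary blood volume. `pulsecam`
implements the complete acquisition-and-validation toolchain for this kind
of monitor, for researchers who want to study or regression-test the
method without phone hardware or human recordings:

* **I/O** for raw Android-style nv21 (YUV420 semi-planar) frame streams
  with a JSON sidecar (`videoio`);
* **extraction** of a scalar PPG intensity series (per-frame luma mean)
  and per-frame finger-presence quality flags (`extract`);
* **pulse detection** — moving-average detrend, 0.67–3.0 Hz zero-phase
  band-pass, prominence-gated peak picking with a 0.33 s refractory
  period and parabolic sub-frame peak timing — and HR reporting as a
  4-beat rolling average (HR_i = 60·4/(t_i − t_{i−4})), sampled per
  second and averaged per minute (`pulse`);
* **method-comparison statistics**: pooled Pearson *r*, standard error of
  estimate SEE = √(Σe²/(n−2)) from the OLS fit of comparison on criterion
  device, the conventional validity rule (*r* ≥ .90, SEE ≤ 5 bpm), and
  repeated-measures Bland–Altman 95% limits of agreement
  d̄ ± 1.96·√(σ²_between + σ²_within) with the variance components from a
  one-way ANOVA of differences by subject (`agreement`);
* a **synthetic study simulator** that renders pulsatile fingertip video
  (20 fps, 176×144) from ground-truth beat schedules and emulates the two
  reference devices — a 4-beat rolling-average ECG monitor and a
  per-second integer-display pulse oximeter — for a full
  subjects × conditions × minutes validation study (`synth`).

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Generate a 125 s synthetic recording at 72 bpm, then estimate HR from the
video alone:

```sh
$ pulsecam synth --out-dir demo --hr 72 --duration 125 --seed 3
... INFO wrote 2500 frames to demo/video.nv21
$ pulsecam hr demo/video.nv21 --out-dir demo
... INFO mean HR 72.0 bpm over 121 valid seconds
$ cat demo/hr_per_minute.csv
t_s,hr_bpm,quality
60.0,72.14558897652795,True
120.0,71.8353027657898,True
```

The per-minute estimates (72.15 and 71.84 bpm) recover the configured
72 bpm to within the beat-to-beat jitter the generator adds (RR jitter SD
20 ms); `quality=True` marks minutes with at least 30 valid seconds.
`demo/hr_per_second.csv` holds the sample-and-held rolling HR,
`demo/beats.csv` the detected beat times, and `demo/events.csv` any
signal-loss events (try `--dropout 20 24` to see one).

A whole simulated validation study — per-minute HR tables for the camera
pipeline, ECG emulator and oximeter emulator, per-condition HR summaries
and per-device-pair agreement reports (r, SEE, Bland–Altman limits,
containment) — runs with:

```sh
pulsecam study --n-subjects 4 --seed 1 --out-dir study_out
```

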