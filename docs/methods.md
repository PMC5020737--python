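# Methods

## Trial engine

A trial is a discrete-event simulation on a virtual clock. Event order:
warning tone → initial random delay (uniform on
`[randomDelayMin, randomDelayMax]`; a degenerate interval gives a constant
delay) → rotation start → two full rotations of `cycle_ms` each → optional
feedback tone `tone_delay_ms` after the accepted key press → trial end. All
trial-relative times are real-valued milliseconds, 0-based at rotation
start, with half-open intervals; per-trial records keep the original mixed
units (the audio-clock trial start is in seconds, everything else in ms).

The **accepted press** (*T*<sub>key</sub>) is the *first* press whose
relative time lies in `[cycle, 2·cycle)` — i.e. during the second rotation.
Presses during the first rotation, or after the second, are logged in the
key-press list but never accepted and never trigger feedback; a trial with
no press in the second rotation is a non-response, and its judgment probe is
skipped. These choices pin down behaviour the paradigm leaves open
(multi-press handling, the meaning of "not answering") with the simplest
rule consistent with the procedure.

The virtual clock maps scheduled to executed event times. With jitter
disabled they are identical, so configured and measured quantities agree
exactly (measured rotation-pair duration = `2·cycle`, measured tone delay =
configured delay). An optional Gaussian per-event latency (mean, SD) stands
in for browser/OS scheduling noise; event streams are concurrent — a
feedback tone may sound while the dot still rotates — so execution never
reorders or clamps events, only the clock's high-water mark is monotonic.
Under a (μ, σ) latency law the measured-minus-configured tone delay has mean
≈ μ and SD ≈ σ, which is the in-silico analogue of measuring audio latency
with an external recorder.

Trial randomization is an explicit seeded Fisher–Yates shuffle (backward
swaps with uniform integer draws), giving every permutation equal
probability; uniformity is verified exhaustively at n = 4 against a
chi-square test.

## Clock geometry and circular judgments

The dot sweeps linearly: `time = angle/360 · cycle`. Judgments are collected
as dial angles and converted with this map; the dial is continuous (no tick
quantization) since entry granularity is unspecified in the paradigm.
Judgment errors use the signed circular difference
`wrapped_diff(judged, actual, cycle) ∈ (−cycle/2, +cycle/2]`, choosing the
integer number of whole cycles that minimizes the magnitude; an exact
half-cycle tie resolves to `+cycle/2`. This single convention is applied
everywhere (generation and analysis), so a judgment just across the
12-o'clock origin from the press differs by milliseconds, never by almost a
full rotation.

## Configuration format

Files are JSON, top-level object of group id → group configuration, with the
original camelCase key names (`randomDelayMin`, `postResultsURL`,
`preScreens`, …) for compatibility; internal names are normalized snake_case
with units. Only `progress`, `scramble` and `cycle` (default 2560 ms) are
optional; a `tone` property absent from a trial means *no feedback on that
trial* and is represented as an absent value, never 0 — a zero delay is a
legal, different configuration. Unknown fields are preserved on round-trip
and flagged as warnings. Validation is total: any malformed document yields
an error naming the JSON path, never a partially built configuration.
Screens, passwords and messages are carried as data and never rendered.
Pseudo-random group assignment is independent and uniform per participant
(not counterbalanced; balancing would be an extension).

The built-in two-condition design builder produces a training phase of 80
trials — 40 immediate (1 ms) and 40 delayed (500 ms) feedback, shuffled once
at build time so the sequence is *predefined* per seed — followed by 20
baseline trials without feedback, all at 2560 ms per rotation.

## Participant model

Per trial, a participant presses at a uniform random time within
`[200, cycle − 200]` ms of the second rotation (the window keeps judgments
plus realistic shifts away from needing more than a half-cycle wrap; no
press-time distribution is prescribed by the paradigm). The judged time is

```
judged = actual + offset_i + bias[condition] + N(0, judgment_sd)
```

wrapped onto the dial: `offset_i` is a per-participant constant (Gaussian
across the population), `bias[condition]` the mean judgment shift for the
trial's feedback condition (including a baseline entry), and the noise is
i.i.d. per trial. Misses occur with a fixed probability per trial. This
additive-Gaussian structure, without trial-order or learning effects, is the
simplest model whose condition means the analysis pipeline estimates; it is
*not* a cognitive model of binding.

Presets calibrate the population to the published cohort-level raw
statistics: condition-bias means equal the printed raw condition means
(lab: 3.806 / 41.152 ms at n = 57; online: −32.967 / 0.041 ms at n = 52),
and each condition's between-participant bias SD is `SEM·√n` so the cohort
SEM at the printed n reproduces the printed SEM. Values not printed anywhere
were fixed once at plausible levels: baseline bias mean 0 (no feedback — no
binding shift) with the smaller condition's between-participant SD,
per-participant offset 0 (between-participant variance is carried by the
per-condition bias draws), within-trial judgment SD 20 ms (trial-level
variability is unreported, so this is a free parameter), miss probability
0.02. What passing parameter-recovery tests show is that the *pipeline*
recovers whatever means the generator encodes at the configured n — not that
human judgments follow an additive-Gaussian law, and not a reproduction of
the original human-subject statistics, whose raw data are unpublished.

## Analysis pipeline

Per participant: mean judgment error per condition (responded trials only),
baseline mean from no-feedback trials (its absence is an error — correction
would be impossible), corrected mean = raw − baseline (exact identity,
asserted in tests). Exclusion is *strictly* more than 25 % non-response in
at least one feedback condition — 10/40 missed is retained, 11/40 excluded;
baseline misses never exclude. The paired comparison is a standard
related-samples *t* on per-participant means (corrected by default, raw as a
robustness path; the *t* statistic is identical because each participant's
own baseline cancels in the pairwise difference), two-sided *p* from the
*t* distribution with df = n − 1, zero variance of differences raised as a
degenerate case rather than reported as t = ∞. Both *d*<sub>z</sub> =
mean diff / SD of diffs and *d*<sub>av</sub> = mean diff / average condition
SD are reported, because published effect sizes in this literature are not
derivable from a single convention (the printed values are inconsistent with
d = t/√n); no attempt is made to match any particular printed *d*.

The null calibration of the pipeline (type-I error at α = 0.05 within 99 %
binomial bounds over 2,000 cohorts of n = 20 with 10 trials/condition) runs
on a vectorised generator of per-participant condition means that applies
the same bias/offset/noise/wrap model and the same baseline-correction and
paired-test code; the discrete-event engine path is validated separately by
end-to-end parameter recovery at 57 participants × 100 trials. These sizes
keep the whole suite fast while leaving Monte-Carlo tolerances (3·SE
throughout) meaningful.

## Timing validation

**Audio.** The validation sequence is a unit-amplitude 1 kHz sine burst of
200 ms followed by 800 ms of silence, repeated; a per-onset injected latency
(constant or Gaussian, seeded) shifts each burst. The onset detector
thresholds the rectified waveform at a fraction of its peak (default 10 %),
groups supra-threshold samples into bursts by closing gaps shorter than
10 ms, locates threshold crossings by linear interpolation, and corrects
each edge by the carrier phase lag `asin(threshold/amplitude)/(2πf)`, with
the carrier frequency estimated from zero crossings within the burst. The
correction assumes each burst begins and ends at a carrier zero crossing —
exact for procedurally generated tones (an oscillator starts at zero phase,
and 200 ms of 1 kHz is an integer number of cycles) — and makes onset and
duration estimates accurate to a small fraction of a sample period
(~2·10⁻⁵ ms on the clean 44.1 kHz sequence), rather than the ~0.5 ms edge
bias a smoothed-RMS envelope would introduce at these thresholds. Detected
onsets are compared in order against the nominal schedule; the mean and SD
of those errors summarize the injected latency law (recovered within 3·SE at
500 onsets). Pure silence yields an empty report, not an error. Real
recordings with background noise or reverberation would need an
energy-envelope detector with hysteresis; this detector is specified for
clean synthetic fixtures.

**Rotation period.** A frame series emulates a 1000 FPS capture: one
(timestamp, angle) sample per millisecond. The angle is unwrapped across
360° boundaries — assuming < 180° of motion between consecutive frames,
guaranteed at millisecond sampling of a multi-second rotation — and fitted
by least squares; the period is `360/slope`. A non-positive slope (dot not
rotating forward) and series spanning ≤ half a rotation are errors. The
estimate is invariant to angle-origin shifts and uniform subsampling, and is
within 1 ms of truth under ±0.5° uniform frame-labelling noise at 5,120
samples.

## Records and I/O

The per-trial record keeps the original variable names and units
(`InitialRandomTime`, `Cycle`, `CycleTime`, `Tone`, `ToneTime`,
`KeyPressTrialTimes`, `StartTrialTime`, `EndTrialTime`,
`StartTrialAudioTime` in seconds), extended with judgment columns. CSV is
UTF-8, RFC-4180 with every field quoted (the key-press list is itself
comma-separated and must be quoted; quoting everything keeps the dialect
uniform); absent values are empty fields in CSV and nulls in JSON-lines.
Floats are serialized with shortest round-trip repr, so a seeded run is
byte-identical across re-runs. Reading is a full inverse with invariant
checks (end ≥ start, presses within the trial, measured tone delay only with
a configured tone and a press) reported as located errors. The local-backup
document is constructed strictly before the post payload — the crash-safety
contract of a browser-local copy — and the payload, a single JSON object
keyed by participant id, parses back to the complete result set; no network
code exists. The payload schema is self-defined and versioned
(`schema_version`), as no wire format is published.

## Known limitations

- No real-time execution, rendering, audio playback or keyboard handling;
  the engine is a simulation of the procedure's timing logic.
- The participant model has no trial-order, learning, or attention dynamics,
  and `judgment_sd_ms` is uncalibrated by construction.
- `T_will` is probed but shares the press-time generative law; no separate
  model of the decision moment is attempted.
- The onset detector targets clean synthetic waveforms, not noisy hardware
  recordings.
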