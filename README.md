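# spanlsci

Speckle-analysis toolkit for laser speckle contrast imaging (LSCI) of the
beating heart.

LSCI images microvascular perfusion by the blurring that moving red blood
cells impose on a coherent-light interference (speckle) pattern. Applied to
the exposed left ventricle, the per-frame ROI flux signal is biphasic —
peaks during diastole, when myocardial flow is maximal, and troughs during
systole, when the contracting muscle compresses its own microvessels — and
is contaminated by bulk motion of the beating wall. `spanlsci` implements
the full analysis chain for such recordings:

- **Speckle contrast engine** — spatial contrast `K = σ/⟨I⟩` over a sliding
  window, the inverse-square flux mapping `F = 1/max(K, K₀)²`, and ROI
  reduction of a raw frame stack to a flux time series.
- **Inflection detection** — a sample is accepted as a diastolic high only
  if it is reached by `m` strictly increasing steps and followed by `m`
  strictly decreasing steps (default `m = 2`); systolic lows are the mirror
  image. Local extrema failing the full trajectory rule are recorded as
  rejected, not silently dropped.
- **Cardiac metrics** — mean diastolic/systolic flux, heart rate
  (diastolic events normalised to a minute), inter-beat intervals between
  systolic points, their sample SD (rhythm irregularity), and mean
  peak-to-peak amplitude.
- **Motion subtraction** — point-by-point removal of a motion-only
  reference trace recorded from a covered (opaque-card) region of the same
  ventricle.
- **Ischaemia–reperfusion time courses** — per-timepoint mean diastolic
  flux, percent-of-baseline normalisation, and trapezoid AUC restricted to
  the reperfusion phase.
- **Synthetic generators** — cardiac flux traces (biphasic pulse train with
  beat jitter, amplitude dispersion, motion floor and noise), IR cohort
  profiles (sham, adult/aged, untreated/treated), and raw speckle stacks
  with controlled decorrelation time — every stage is verifiable against
  known ground truth without animal data.

## Worked example

```python
from spanlsci import beat_metrics, detect_inflections, enforce_alternation
from spanlsci.synth import CardiacSimParams, generate_trace

# a standard recording: 1,400 frames at 25 Hz (56 s), 150 bpm rhythm
trace, truth = generate_trace(CardiacSimParams(seed=42))
labels = enforce_alternation(detect_inflections(trace, margin=2), trace)
m = beat_metrics(trace, labels, alternation_enforced=True)
print(m.n_beats, round(m.heart_rate_bpm, 1))
print(round(m.mean_diastolic_flux, 1), round(m.mean_systolic_flux, 1))
print(round(m.ibi_sd_s, 4), round(m.peak_to_peak_amplitude, 1))
```

prints

```
140 150.0
899.8 348.7
0.016 551.5
```

i.e. all 140 simulated beats are recovered (truth: 140 beats, 150.0 bpm);
mean diastolic flux ≈ 900 arbitrary units (the simulated 800-unit diastolic
perfusion level plus the 100-unit motion-artifact ceiling) versus ≈ 349 in
systole; the inter-beat SD of 16 ms reflects the injected 10 ms beat-period
jitter plus 25 Hz interval quantisation; and the mean diastolic-to-systolic
swing is ≈ 551 units.

The same pipeline runs from the shell:

```sh
span simulate --profile aged_untreated --n 6 --seed 42 --out cohort/
span metrics cohort/aged_untreated_s0_baseline.csv --column 2 --skip-rows 1 --out metrics.json
span run --config run.yaml --out report/     # labels + metrics + timecourse + AUC
```

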