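# Methods

## Signal model

A flux recording is a uniformly sampled, non-negative time series in
arbitrary perfusion units (absolute calibration of LSCI flux is not
possible; all comparisons are within-subject or percent-of-baseline). In
the beating heart the series is biphasic: coronary perfusion peaks in
diastole and collapses in systole as the contracting myocardium compresses
its own microvasculature. Bulk wall motion adds a second flux component
that is present even when perfusion is absent, so an ischaemic ventricle
never reads zero.

## Speckle contrast engine

Spatial contrast is the per-pixel ratio `K = σ/⟨I⟩` computed over a centred
odd-sized sliding window (default 5×5, common practice for spatial LSCI
processing), with the **population** (divide-by-n) standard deviation — the
standard definition of speckle contrast; a sample SD would bias small
windows. Implementation uses two uniform filters (mean and mean of
squares); a per-pixel brute-force loop serves as an independent oracle in
the tests. Numerical choices:

- Pixels whose window exits the frame are marked invalid rather than
  padded: padding fabricates intensities.
- A window with zero mean leaves `K` undefined (0/0); the pixel is invalid,
  not zero.
- Round-off can make the filtered variance slightly negative for constant
  patches; it is clipped at zero before the square root.

Flux uses the simplest standard inverse-square model `F = 1/max(K, K₀)²`
with a configurable contrast floor `K₀` (default 10⁻³) keeping `F` finite
at degenerate pixels. Commercial devices apply a proprietary scaling;
since downstream metrics are in arbitrary units and are ratio- or
rank-based, any monotone decreasing map would serve — the inverse square is
the conventional choice. ROI reduction is a plain average of valid ROI
pixels, one value per frame. An acquisition-style temporal moving average
(window in seconds) is provided but **off by default**: detection operates
on raw exported flux.

## Inflection detection

Index `i` is an accepted diastolic high iff

```
v[i−m] < … < v[i−1] < v[i] > v[i+1] > … > v[i+m]
```

with every inequality strict; a systolic low is the mirror image. The
trajectory margin `m` defaults to 2 (two concurrent movements on each
side). Design decisions:

- **Strictness.** Plateaus (equal neighbours) carry no directional
  evidence; they break a trajectory and the candidate is rejected. This
  also makes the brute-force oracle unambiguous.
- **Rejected set.** One-step local extrema inside the candidate range that
  fail the full rule are reported, making acceptance auditable.
- **Boundaries.** Indices within `m` of either end cannot be verified and
  are never candidates. An optional `skip_initial` discards leading samples
  (acquisition settling); default 0.
- **Alternation** is a separate optional pass, not part of the detector:
  between consecutive same-type accepts the more extreme one is kept (ties
  keep the earlier index). Pruned extrema are *not* added to `rejected` —
  they passed the trajectory rule.

## Cardiac metrics

- Mean diastolic flux (the perfusion summary used for group comparisons)
  averages the trace at accepted highs; systolic troughs are dominated by
  vessel compression and are not used for perfusion.
- Heart rate = accepted diastolic events ÷ recording duration × 60. A
  standard 1,400-frame, 25 Hz recording lasts 56 s, so "per minute" must be
  rate-scaled, not assumed.
- Inter-beat intervals are successive differences of systolic lows (a flag
  switches to diastolic anchors for sensitivity analysis); their **sample**
  (n−1) SD is the rhythm-irregularity metric. The denominator convention is
  a documented choice.
- Peak-to-peak amplitude averages (high − next low) over alternation-
  enforced pairs; unpaired trailing extrema are dropped.

## Motion subtraction

An opaque card over part of the ventricle blocks the perfusion signal but
not the mechanical beating, giving a simultaneous motion-only reference.
Subtraction is point-by-point; negative differences are clipped to zero
(perfusion is non-negative) and **counted**, because a large clip count is
the signature of a misaligned or mismatched pair and must not be hidden.

## Time courses and AUC

A time course holds one summary flux per timepoint (exactly one baseline,
strictly increasing minutes). The default experiment schedule is baseline
at 0 min, ischaemia at 45 min (the occlusion period), and reperfusion
sampled every 15 min from 60 to 195 min (10 points). Percent-of-baseline
maps the baseline to exactly 100 by definition (not by division, avoiding
a 100±ε artefact). AUC is the trapezoid rule over minutes, restricted by
default to the reperfusion phase only, so it summarises perfusion
recovery; ordinates default to raw summary flux with normalised ordinates
available via the same API (percent-baseline first, then AUC).

## Synthetic cardiac traces

The generator emulates the features the analysis must survive, with full
ground truth (true peak/trough samples, per-beat periods and amplitudes,
separate noiseless perfusion and motion components):

- **Waveform.** Asymmetric triangular pulse, fast upstroke peaking at 30%
  of the beat, slower linear decay. Linear flanks keep a constant
  directional step right up to the extremum, so peaks/troughs are
  unambiguous single samples that remain detectable under additive noise
  (a sine or raised cosine flattens quadratically at its extrema, making
  near-extremum steps vanish at fine sampling).
- **Timing.** Beat onsets advance in continuous time (period + Gaussian
  jitter, default SD 10 ms) and are rounded to the sample grid
  cumulatively, so quantisation never drifts.
- **Levels.** Defaults: diastolic 800, systolic 300 arbitrary units, motion
  ceiling 100 units riding the same beat (floor 50 — flux never reaches
  zero), amplitude dispersion 5%, additive Gaussian noise SD 8. These are
  testability choices in arbitrary units, not measured values.
- **Geometry.** Default 25 Hz × 56 s (1,400 frames) with a 0.4 s beat
  period: 10 samples/beat, comfortably above the ~6 samples/beat limit at
  which a margin-2 rule can certify a beat. A murine 500 bpm rhythm at
  25 Hz (~3 samples/beat) is deliberately kept as a flagged, undersampled
  stress case (`undersampled=True` in the ground truth), not an accuracy
  regime. Rhythm-recovery studies that need fine interval resolution use
  100 Hz × 0.12 s beats (12 samples/beat), where interval quantisation
  (~4 ms SD) is well below the injected jitter.
- **Exactness.** The noiseless perfusion and motion components are snapped
  to a dyadic grid (multiples of 2⁻¹² flux units) so sums and differences
  are exact in float64: subtracting the covered-region trace from the
  noiseless total recovers the perfusion component bit-for-bit.

### IR cohort profiles

Per-phase multipliers scale the perfusion component only (motion is
untouched). Baseline is always exactly 1; injured profiles drop to 0.1 in
ischaemia. Adult-untreated reperfusion returns to 1.0; aged-untreated
declines linearly 0.80 → 0.35 across the ten reperfusion points (progressive
failure); treated profiles overshoot (transient hyperaemia, +60% adult /
+50% aged decaying exponentially to baseline). Aged arms additionally carry
the "erratic" phenotype: amplitude dispersion 0.25, jitter SD 20 ms, and a
1.4× wider diastolic–systolic swing grown downward into systole so the
diastolic summary level is unchanged. Per-subject seeds spawn from the
cohort seed (`SeedSequence`); per-timepoint multipliers get small Gaussian
perturbations (SD 0.01) as biological variability.

## Synthetic speckle

Static fully developed speckle is the squared modulus of a unit-variance
circular complex Gaussian field, pixel-independent (fine-grain limit):
intensity ~ Exp(1), theoretical contrast exactly 1. Dynamic stacks
integrate the exposure by averaging `n` substeps of an AR(1)-evolving field
with per-substep correlation `exp(−Δt/τc)` (per-pixel `τc` maps supported;
the field also evolves through inter-frame dead time). This is simple,
seedable, and has the correct limits — `τc → ∞` gives identical frames and
unit contrast, `τc ≪ T` drives `K → 0` — and a monotone contrast response
to `1/τc`; no claim is made of matching the exact closed-form `K(T/τc)`
curve. A warning is raised when the substep interval exceeds `τc/2`
(integration too coarse). Diffraction-accurate speckle-size modelling and
camera noise are out of scope.

## What the synthetic tests do and do not show

Passing tests demonstrate that the detector implements its rule exactly,
that metrics recover known physiology at realistic noise, and that the
time-course machinery reproduces the qualitative IR phenomenology its
profiles encode *by construction*. They do not validate against real
animal recordings: real flux waveforms are not triangular, real motion is
not perfectly additive or shared between covered and uncovered regions,
respiration adds a second oscillation, and vendor devices apply unknown
K→flux scaling and temporal smoothing (the acquisition "time constant" is
treated as display smoothing and not applied). Problem sizes in the test
suite (trace lengths ≤ 2,000 for oracle comparisons, 96×96–256×256 speckle
fields, 6 subjects per simulated arm) are chosen to make every property
checkable in seconds while keeping estimator standard errors well inside
the asserted bands.

## Known limitations

- Interval estimates are quantised to the sampling grid; at 25 Hz the
  ±0.5-sample rounding contributes ≈ 16 ms SD to inter-beat intervals,
  which can dominate small true jitter. Use finer sampling when rhythm
  variability is the target.
- Heart rate counts accepted highs, so a single boundary beat (first or
  last) can shift the estimate by one beat per recording (≤ 0.7% at
  150 bpm × 60 s).
- The CSV reader handles decimal-point dialects only, by design; locale
  commas are rejected with an explicit message rather than guessed.
- No frequency-domain HRV, arrhythmia classification, absolute perfusion
  units, or inferential group statistics — per-subject tidy summaries are
  the intended hand-off to external statistics tools.
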