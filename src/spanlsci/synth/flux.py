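"""Synthetic cardiac flux traces and ischaemia-reperfusion cohorts.

The generator emulates what an LSCI flux recording of the beating left
ventricle looks like: a biphasic oscillation with a single-sample diastolic
peak and systolic trough per beat, an additive motion-artifact component
that never reaches zero (bulk wall movement registers as flux even with no
perfusion), Gaussian beat-period jitter, per-beat amplitude dispersion (the
"erratic" knob), and additive sensor noise.  Every emitted trace carries a
full ground-truth record — true peak/trough samples, per-beat periods and
amplitudes, and the separate noiseless perfusion and motion components — so
any downstream metric can be scored without re-simulation.

Beat waveform: an asymmetric triangular pulse with a fast upstroke (peak at
30% of the beat) and a slower linear decay.  Unlike a sine or raised cosine,
whose flanks flatten quadratically at the extrema, linear flanks keep a
constant directional step size right up to the peak/trough, so the extrema
are unambiguous single samples and remain detectable under additive noise;
detector ground truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ..flux_io import FluxTrace

__all__ = [
    "CardiacSimParams",
    "TraceGroundTruth",
    "CohortProfile",
    "COHORT_PROFILES",
    "generate_trace",
    "generate_paired_covered_uncovered",
    "generate_cohort",
]

#: Fraction of the beat period at which the diastolic peak sits.
PEAK_FRACTION = 0.3


@dataclass(frozen=True)
class CardiacSimParams:
    """Parameters of one simulated flux recording.

    Defaults mirror a standard acquisition: 25 Hz for 56 s (1,400 frames)
    with a 0.4 s beat period (150 bpm, 10 samples/beat — comfortably above
    the ~6 samples/beat resolvability limit of margin-2 detection). Flux
    levels are arbitrary perfusion units.
    """

    sampling_rate: float = 25.0
    duration_s: float = 56.0
    beat_period_s: float = 0.4
    jitter_sd_s: float = 0.01
    diastolic_level: float = 800.0
    systolic_level: float = 300.0
    motion_level: float = 100.0
    amplitude_dispersion: float = 0.05
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.diastolic_level > self.systolic_level >= 0:
            raise ValueError(
                "require diastolic_level > systolic_level >= 0, got "
                f"{self.diastolic_level} / {self.systolic_level}"
            )
        if not self.beat_period_s > 2.0 / self.sampling_rate:
            raise ValueError(
                f"beat_period_s {self.beat_period_s} not resolvable at "
                f"{self.sampling_rate} Hz (need > {2.0 / self.sampling_rate:.4f} s)"
            )
        for name in ("jitter_sd_s", "amplitude_dispersion", "noise_sd", "motion_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    @property
    def samples_per_beat(self) -> float:
        return self.beat_period_s * self.sampling_rate


@dataclass(frozen=True)
class TraceGroundTruth:
    """Everything needed to score downstream analyses of one synthetic trace."""

    peak_indices: np.ndarray          # one diastolic peak sample per complete beat
    trough_indices: np.ndarray        # systolic trough samples (beat boundaries)
    beat_periods_s: np.ndarray        # continuous-time per-beat periods
    beat_amplitudes: np.ndarray       # per-beat perfusion amplitude (peak - trough)
    perfusion_component: np.ndarray   # noiseless perfusion signal
    motion_component: np.ndarray      # noiseless motion-artifact signal
    params: CardiacSimParams
    undersampled: bool                # True if beats are too short for margin-2 detection

    @property
    def n_beats(self) -> int:
        return self.peak_indices.size

    @property
    def true_heart_rate_bpm(self) -> float:
        duration = self.perfusion_component.size / self.params.sampling_rate
        return 60.0 * self.n_beats / duration


def _beat_waveform(length: int, peak_offset: int) -> np.ndarray:
    """Asymmetric triangular pulse over ``length`` samples: 0 at both beat
    boundaries, 1 at ``peak_offset``; strictly monotone linear flanks."""
    j = np.arange(length, dtype=float)
    w = np.empty(length)
    rise = j <= peak_offset
    w[rise] = j[rise] / peak_offset
    w[~rise] = (length - j[~rise]) / (length - peak_offset)
    return w


def generate_trace(params: CardiacSimParams) -> tuple[FluxTrace, TraceGroundTruth]:
    """Simulate one flux recording. Deterministic for a fixed seed.

    Beat onsets advance in continuous time (period + Gaussian jitter) and are
    rounded to the sample grid cumulatively, so rounding never drifts.  The
    recorded ground truth lists complete beats only; a trailing partial beat
    is rendered but not counted.
    """
    fs = params.sampling_rate
    n = params.n_samples
    rng = np.random.default_rng(params.seed)

    min_period = 3.0 / fs  # need at least 3 samples to render a beat at all
    onsets_t = [0.0]
    periods: list[float] = []
    while onsets_t[-1] < params.duration_s + params.beat_period_s:
        p = params.beat_period_s
        if params.jitter_sd_s > 0:
            p += rng.normal(0.0, params.jitter_sd_s)
        p = max(p, min_period)
        periods.append(p)
        onsets_t.append(onsets_t[-1] + p)

    boundaries = np.round(np.asarray(onsets_t) * fs).astype(int)
    base_amp = params.diastolic_level - params.systolic_level

    perfusion = np.full(n, params.systolic_level, dtype=float)
    motion = np.full(n, 0.5 * params.motion_level, dtype=float)
    peak_idx: list[int] = []
    trough_idx: list[int] = []
    amplitudes: list[float] = []
    kept_periods: list[float] = []

    for k in range(len(boundaries) - 1):
        b0, b1 = boundaries[k], boundaries[k + 1]
        if b0 >= n:
            break
        length = b1 - b0
        if length < 3:
            continue
        p_off = int(np.clip(round(PEAK_FRACTION * length), 1, length - 2))
        amp = base_amp
        if params.amplitude_dispersion > 0:
            amp *= max(0.0, 1.0 + rng.normal(0.0, params.amplitude_dispersion))
        w = _beat_waveform(length, p_off)
        end = min(b1, n)
        seg = slice(b0, end)
        perfusion[seg] = params.systolic_level + amp * w[: end - b0]
        motion[seg] = params.motion_level * (0.5 + 0.5 * w[: end - b0])
        if b1 <= n:  # complete beat
            peak_idx.append(b0 + p_off)
            trough_idx.append(b0)
            amplitudes.append(amp)
            kept_periods.append(periods[k])

    # snap components to a dyadic grid (1/4096 flux unit): sums and
    # differences of grid values are exact in float64, so subtracting the
    # motion component from the noiseless total recovers perfusion bit-exactly
    np.round(perfusion * 4096.0, out=perfusion)
    perfusion /= 4096.0
    np.round(motion * 4096.0, out=motion)
    motion /= 4096.0

    noiseless = perfusion + motion
    values = noiseless.copy()
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n)
    np.clip(values, 0.0, None, out=values)

    truth = TraceGroundTruth(
        peak_indices=np.asarray(peak_idx, dtype=np.int64),
        trough_indices=np.asarray(trough_idx, dtype=np.int64),
        beat_periods_s=np.asarray(kept_periods),
        beat_amplitudes=np.asarray(amplitudes),
        perfusion_component=perfusion,
        motion_component=motion,
        params=params,
        undersampled=params.samples_per_beat < 6.0,
    )
    trace = FluxTrace(values, sampling_rate=fs, label="synthetic")
    return trace, truth


def generate_paired_covered_uncovered(
    params: CardiacSimParams,
) -> tuple[FluxTrace, FluxTrace, TraceGroundTruth]:
    """Simulate the covered/uncovered left-ventricle pair.

    The uncovered ("total") trace carries perfusion + motion + noise; the
    covered ("motion only") trace carries the identical motion component
    plus an independent noise draw — an opaque card blocks the perfusion
    signal but not the mechanical beating.  With ``noise_sd = 0`` subtracting
    the motion trace from the total recovers the perfusion component exactly.
    """
    trace, truth = generate_trace(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EC0]))
    motion_values = truth.motion_component.copy()
    if params.noise_sd > 0:
        motion_values = motion_values + rng.normal(0.0, params.noise_sd, size=motion_values.size)
    np.clip(motion_values, 0.0, None, out=motion_values)
    motion_trace = FluxTrace(motion_values, sampling_rate=params.sampling_rate,
                             label="motion-only (covered)")
    return trace, motion_trace, truth


# ---------------------------------------------------------------------------
# IR cohorts

@dataclass(frozen=True)
class CohortProfile:
    """Per-phase perfusion multipliers over an IR time course.

    The multiplier scales the perfusion component (diastolic and systolic
    levels alike); the motion component is untouched, so ischaemic flux never
    approaches zero.  ``reperfusion_multipliers`` covers 10 timepoints at
    15-min spacing.
    """

    name: str
    ischaemia_multiplier: float
    reperfusion_multipliers: tuple[float, ...]
    amplitude_dispersion: float = 0.05
    jitter_sd_s: float = 0.01
    amplitude_scale: float = 1.0
    hyperaemia: bool = False

    def __post_init__(self) -> None:
        if self.name != "sham" and not self.ischaemia_multiplier < 0.3:
            raise ValueError("injured profiles require a near-zero ischaemia multiplier")


def _hyperaemic(overshoot: float, n: int = 10, tau: float = 2.5) -> tuple[float, ...]:
    k = np.arange(n)
    return tuple(1.0 + overshoot * np.exp(-k / tau))


COHORT_PROFILES: dict[str, CohortProfile] = {
    "sham": CohortProfile("sham", 1.0, (1.0,) * 10),
    "adult_untreated": CohortProfile("adult_untreated", 0.1, (1.0,) * 10),
    "aged_untreated": CohortProfile(
        "aged_untreated", 0.1, tuple(np.linspace(0.80, 0.35, 10)),
        amplitude_dispersion=0.25, jitter_sd_s=0.02, amplitude_scale=1.4,
    ),
    "adult_treated": CohortProfile(
        "adult_treated", 0.1, _hyperaemic(0.6), hyperaemia=True,
    ),
    "aged_treated": CohortProfile(
        "aged_treated", 0.1, _hyperaemic(0.5),
        amplitude_dispersion=0.25, jitter_sd_s=0.02, amplitude_scale=1.4,
        hyperaemia=True,
    ),
}

#: Experiment schedule in minutes: baseline before occlusion, ischaemia during
#: the 45-min occlusion, then reperfusion sampled every 15 min for 2.5 h.
SCHEDULE: tuple[tuple[str, float, str], ...] = (
    ("baseline", 0.0, "baseline"),
    ("ischaemia", 45.0, "ischaemia"),
) + tuple(
    (f"R+{15 * (k + 1)}", 60.0 + 15.0 * k, "reperfusion") for k in range(10)
)


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject: per-timepoint traces plus ground truth."""

    subject_id: str
    profile: CohortProfile
    timepoints: tuple[tuple[str, float, str, FluxTrace], ...]
    truths: tuple[TraceGroundTruth, ...]
    true_multipliers: tuple[float, ...]


def generate_cohort(
    profile: CohortProfile | str,
    n_subjects: int = 6,
    base_params: CardiacSimParams | None = None,
    seed: int = 0,
    multiplier_noise_sd: float = 0.01,
) -> list[SubjectRecord]:
    """Simulate an experimental arm of ``n_subjects`` IR time courses.

    Per-subject seeds derive reproducibly from the cohort seed via
    ``numpy.random.SeedSequence`` spawning. Each timepoint's perfusion level
    is the profile multiplier perturbed by a small Gaussian (subject-level
    biological variability); the baseline multiplier is always exactly 1 so
    percent-of-baseline has a clean reference.
    """
    if isinstance(profile, str):
        try:
            profile = COHORT_PROFILES[profile]
        except KeyError:
            raise ValueError(
                f"unknown profile {profile!r}; valid: {sorted(COHORT_PROFILES)}"
            ) from None
    base = base_params if base_params is not None else CardiacSimParams()
    base = replace(base, amplitude_dispersion=profile.amplitude_dispersion,
                   jitter_sd_s=profile.jitter_sd_s)
    multipliers = (1.0, profile.ischaemia_multiplier) + profile.reperfusion_multipliers
    ss = np.random.SeedSequence(seed)
    subjects = []
    for j, child in enumerate(ss.spawn(n_subjects)):
        tp_seeds = child.generate_state(len(SCHEDULE) + 1) % (2**31)
        rng = np.random.default_rng(tp_seeds[-1])
        tps, truths, true_mults = [], [], []
        for (label, minutes, phase), mult, tp_seed in zip(SCHEDULE, multipliers, tp_seeds):
            m = mult
            if phase != "baseline" and multiplier_noise_sd > 0:
                m = max(0.0, m + rng.normal(0.0, multiplier_noise_sd))
            # amplitude_scale widens the diastolic-systolic swing (the
            # "erratic" phenotype) while leaving the diastolic summary level
            # untouched: the swing grows downward into systole
            amp = base.diastolic_level - base.systolic_level
            dia = base.systolic_level * m + max(amp * m, 1e-6)
            sys_ = max(dia - profile.amplitude_scale * amp * m, 0.0)
            params = replace(
                base,
                systolic_level=sys_,
                diastolic_level=max(dia, sys_ + 1e-6),
                seed=int(tp_seed),
            )
            trace, truth = generate_trace(params)
            tps.append((label, minutes, phase, trace.with_values(trace.values,
                                                                 label=f"s{j}:{label}")))
            truths.append(truth)
            true_mults.append(m)
        subjects.append(
            SubjectRecord(
                subject_id=f"{profile.name}_s{j}",
                profile=profile,
                timepoints=tuple(tps),
                truths=tuple(truths),
                true_multipliers=tuple(true_mults),
            )
        )
    return subjects
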