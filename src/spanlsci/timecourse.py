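"""Ischaemia-reperfusion time courses: motion subtraction, normalisation, AUC.

An IR experiment yields one flux recording per timepoint (baseline before
occlusion, during ischaemia, then every 15 min of reperfusion).  Each
recording is summarised by its mean diastolic flux; the ordered summaries
form a time course that can be expressed as a percentage of baseline and
integrated (trapezoid rule) over the reperfusion phase to give a single
perfusion-recovery number per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import detect_inflections, enforce_alternation
from .flux_io import FluxTrace
from .metrics import mean_diastolic_flux

__all__ = [
    "Timepoint",
    "TimeCourse",
    "AUCResult",
    "subtract_motion",
    "percent_of_baseline",
    "auc_trapezoid",
    "build_timecourse",
]

PHASES = ("baseline", "ischaemia", "reperfusion")


@dataclass(frozen=True)
class Timepoint:
    label: str
    minutes: float
    flux: float
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.flux < 0:
            raise ValueError(f"summary flux must be >= 0, got {self.flux}")


@dataclass(frozen=True)
class TimeCourse:
    """Ordered per-timepoint flux summaries for one subject."""

    timepoints: tuple[Timepoint, ...]

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        minutes = [tp.minutes for tp in tps]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ValueError("timepoint minutes must be strictly increasing")
        n_base = sum(tp.phase == "baseline" for tp in tps)
        if n_base != 1:
            raise ValueError(f"exactly one baseline timepoint required, got {n_base}")
        object.__setattr__(self, "timepoints", tps)

    @property
    def baseline(self) -> Timepoint:
        return next(tp for tp in self.timepoints if tp.phase == "baseline")

    def phase_points(self, *phases: str) -> list[Timepoint]:
        return [tp for tp in self.timepoints if tp.phase in phases]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [tp.label for tp in self.timepoints],
                "minutes": [tp.minutes for tp in self.timepoints],
                "phase": [tp.phase for tp in self.timepoints],
                "flux": [tp.flux for tp in self.timepoints],
            }
        )


@dataclass(frozen=True)
class AUCResult:
    """Trapezoid area under the flux-time curve, in flux-units x minutes."""

    value: float
    phase_restriction: tuple[str, ...]
    n_points: int


def subtract_motion(total: FluxTrace, motion: FluxTrace) -> tuple[FluxTrace, int]:
    """Subtract a motion-only reference trace from a total flux trace.

    The motion trace comes from a covered (opaque-card) region of the same
    ventricle recorded simultaneously: it carries beating-motion artifact but
    no perfusion signal. The point-by-point difference isolates the perfusion
    component. Differences that come out negative are clipped to zero —
    perfusion flux cannot be negative — and the count of clipped samples is
    returned, since many clips indicate a misaligned or mismatched pair.

    Returns
    -------
    (FluxTrace, int)
        The corrected trace and the number of samples clipped at zero.
    """
    if len(total) != len(motion):
        raise ValueError(
            f"trace lengths differ: total {len(total)} vs motion {len(motion)}"
        )
    if total.sampling_rate != motion.sampling_rate:
        raise ValueError(
            f"sampling rates differ: {total.sampling_rate} vs {motion.sampling_rate} Hz"
        )
    diff = total.values - motion.values
    n_clipped = int(np.sum(diff < 0))
    corrected = total.with_values(np.maximum(diff, 0.0),
                                  label=total.label or "motion-subtracted")
    return corrected, n_clipped


def percent_of_baseline(tc: TimeCourse) -> TimeCourse:
    """Express every summary flux as a percentage of the baseline value.

    Flux is in arbitrary units, so absolute values are not comparable across
    subjects; baseline maps to exactly 100. Re-normalising an already
    normalised course is a no-op.
    """
    base = tc.baseline.flux
    if not base > 0:
        raise ValueError(f"baseline flux must be > 0 to normalise, got {base}")
    return TimeCourse(
        tuple(
            Timepoint(
                tp.label, tp.minutes,
                # the baseline is 100 by definition, not by division
                100.0 if tp.phase == "baseline" else 100.0 * tp.flux / base,
                tp.phase,
            )
            for tp in tc.timepoints
        )
    )


def auc_trapezoid(
    tc: TimeCourse,
    phase_restriction: Sequence[str] = ("reperfusion",),
) -> AUCResult:
    """Trapezoid-rule area under the summary flux curve over selected phases.

    Defaults to the reperfusion phase only: ischaemic and baseline points are
    excluded so the integral summarises perfusion recovery. Units are
    flux-units x minutes.
    """
    phases = tuple(phase_restriction)
    for p in phases:
        if p not in PHASES:
            raise ValueError(f"unknown phase {p!r}; valid: {PHASES}")
    pts = tc.phase_points(*phases)
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 timepoints in phase(s) {phases} for an AUC, got {len(pts)}"
        )
    t = np.array([tp.minutes for tp in pts])
    y = np.array([tp.flux for tp in pts])
    value = float(np.trapezoid(y, t))
    return AUCResult(value=value, phase_restriction=phases, n_points=len(pts))


def build_timecourse(
    traces: Iterable[tuple[str, float, str, FluxTrace]],
    margin: int = 2,
) -> TimeCourse:
    """Assemble a time course from labelled per-timepoint recordings.

    Parameters
    ----------
    traces : iterable of (label, minutes, phase, FluxTrace)
        One recording per experimental timepoint.
    margin : int
        Trajectory margin for inflection detection.

    Each recording is summarised by its mean diastolic flux (alternation
    enforced first). Duplicate minutes or a missing baseline are rejected.
    """
    entries = sorted(traces, key=lambda e: e[1])
    minutes = [e[1] for e in entries]
    if len(set(minutes)) != len(minutes):
        dup = next(m for m in minutes if minutes.count(m) > 1)
        raise ValueError(f"duplicate timepoint at {dup} minutes")
    tps = []
    for label, mins, phase, trace in entries:
        labels = enforce_alternation(detect_inflections(trace, margin=margin), trace)
        tps.append(Timepoint(label, mins, mean_diastolic_flux(trace, labels), phase))
    return TimeCourse(tuple(tps))
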