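"""Per-trace cardiac physiology metrics derived from inflection labels.

Accepted diastolic highs serve as surrogates for peak myocardial perfusion
(diastolic flow) and each one marks a heart beat; systolic lows mark the
trough of each cardiac cycle.  From these the module derives mean diastolic
and systolic flux, heart rate, inter-beat intervals and their standard
deviation (the rhythm-irregularity metric), and the mean peak-to-peak
amplitude of the flux oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .detect import InflectionLabels, enforce_alternation
from .flux_io import FluxTrace

__all__ = [
    "BeatMetrics",
    "mean_diastolic_flux",
    "mean_systolic_flux",
    "heart_rate",
    "inter_beat_intervals",
    "ibi_sd",
    "peak_to_peak_amplitude",
    "beat_metrics",
]


@dataclass(frozen=True)
class BeatMetrics:
    """Summary physiology for one flux trace.

    Flux fields are in arbitrary perfusion units; intervals in seconds.
    ``ibi_sd_s`` uses the sample (n-1) standard deviation.
    """

    mean_diastolic_flux: float
    mean_systolic_flux: float
    heart_rate_bpm: float
    inter_beat_intervals_s: np.ndarray
    ibi_sd_s: float
    peak_to_peak_amplitude: float
    n_beats: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inter_beat_intervals_s"] = np.asarray(self.inter_beat_intervals_s).tolist()
        return d


def _values_at(trace: FluxTrace, indices: np.ndarray, what: str) -> np.ndarray:
    if indices.size == 0:
        raise ValueError(f"no beats detected: no accepted {what} in labels")
    return trace.values[indices]


def mean_diastolic_flux(trace: FluxTrace, labels: InflectionLabels) -> float:
    """Mean flux over accepted diastolic highs.

    The diastolic average is the group-comparison perfusion summary: systolic
    troughs are dominated by microvascular compression, so only diastole
    reflects overall microcirculatory perfusion.
    """
    return float(_values_at(trace, labels.highs, "diastolic highs").mean())


def mean_systolic_flux(trace: FluxTrace, labels: InflectionLabels) -> float:
    """Mean flux over accepted systolic lows."""
    return float(_values_at(trace, labels.lows, "systolic lows").mean())


def heart_rate(labels: InflectionLabels, trace: FluxTrace) -> float:
    """Heart rate in beats/min: diastolic events per recording minute.

    Each accepted diastolic high counts as one beat; the count is scaled by
    the actual trace duration (a 56 s recording is normalised to a minute,
    not assumed to be one). Zero highs gives 0 bpm rather than an error.
    """
    duration = trace.duration_s
    if not duration > 0:
        raise ValueError("trace duration must be positive")
    return 60.0 * labels.n_highs / duration


def inter_beat_intervals(
    labels: InflectionLabels,
    sampling_rate: float,
    use: str = "lows",
) -> np.ndarray:
    """Successive intervals (seconds) between systolic points.

    The beat-to-beat distance is measured between one systolic low and the
    next; ``use='highs'`` switches to diastolic-based intervals for
    sensitivity analysis.
    """
    if use not in ("lows", "highs"):
        raise ValueError(f"use must be 'lows' or 'highs', got {use!r}")
    anchors = labels.lows if use == "lows" else labels.highs
    if anchors.size < 2:
        raise ValueError(
            f"need at least 2 accepted {use} to form intervals, got {anchors.size}"
        )
    return np.diff(anchors) / sampling_rate


def ibi_sd(intervals: Sequence[float]) -> float:
    """Sample (n-1 denominator) standard deviation of inter-beat intervals.

    The rhythm-irregularity metric: a steady rhythm gives 0, beat-period
    jitter inflates it.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise ValueError(f"need at least 2 intervals for an SD, got {intervals.size}")
    return float(np.std(intervals, ddof=1))


def peak_to_peak_amplitude(trace: FluxTrace, labels: InflectionLabels) -> float:
    """Mean oscillation amplitude: average of (high flux - next low flux).

    Requires alternation-enforced labels so each high pairs with the next
    low; unpaired trailing extrema are dropped. Elevated amplitude (and its
    dispersion) marks the "erratic" flux phenotype.
    """
    v = trace.values
    amps = []
    lows = labels.lows
    for h in labels.highs:
        following = lows[lows > h]
        if following.size:
            amps.append(v[h] - v[following[0]])
    if not amps:
        raise ValueError("no complete high->low pair; cannot compute amplitude")
    return float(np.mean(amps))


def beat_metrics(
    trace: FluxTrace,
    labels: InflectionLabels,
    alternation_enforced: bool = False,
) -> BeatMetrics:
    """Compute the full :class:`BeatMetrics` bundle for one trace.

    If ``alternation_enforced`` is False the labels are first pruned with
    :func:`~spanlsci.detect.enforce_alternation` so that interval and
    amplitude metrics are well defined.
    """
    if not alternation_enforced:
        labels = enforce_alternation(labels, trace)
    intervals = (
        inter_beat_intervals(labels, trace.sampling_rate)
        if labels.n_lows >= 2
        else np.empty(0)
    )
    return BeatMetrics(
        mean_diastolic_flux=mean_diastolic_flux(trace, labels),
        mean_systolic_flux=mean_systolic_flux(trace, labels),
        heart_rate_bpm=heart_rate(labels, trace),
        inter_beat_intervals_s=intervals,
        ibi_sd_s=ibi_sd(intervals) if intervals.size >= 2 else float("nan"),
        peak_to_peak_amplitude=peak_to_peak_amplitude(trace, labels),
        n_beats=labels.n_highs,
    )
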