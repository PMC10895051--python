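"""SpAn inflection detection: accepted diastolic highs and systolic lows.

Coronary perfusion in the beating heart produces a biphasic flux oscillation:
peaks during diastole (ventricular filling, maximal myocardial flow) and
troughs during systole (microvascular compression).  A sample is accepted as
a diastolic high only if it is reached by ``margin`` strictly increasing
steps and followed by ``margin`` strictly decreasing steps; a systolic low is
the mirror image.  Local extrema that fail the full trajectory requirement
are recorded as rejected rather than silently dropped, so the acceptance
behaviour is auditable.

Plateaus (equal neighbouring samples) break a trajectory: a flat step carries
no directional evidence, so strict inequalities are required throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .flux_io import FluxTrace

__all__ = ["InflectionLabels", "detect_inflections", "enforce_alternation"]

DEFAULT_MARGIN = 2


@dataclass(frozen=True)
class InflectionLabels:
    """Indices of accepted highs/lows and rejected candidate extrema.

    All indices lie in ``[margin, n - 1 - margin]``; samples nearer either
    boundary can never be verified against the trajectory rule and are not
    candidates.
    """

    highs: np.ndarray
    lows: np.ndarray
    rejected: np.ndarray
    margin: int

    def __post_init__(self) -> None:
        for name in ("highs", "lows", "rejected"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
        if np.intersect1d(self.highs, self.lows).size:
            raise ValueError("an index cannot be both a high and a low")

    @property
    def n_highs(self) -> int:
        return self.highs.size

    @property
    def n_lows(self) -> int:
        return self.lows.size

    def to_dict(self) -> dict:
        return {
            "highs": self.highs.tolist(),
            "lows": self.lows.tolist(),
            "rejected": self.rejected.tolist(),
            "margin": self.margin,
        }

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "InflectionLabels":
        d = json.loads(Path(path).read_text())
        return cls(
            highs=np.asarray(d["highs"], dtype=np.int64),
            lows=np.asarray(d["lows"], dtype=np.int64),
            rejected=np.asarray(d["rejected"], dtype=np.int64),
            margin=int(d["margin"]),
        )


def detect_inflections(
    trace: FluxTrace,
    margin: int = DEFAULT_MARGIN,
    skip_initial: int = 0,
) -> InflectionLabels:
    """Label accepted diastolic highs, systolic lows and rejected extrema.

    Index ``i`` is an accepted high iff
    ``v[i-margin] < ... < v[i-1] < v[i] > v[i+1] > ... > v[i+margin]``
    with every inequality strict; an accepted low is the mirror image.
    One-step local extrema inside the candidate range that fail the full
    margin rule are returned in ``rejected``.

    Parameters
    ----------
    trace : FluxTrace
        The flux recording.
    margin : int
        Number of strictly directional steps required on each side
        (default 2, the SpAn rule).
    skip_initial : int
        Discard this many leading samples from candidacy (acquisition
        settling); 0 by default.

    Raises
    ------
    ValueError
        If ``margin < 1`` or the trace is shorter than ``2*margin + 1``.
    """
    if margin < 1:
        raise ValueError(f"margin must be >= 1, got {margin}")
    v = trace.values
    n = v.size
    if n < 2 * margin + 1:
        raise ValueError(
            f"trace of {n} samples is too short for margin {margin}; "
            f"need at least {2 * margin + 1}"
        )
    if skip_initial < 0:
        raise ValueError("skip_initial must be >= 0")

    up = v[1:] > v[:-1]    # up[j]:   step j -> j+1 strictly increasing
    down = v[1:] < v[:-1]  # down[j]: step j -> j+1 strictly decreasing

    lo_bound = max(margin, skip_initial)
    idx = np.arange(lo_bound, n - margin)
    if idx.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return InflectionLabels(empty, empty, empty, margin)

    rise_before = np.ones(idx.size, dtype=bool)
    fall_after = np.ones(idx.size, dtype=bool)
    fall_before = np.ones(idx.size, dtype=bool)
    rise_after = np.ones(idx.size, dtype=bool)
    for k in range(1, margin + 1):
        rise_before &= up[idx - k]
        fall_before &= down[idx - k]
        fall_after &= down[idx + k - 1]
        rise_after &= up[idx + k - 1]

    is_high = rise_before & fall_after
    is_low = fall_before & rise_after
    # one-step candidate extrema that fail the full trajectory rule
    cand_high = up[idx - 1] & down[idx]
    cand_low = down[idx - 1] & up[idx]
    is_rejected = (cand_high | cand_low) & ~is_high & ~is_low

    return InflectionLabels(
        highs=idx[is_high],
        lows=idx[is_low],
        rejected=idx[is_rejected],
        margin=margin,
    )


def enforce_alternation(labels: InflectionLabels, trace: FluxTrace) -> InflectionLabels:
    """Prune labels so highs and lows strictly alternate.

    Between consecutive accepted highs with no intervening low, only the
    higher-flux high is kept (for lows, the lower-flux low); ties keep the
    earlier index.  Optional cleanup pass — the core detector does not
    enforce alternation, since a usable beat sequence is a downstream need,
    not part of the acceptance rule itself.  ``rejected`` is left unchanged:
    pruned extrema passed the trajectory rule.
    """
    v = trace.values
    events = sorted(
        [(int(i), +1) for i in labels.highs] + [(int(i), -1) for i in labels.lows]
    )
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            if kind == +1:
                better = v[idx] > v[prev_idx]  # strict: tie keeps the earlier
            else:
                better = v[idx] < v[prev_idx]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    highs = np.array([i for i, k in kept if k == +1], dtype=np.int64)
    lows = np.array([i for i, k in kept if k == -1], dtype=np.int64)
    return InflectionLabels(highs=highs, lows=lows, rejected=labels.rejected,
                            margin=labels.margin)
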