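"""Flux time-series container and CSV ingestion/export.

LSCI acquisition software exports one flux value per frame for a drawn
region of interest.  Export dialects vary between vendors and software
versions, so the reader takes an explicit column/skip-row specification and
never sniffs the layout: silent misparsing of a perfusion trace is the worst
failure mode for downstream physiology metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["FluxTrace", "read_flux_csv", "write_flux_csv"]

#: Default acquisition rate in Hz (moorFLPI-class devices record at 25 Hz).
DEFAULT_SAMPLING_RATE = 25.0


@dataclass(frozen=True)
class FluxTrace:
    """A uniformly sampled perfusion-flux time series.

    Parameters
    ----------
    values : ndarray
        Flux samples in arbitrary perfusion units, one per frame. Must be
        finite and non-negative.
    sampling_rate : float
        Acquisition rate in Hz; strictly positive.
    label : str
        Free-text tag (ROI name, experimental phase, subject id).
    """

    values: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"flux trace must be 1-D, got shape {values.shape}")
        if values.size < 1:
            raise ValueError("flux trace must contain at least one sample")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(f"non-finite flux value at sample {bad}")
        if np.any(values < 0):
            bad = int(np.flatnonzero(values < 0)[0])
            raise ValueError(
                f"negative flux value {values[bad]} at sample {bad}; "
                "perfusion flux is non-negative by definition"
            )
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds (n_samples / sampling_rate)."""
        return self.values.size / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) / self.sampling_rate

    def with_values(self, values: Sequence[float], label: str | None = None) -> "FluxTrace":
        return FluxTrace(np.asarray(values, dtype=float), self.sampling_rate,
                         self.label if label is None else label)


@dataclass(frozen=True)
class ColumnSpec:
    """Where the flux column lives in a vendor CSV export.

    ``column`` is a 0-based positional index or a header name.
    """

    column: Union[int, str] = 0
    skip_rows: int = 0


def read_flux_csv(
    path: Union[str, Path],
    column: Union[int, str] = 0,
    skip_rows: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    label: str = "",
) -> FluxTrace:
    """Read a flux trace from a CSV export.

    Parameters
    ----------
    path : str or Path
        CSV file. Values must use a decimal point; locale decimal commas are
        rejected.
    column : int or str
        0-based column index, or header name (in which case the first
        non-skipped row is treated as the header).
    skip_rows : int
        Metadata lines to discard before data (vendor exports often prepend
        device/ROI metadata).
    sampling_rate : float
        Acquisition rate in Hz; metadata supplied by the caller, never
        inferred from the file.

    Returns
    -------
    FluxTrace
        Samples in file order.

    Raises
    ------
    ValueError
        On missing/short columns, non-numeric entries (reported with their
        row number) or negative flux.
    FileNotFoundError
        If the file does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"flux CSV not found: {path}")
    header = 0 if isinstance(column, str) else None
    try:
        frame = pd.read_csv(
            path,
            skiprows=skip_rows,
            header=header,
            dtype=str,
            skip_blank_lines=True,
            comment=None,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows after skipping {skip_rows} line(s)")
    if isinstance(column, str):
        if column not in frame.columns:
            raise ValueError(
                f"{path}: column {column!r} not found; available: {list(frame.columns)}"
            )
        raw = frame[column]
    else:
        if column >= frame.shape[1]:
            raise ValueError(
                f"{path}: column index {column} out of range (file has "
                f"{frame.shape[1]} column(s))"
            )
        raw = frame.iloc[:, column]
    raw = raw.astype(str).str.strip()
    if len(raw) == 0:
        raise ValueError(f"{path}: no flux samples found")
    # parse with Python's float(): correctly rounded, unlike pandas' fast
    # default parser, so written values round-trip bit-exactly
    values = np.empty(len(raw))
    header_offset = 1 if isinstance(column, str) else 0
    for i, text in enumerate(raw):
        try:
            values[i] = float(text)
        except ValueError:
            row = i + skip_rows + 1 + header_offset  # 1-based file line
            raise ValueError(
                f"{path}: non-numeric flux value {text!r} at file line {row} "
                "(decimal points required; locale commas are not supported)"
            ) from None
        if not np.isfinite(values[i]):
            row = i + skip_rows + 1 + header_offset
            raise ValueError(f"{path}: non-finite flux value at file line {row}")
    return FluxTrace(values, sampling_rate=sampling_rate, label=label)


def write_flux_csv(trace: FluxTrace, path: Union[str, Path]) -> Path:
    """Write a trace as ``frame,time_s,flux`` with full float precision.

    ``time_s`` is frame index divided by the sampling rate. Round-trips
    exactly through :func:`read_flux_csv` (value-wise).
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "frame": np.arange(trace.n_samples),
            "time_s": trace.times_s,
            "flux": trace.values,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    return path
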