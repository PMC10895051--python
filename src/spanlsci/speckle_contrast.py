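"""Spatial speckle contrast and flux maps from raw frame stacks.

Speckle contrast is the local ratio K = sigma/<I> of intensity standard
deviation to mean intensity over a small sliding window.  Moving scatterers
(red blood cells) blur the speckle pattern within the camera exposure,
lowering K; flux is therefore a decreasing function of K.  A region of
interest is reduced to one flux value per frame by a plain pixel average,
which is how commercial LSCI software reports ROI flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .flux_io import FluxTrace

__all__ = [
    "SpeckleStack",
    "ContrastMap",
    "FluxMap",
    "ROIMask",
    "spatial_contrast",
    "flux_from_contrast",
    "roi_mean_flux",
    "stack_to_trace",
    "temporal_smooth",
]

DEFAULT_WINDOW = 5
DEFAULT_CONTRAST_FLOOR = 1e-3


@dataclass(frozen=True)
class SpeckleStack:
    """Raw speckle intensity frames (time x rows x cols) with timing metadata."""

    frames: np.ndarray
    exposure_time: float
    frame_rate: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, rows, cols); got shape {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if np.any(frames < 0):
            raise ValueError("intensities must be non-negative")
        if not self.exposure_time > 0:
            raise ValueError(f"exposure_time must be > 0, got {self.exposure_time}")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ContrastMap:
    """Per-pixel speckle contrast K with a validity mask.

    ``valid_mask`` is False where the sliding window exits the image or where
    the window mean is zero (K undefined there).
    """

    values: np.ndarray
    window_size: int
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ValueError(f"window_size must be odd and >= 3, got {self.window_size}")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")


@dataclass(frozen=True)
class FluxMap:
    """Per-pixel flux F = 1/max(K, floor)^2 in arbitrary perfusion units."""

    values: np.ndarray
    contrast_floor: float
    valid_mask: np.ndarray


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask; must select at least one pixel."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError(f"ROI mask must be 2-D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError("ROI mask selects no pixels")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_rect(cls, shape: tuple[int, int], row0: int, col0: int,
                  height: int, width: int) -> "ROIMask":
        mask = np.zeros(shape, dtype=bool)
        mask[row0:row0 + height, col0:col0 + width] = True
        return cls(mask)


def _contrast_single(frame: np.ndarray, window_size: int) -> ContrastMap:
    # local mean and mean-of-squares via uniform filters; population variance
    # = E[I^2] - E[I]^2 (divide-by-n, the standard LSCI definition)
    mean = ndimage.uniform_filter(frame, size=window_size, mode="constant")
    mean_sq = ndimage.uniform_filter(frame * frame, size=window_size, mode="constant")
    var = mean_sq - mean * mean
    np.clip(var, 0.0, None, out=var)  # guard tiny negative round-off

    half = window_size // 2
    valid = np.zeros(frame.shape, dtype=bool)
    if frame.shape[0] > 2 * half and frame.shape[1] > 2 * half:
        valid[half:frame.shape[0] - half, half:frame.shape[1] - half] = True
    zero_mean = mean <= 0
    valid &= ~zero_mean

    k = np.full(frame.shape, np.nan)
    np.divide(np.sqrt(var), mean, out=k, where=valid)
    k[~valid] = np.nan
    return ContrastMap(values=k, window_size=window_size, valid_mask=valid)


def spatial_contrast(stack: SpeckleStack, window_size: int = DEFAULT_WINDOW) -> list[ContrastMap]:
    """Compute a per-frame spatial contrast map.

    K at each pixel is the population standard deviation over the centred
    ``window_size`` x ``window_size`` window divided by the window mean.
    Pixels whose window exits the image, or whose window mean is zero, are
    marked invalid rather than padded or zero-filled.

    Raises
    ------
    ValueError
        If the window is even, < 3, or not smaller than both frame dimensions.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window_size must be odd and >= 3, got {window_size}")
    rows, cols = stack.shape
    if window_size >= rows or window_size >= cols:
        raise ValueError(
            f"window_size {window_size} does not fit inside {rows}x{cols} frames"
        )
    return [_contrast_single(frame, window_size) for frame in stack.frames]


def flux_from_contrast(cmap: ContrastMap, contrast_floor: float = DEFAULT_CONTRAST_FLOOR) -> FluxMap:
    """Map contrast to flux with the inverse-square model F = 1/max(K, floor)^2.

    The floor clips near-zero contrast (static, fully blurred or degenerate
    pixels) so flux stays finite; F is strictly decreasing in K above the
    floor. Flux is in arbitrary perfusion units.
    """
    if not contrast_floor > 0:
        raise ValueError(f"contrast_floor must be > 0, got {contrast_floor}")
    k = np.maximum(cmap.values, contrast_floor)
    flux = np.full(cmap.values.shape, np.nan)
    np.divide(1.0, k * k, out=flux, where=cmap.valid_mask)
    flux[~cmap.valid_mask] = np.nan
    return FluxMap(values=flux, contrast_floor=contrast_floor, valid_mask=cmap.valid_mask)


def roi_mean_flux(fmap: FluxMap, roi: ROIMask) -> float:
    """Mean flux over the valid pixels of a region of interest.

    A simple average: the summed flux inside the ROI divided by the number of
    contributing (valid) pixels.
    """
    if roi.mask.shape != fmap.values.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match map shape {fmap.values.shape}"
        )
    sel = roi.mask & fmap.valid_mask
    if not sel.any():
        raise ValueError("ROI contains no valid pixels (all windows off-image or degenerate)")
    return float(fmap.values[sel].mean())


def stack_to_trace(
    stack: SpeckleStack,
    roi: ROIMask,
    window_size: int = DEFAULT_WINDOW,
    contrast_floor: float = DEFAULT_CONTRAST_FLOOR,
    label: str = "",
) -> FluxTrace:
    """Reduce a raw stack to a flux time series: contrast -> flux -> ROI mean per frame."""
    cmaps = spatial_contrast(stack, window_size)
    values = np.array(
        [roi_mean_flux(flux_from_contrast(c, contrast_floor), roi) for c in cmaps]
    )
    return FluxTrace(values, sampling_rate=stack.frame_rate, label=label)


def temporal_smooth(trace: FluxTrace, window_s: float) -> FluxTrace:
    """Optional moving-average smoother (window in seconds).

    Off by default everywhere: provided only for parity experiments with
    acquisition GUIs that apply temporal display smoothing (e.g. a 0.1 s
    "time constant"). Uses a centred boxcar with edge truncation.
    """
    if not window_s > 0:
        raise ValueError("window_s must be > 0")
    n = max(1, int(round(window_s * trace.sampling_rate)))
    if n == 1:
        return trace
    kernel = np.ones(n) / n
    smoothed = np.convolve(trace.values, kernel, mode="same")
    # renormalise edges where the kernel is truncated
    norm = np.convolve(np.ones_like(trace.values), kernel, mode="same")
    return trace.with_values(smoothed / norm)
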