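"""Synthetic raw speckle stacks with controlled decorrelation statistics.

Fully developed speckle from a rough surface under coherent illumination has
a circular complex Gaussian field; the intensity (squared modulus) is
exponentially distributed, giving unit contrast K = sigma/<I> = 1 in the
static, fine-grain (pixel-independent) limit.  Moving scatterers decorrelate
the field with characteristic time tau_c (inversely related to velocity);
within a camera exposure the detector integrates many partially correlated
realizations, shrinking the intensity spread and hence K.

Exposure integration is modelled by discrete substep averaging of an
AR(1)-evolving complex field with per-substep correlation exp(-dt/tau_c):
simple, seedable, and with the right limits (static -> K = 1, fast flow ->
K -> 0) and a monotone contrast-velocity response — no claim to match the
exact closed-form K(T/tau_c) curve beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..speckle_contrast import SpeckleStack

__all__ = ["SpeckleSimParams", "generate_static_speckle", "generate_dynamic_stack"]


@dataclass(frozen=True)
class SpeckleSimParams:
    """Parameters for a dynamic speckle stack simulation.

    ``correlation_time_map`` gives per-pixel tau_c in seconds (scalar input is
    broadcast); smaller tau_c means faster scatterers and lower contrast.
    """

    shape: tuple[int, int]
    n_frames: int
    exposure_time: float
    frame_rate: float
    correlation_time_map: np.ndarray | float
    n_integration_substeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        tau = np.broadcast_to(np.asarray(self.correlation_time_map, dtype=float),
                              self.shape).copy()
        if np.any(tau <= 0):
            raise ValueError("correlation times must be strictly positive")
        if self.n_integration_substeps < 1:
            raise ValueError("n_integration_substeps must be >= 1")
        if not 0 < self.exposure_time <= 1.0 / self.frame_rate:
            raise ValueError(
                f"exposure_time must lie in (0, 1/frame_rate]; got "
                f"{self.exposure_time} at {self.frame_rate} Hz"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "correlation_time_map", tau)


def _complex_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance circular complex Gaussian field, pixel-independent."""
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def generate_static_speckle(shape: tuple[int, int], seed: int = 0) -> np.ndarray:
    """One static fully developed speckle frame (exponential intensity).

    Theoretical global contrast is exactly 1; a 256x256 frame measures within
    a few percent of it.
    """
    rng = np.random.default_rng(seed)
    field = _complex_field(shape, rng)
    return np.abs(field) ** 2


def generate_dynamic_stack(params: SpeckleSimParams) -> tuple[SpeckleStack, dict]:
    """Simulate an exposure-integrated dynamic speckle stack.

    Each frame averages ``n_integration_substeps`` instantaneous intensity
    realizations; between substeps the field evolves as an AR(1) process with
    per-pixel correlation ``exp(-dt/tau_c)``.  Between frames the field keeps
    evolving through the dead time so consecutive frames decorrelate
    consistently with tau_c.

    Returns the stack and a ground-truth dict with the tau_c map and the
    substep interval.
    """
    tau = params.correlation_time_map
    dt = params.exposure_time / params.n_integration_substeps
    if np.any(dt > tau / 2.0):
        warnings.warn(
            "substep interval exceeds tau_c/2 for some pixels; exposure "
            "integration is too coarse to resolve the decorrelation",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    rho = np.exp(-dt / tau)
    innov = np.sqrt(1.0 - rho**2)
    dead_time = 1.0 / params.frame_rate - params.exposure_time
    if dead_time > 0:
        rho_dead = np.exp(-dead_time / tau)
        innov_dead = np.sqrt(1.0 - rho_dead**2)

    field = _complex_field(params.shape, rng)
    frames = np.empty((params.n_frames,) + tuple(params.shape))
    for f in range(params.n_frames):
        acc = np.abs(field) ** 2
        for _ in range(params.n_integration_substeps - 1):
            field = rho * field + innov * _complex_field(params.shape, rng)
            acc += np.abs(field) ** 2
        frames[f] = acc / params.n_integration_substeps
        if dead_time > 0:
            field = rho_dead * field + innov_dead * _complex_field(params.shape, rng)

    stack = SpeckleStack(frames=frames, exposure_time=params.exposure_time,
                         frame_rate=params.frame_rate)
    truth = {
        "correlation_time_map": tau,
        "substep_interval_s": dt,
        "n_integration_substeps": params.n_integration_substeps,
    }
    return stack, truth
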