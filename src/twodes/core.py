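"""Axes, units, the central dataset container, and generic 2D peak location.

Conventions used throughout the package:

* Frequencies (excitation ``w1``, emission ``w3``, beat frequencies) are in
  wavenumbers, cm^-1.  Population times ``t2`` are in femtoseconds.
* The data cube is ordered ``(excitation, emission, time)``; a 2D map is a
  matrix of shape ``(n_excitation, n_emission)``.
* The speed of light ``C_CM_PER_FS`` is defined once here and used by every
  module that converts between time and wavenumber domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import DomainError

#: Speed of light in cm/fs.
C_CM_PER_FS = 2.99792458e-5

#: Gaussian time-bandwidth product (intensity FWHM x spectral FWHM) = 2 ln2 / pi.
GAUSSIAN_TBP = 2.0 * math.log(2.0) / math.pi

_UNIFORMITY_RTOL = 1e-6


def _check_uniform(values: np.ndarray, what: str) -> None:
    steps = np.diff(values)
    if np.any(steps <= 0):
        raise DomainError(f"{what} must be strictly increasing")
    step = steps.mean()
    if np.max(np.abs(steps - step)) > _UNIFORMITY_RTOL * abs(step):
        raise DomainError(f"{what} must be uniformly spaced")


@dataclass(frozen=True)
class FrequencyAxis:
    """Uniform, strictly increasing wavenumber grid in cm^-1 (length >= 8)."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 8:
            raise DomainError("frequency axis needs >= 8 points")
        if not np.all(np.isfinite(values)):
            raise DomainError("frequency axis values must be finite")
        _check_uniform(values, "frequency axis")

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def nearest_index(self, value: float) -> int:
        """Index of the closest grid point; ties broken toward the lower index."""
        if not (self.lo <= value <= self.hi):
            raise DomainError(
                f"{value} cm^-1 outside axis range [{self.lo}, {self.hi}]"
            )
        dist = np.abs(self.values - value)
        return int(np.argmin(dist))  # argmin returns the first (lower) index on ties


@dataclass(frozen=True)
class TimeAxis:
    """Uniform, strictly increasing population-time grid in fs.

    Starts at 0 for freshly generated data; a fit window may truncate it so a
    nonzero origin is allowed.  A single-point axis is valid (no step defined).
    """

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise DomainError("time axis needs >= 1 point")
        if not np.all(np.isfinite(values)):
            raise DomainError("time axis values must be finite")
        if values.size >= 2:
            _check_uniform(values, "time axis")

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        if self.values.size < 2:
            raise DomainError("single-point time axis has no step")
        return float(self.values[1] - self.values[0])


@dataclass(frozen=True)
class Map2D:
    """A single absorptive 2D frequency-frequency map.

    ``amplitude[i, j]`` is the signal at excitation ``excitation.values[i]``
    and emission ``emission.values[j]`` (arbitrary signal units).
    """

    excitation: FrequencyAxis
    emission: FrequencyAxis
    amplitude: np.ndarray

    def __post_init__(self):
        amp = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "amplitude", amp)
        if amp.shape != (len(self.excitation), len(self.emission)):
            raise DomainError(
                f"map shape {amp.shape} does not match axes "
                f"({len(self.excitation)}, {len(self.emission)})"
            )
        if not np.all(np.isfinite(amp)):
            raise DomainError("map amplitudes must be finite")


@dataclass
class Dataset2DES:
    """Stack of absorptive 2D maps versus population time.

    The cube is ordered ``(excitation, emission, time)``.  ``meta`` carries
    free-form provenance (preset name, temperature label, noise seed, ...).
    """

    excitation: FrequencyAxis
    emission: FrequencyAxis
    time: TimeAxis
    cube: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cube = np.asarray(self.cube, dtype=float)
        expected = (len(self.excitation), len(self.emission), len(self.time))
        if self.cube.shape != expected:
            raise DomainError(
                f"cube shape {self.cube.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.cube)):
            raise DomainError("cube values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.cube)))

    def map_at_index(self, k: int) -> Map2D:
        return Map2D(self.excitation, self.emission, self.cube[:, :, k])

    def map_at(self, t2: float) -> Map2D:
        """Map at the population time nearest ``t2`` (ties to lower index)."""
        dist = np.abs(self.time.values - t2)
        return self.map_at_index(int(np.argmin(dist)))

    def copy(self) -> "Dataset2DES":
        return Dataset2DES(
            self.excitation, self.emission, self.time, self.cube.copy(), dict(self.meta)
        )


# ---------------------------------------------------------------------------
# unit conversions and Fourier plumbing


def wavelength_nm_to_wavenumber(lam: float) -> float:
    """Convert a vacuum wavelength in nm to a wavenumber in cm^-1 (1e7 / lambda)."""
    if not lam > 0:
        raise DomainError("wavelength must be positive")
    return 1e7 / lam


def wavenumber_to_wavelength_nm(nu: float) -> float:
    """Inverse of :func:`wavelength_nm_to_wavenumber`."""
    if not nu > 0:
        raise DomainError("wavenumber must be positive")
    return 1e7 / nu


def transform_limited_gaussian_bandwidth(dt_fs: float) -> float:
    """Spectral FWHM (cm^-1) of a transform-limited Gaussian pulse.

    For a Gaussian pulse the intensity-FWHM duration and the spectral FWHM
    satisfy ``dt * dnu = 2 ln2 / pi``; a 10 fs pulse therefore corresponds to
    a bandwidth of about 1471 cm^-1.
    """
    if not dt_fs > 0:
        raise DomainError("pulse duration must be positive")
    return GAUSSIAN_TBP / (dt_fs * C_CM_PER_FS)


def fft_wavenumber_axis(dt_fs: float, n: int, pad_factor: int = 1) -> FrequencyAxis:
    """Non-negative DFT frequency grid in cm^-1 for ``n * pad_factor`` samples.

    The last value is the Nyquist frequency ``1 / (2 dt c)``; the bin spacing
    is ``1 / (n pad_factor dt c)``.
    """
    if not dt_fs > 0:
        raise DomainError("sampling step must be positive")
    if n < 2:
        raise DomainError("need at least 2 samples")
    if pad_factor < 1:
        raise DomainError("pad_factor must be >= 1")
    n_total = n * pad_factor
    freqs = np.fft.rfftfreq(n_total, d=dt_fs) / C_CM_PER_FS
    return FrequencyAxis(freqs)


# ---------------------------------------------------------------------------
# peak location


def _parabolic_offset(y_m: float, y_0: float, y_p: float) -> tuple[float, float]:
    """Sub-pixel offset (in units of the grid step) and peak value from a
    3-point parabola through (y_m, y_0, y_p); offset clamped to [-0.5, 0.5]."""
    denom = y_m - 2.0 * y_0 + y_p
    if denom == 0.0:
        return 0.0, y_0
    delta = 0.5 * (y_m - y_p) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    peak = y_0 - 0.25 * (y_m - y_p) * delta
    return delta, peak


def locate_extremum(
    map2d: Map2D,
    mode: Literal["max", "min"] = "max",
    window: Sequence[float] | None = None,
    mask: np.ndarray | None = None,
    local_only: bool = False,
) -> tuple[float, float, float]:
    """Locate the extremal feature of a 2D map with sub-pixel refinement.

    Parameters
    ----------
    mode
        ``"max"`` for the most positive pixel, ``"min"`` for the most negative.
    window
        Optional axis-aligned rectangle ``(w1_lo, w1_hi, w3_lo, w3_hi)`` in
        cm^-1; must overlap the grid by at least 3x3 pixels.
    mask
        Optional boolean array (same shape as the map) restricting the search
        to arbitrary regions, e.g. below-diagonal pixels.  Combined (AND) with
        the window if both are given.
    local_only
        Restrict the search to genuine local extrema of the full map (pixels
        extremal among their 8 neighbours).  Use this when a mask cuts
        through the shoulder of a stronger feature outside the region, which
        would otherwise win as a spurious boundary extremum.

    Returns
    -------
    (w1, w3, value)
        Coordinates refined by independent 1D 3-point parabolic interpolation
        along each axis (skipped at grid edges) and the interpolated value.
    """
    if mode not in ("max", "min"):
        raise DomainError(f"mode must be 'max' or 'min', got {mode!r}")
    amp = map2d.amplitude
    w1 = map2d.excitation.values
    w3 = map2d.emission.values

    allowed = np.ones(amp.shape, dtype=bool)
    if window is not None:
        lo1, hi1, lo3, hi3 = window
        sel1 = (w1 >= lo1) & (w1 <= hi1)
        sel3 = (w3 >= lo3) & (w3 <= hi3)
        if sel1.sum() < 3 or sel3.sum() < 3:
            raise DomainError("window must overlap the grid by >= 3x3 pixels")
        allowed &= sel1[:, None] & sel3[None, :]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != amp.shape:
            raise DomainError("mask shape does not match the map")
        allowed &= mask
    if local_only:
        signed = amp if mode == "max" else -amp
        interior = np.zeros(amp.shape, dtype=bool)
        c = signed[1:-1, 1:-1]
        interior[1:-1, 1:-1] = (
            (c >= signed[:-2, 1:-1]) & (c >= signed[2:, 1:-1])
            & (c >= signed[1:-1, :-2]) & (c >= signed[1:-1, 2:])
            & (c >= signed[:-2, :-2]) & (c >= signed[2:, 2:])
            & (c >= signed[:-2, 2:]) & (c >= signed[2:, :-2])
        )
        allowed &= interior
    if not allowed.any():
        raise DomainError("empty search region")

    search = np.where(allowed, amp, -np.inf if mode == "max" else np.inf)
    flat = np.argmax(search) if mode == "max" else np.argmin(search)
    i, j = np.unravel_index(flat, amp.shape)

    x1, v1 = float(w1[i]), float(amp[i, j])
    x3 = float(w3[j])
    vals = []
    if 0 < i < amp.shape[0] - 1:
        d1, p1 = _parabolic_offset(amp[i - 1, j], amp[i, j], amp[i + 1, j])
        x1 += d1 * map2d.excitation.step
        vals.append(p1)
    if 0 < j < amp.shape[1] - 1:
        d3, p3 = _parabolic_offset(amp[i, j - 1], amp[i, j], amp[i, j + 1])
        x3 += d3 * map2d.emission.step
        vals.append(p3)
    value = float(np.mean(vals)) if vals else v1
    return x1, x3, value


def slice_trace(ds: Dataset2DES, w1: float, w3: float) -> np.ndarray:
    """Population-time trace of the pixel nearest ``(w1, w3)``.

    Nearest-pixel extraction (no interpolation); distance ties break toward
    the lower index.
    """
    i = ds.excitation.nearest_index(w1)
    j = ds.emission.nearest_index(w3)
    return ds.cube[i, j, :].copy()
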