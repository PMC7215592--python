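"""Center line slope (CLS) analysis of spectral diffusion.

For each population time, the emission-frequency position of the signal
maximum is located in every excitation column inside a window around the
diagonal peak; the slope of the weighted straight-line fit of those centers
against excitation frequency is the CLS.  For a bivariate-Gaussian peak the
CLS equals ``rho * sigma3 / sigma1``, so with equal marginal widths it reads
out the excitation-emission correlation directly and its decay versus t2
tracks the frequency-frequency correlation function (spectral diffusion).

The CLS trace is fitted with ``a * exp(-t2/tau) + b``; ``tau`` is the
spectral-diffusion time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import Dataset2DES, Map2D, _parabolic_offset, locate_extremum
from .exceptions import DomainError, FitError


@dataclass(frozen=True)
class CLSConfig:
    """Settings for center-line extraction.

    ``window`` is ``(w1_lo, w1_hi, w3_lo, w3_hi)`` in cm^-1; when ``None``
    it is auto-derived from the t2 = 0 slice as peak center +- 1.2 x FWHM on
    each axis.  Columns whose maximum falls below ``min_rel_intensity`` of
    the windowed slice maximum are excluded from the line fit.
    """

    window: tuple[float, float, float, float] | None = None
    column_method: Literal["parabolic", "centroid"] = "parabolic"
    min_rel_intensity: float = 0.2
    weighted: bool = True
    window_widen: float = 1.2

    def __post_init__(self):
        if not (0 < self.min_rel_intensity < 1):
            raise DomainError("min_rel_intensity must be in (0, 1)")
        if self.column_method not in ("parabolic", "centroid"):
            raise DomainError("column_method must be 'parabolic' or 'centroid'")


@dataclass
class CLSTrace:
    """Center line slope versus population time.

    Only t2 points where a valid slope could be computed are recorded, so
    ``t2`` may be a non-uniform subset of the dataset's time axis.
    """

    t2: np.ndarray
    slope: np.ndarray
    n_columns: np.ndarray

    def __post_init__(self):
        self.t2 = np.asarray(self.t2, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        self.n_columns = np.asarray(self.n_columns, dtype=int)
        if not np.all(np.isfinite(self.slope)):
            raise DomainError("CLS slopes must be finite")
        if np.any(np.abs(self.slope) > 2.0):
            raise DomainError("|CLS| > 2 fails the sanity bound")

    def __len__(self) -> int:
        return self.t2.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t2_fs": self.t2, "slope": self.slope, "n_columns": self.n_columns}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CLSFit:
    """Exponential fit ``slope(t2) = a exp(-t2/tau) + b`` of a CLS trace.

    ``tau_identifiable`` is False for (near-)constant traces, where the decay
    amplitude ``a`` is indistinguishable from zero and ``b`` carries the
    level; ``tau`` is then meaningless and should not be interpreted.
    """

    tau: float
    a: float
    b: float
    rmse: float
    tau_identifiable: bool = True
    n_points: int = 0

    def summary(self) -> str:
        lines = ["CLS exponential fit: slope(t2) = a*exp(-t2/tau) + b"]
        if self.tau_identifiable:
            lines.append(f"  tau  = {self.tau:.1f} fs (spectral diffusion)")
        else:
            lines.append("  tau  = not identifiable (trace is constant; "
                         "no spectral diffusion detected)")
        lines.append(f"  a    = {self.a:+.4f}")
        lines.append(f"  b    = {self.b:+.4f}")
        lines.append(f"  rmse = {self.rmse:.4g} over {self.n_points} points")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def _axis_fwhm(x: np.ndarray, profile: np.ndarray, i_peak: int) -> float:
    """FWHM of a 1D cut through its maximum, by linear interpolation of the
    half-maximum crossings; falls back to the available half-width at edges."""
    peak = profile[i_peak]
    half = 0.5 * peak
    step = x[1] - x[0]

    def _cross(idx_range) -> float:
        prev = i_peak
        for i in idx_range:
            if profile[i] < half:
                frac = (profile[prev] - half) / (profile[prev] - profile[i])
                return abs(x[prev] - x[i]) * frac + abs(x[i_peak] - x[prev])
            prev = i
        return abs(x[idx_range[-1]] - x[i_peak]) if len(idx_range) else step

    left = _cross(range(i_peak - 1, -1, -1))
    right = _cross(range(i_peak + 1, len(x)))
    return left + right


def derive_window(map2d: Map2D, widen: float = 1.2) -> tuple[float, float, float, float]:
    """Default CLS window: peak center +- ``widen`` x FWHM on both axes."""
    w1c, w3c, _ = locate_extremum(map2d, "max")
    i = map2d.excitation.nearest_index(w1c)
    j = map2d.emission.nearest_index(w3c)
    fwhm1 = _axis_fwhm(map2d.excitation.values, map2d.amplitude[:, j], i)
    fwhm3 = _axis_fwhm(map2d.emission.values, map2d.amplitude[i, :], j)
    return (w1c - widen * fwhm1, w1c + widen * fwhm1,
            w3c - widen * fwhm3, w3c + widen * fwhm3)


def center_line(
    map2d: Map2D, config: CLSConfig | None = None
) -> list[tuple[float, float, float]]:
    """Per-column emission centers of the windowed peak.

    Returns ``(w1, w3_center, weight)`` for every excitation column inside
    the window whose maximum passes ``min_rel_intensity`` (relative to the
    windowed slice maximum); the center is the column maximum refined by
    3-point parabolic interpolation, or the intensity centroid.
    """
    config = config or CLSConfig()
    window = config.window or derive_window(map2d, config.window_widen)
    lo1, hi1, lo3, hi3 = window
    w1 = map2d.excitation.values
    w3 = map2d.emission.values
    cols = np.where((w1 >= lo1) & (w1 <= hi1))[0]
    rows = np.where((w3 >= lo3) & (w3 <= hi3))[0]
    if cols.size < 3 or rows.size < 2:
        raise DomainError("CLS window does not overlap the grid")
    sub = map2d.amplitude[np.ix_(cols, rows)]
    slice_max = float(sub.max())
    if slice_max <= 0:
        raise DomainError("windowed slice has no positive signal")
    w3_win = w3[rows]
    out: list[tuple[float, float, float]] = []
    for ci, col in zip(cols, sub):
        cmax = float(col.max())
        if cmax < config.min_rel_intensity * slice_max:
            continue
        j = int(np.argmax(col))
        if config.column_method == "parabolic":
            if 0 < j < col.size - 1:
                d, _ = _parabolic_offset(col[j - 1], col[j], col[j + 1])
            else:
                d = 0.0
            center = w3_win[j] + d * map2d.emission.step
        else:  # centroid of the positive intensity
            w = np.clip(col, 0.0, None)
            center = float(np.sum(w * w3_win) / np.sum(w))
        out.append((float(w1[ci]), float(center), cmax))
    if len(out) < 3:
        raise DomainError("fewer than 3 usable excitation columns in the CLS window")
    return out


def cls_value(map2d: Map2D, config: CLSConfig | None = None) -> float:
    """Weighted least-squares slope of the center line (emission center
    versus excitation frequency)."""
    config = config or CLSConfig()
    pts = center_line(map2d, config)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    w = np.array([p[2] for p in pts]) if config.weighted else np.ones(len(pts))
    xm = np.sum(w * x) / np.sum(w)
    ym = np.sum(w * y) / np.sum(w)
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 1e-12 * np.sum(w) * max(1.0, xm**2):
        raise DomainError("degenerate excitation spread in the center line")
    return float(np.sum(w * (x - xm) * (y - ym)) / sxx)


def cls_trace(ds: Dataset2DES, config: CLSConfig | None = None) -> CLSTrace:
    """CLS per t2 slice; the window is fixed from the t2 = 0 slice.

    Slices where the center line is degenerate (too few columns, no signal)
    are skipped; the trace records usable points only.
    """
    config = config or CLSConfig()
    if config.window is None:
        window = derive_window(ds.map_at_index(0), config.window_widen)
        config = CLSConfig(
            window=window, column_method=config.column_method,
            min_rel_intensity=config.min_rel_intensity,
            weighted=config.weighted, window_widen=config.window_widen,
        )
    t2s, slopes, ncols = [], [], []
    for k, t2 in enumerate(ds.time.values):
        m = ds.map_at_index(k)
        try:
            pts = center_line(m, config)
            slope = cls_value(m, config)
        except DomainError:
            continue
        t2s.append(t2)
        slopes.append(slope)
        ncols.append(len(pts))
    if not t2s:
        raise DomainError("no t2 slice yielded a valid center line")
    return CLSTrace(np.array(t2s), np.array(slopes), np.array(ncols))


def fit_cls_exponential(trace: CLSTrace) -> CLSFit:
    """Fit ``a exp(-t2/tau) + b`` to a CLS trace.

    Nonlinear least squares with multistart on tau (log-spaced over the t2
    span).  Near-constant traces are flagged ``tau_identifiable=False``;
    ``b`` then carries the level.
    """
    if len(trace) < 5:
        raise DomainError("need at least 5 CLS points to fit an exponential")
    t = trace.t2
    y = trace.slope
    span = float(t[-1] - t[0]) or 1.0

    def model(p, tt):
        a, log_tau, b = p
        return a * np.exp(-tt / 10.0**log_tau) + b

    def resid(p):
        return model(p, t) - y

    best = None
    a0 = float(y[0] - y[-1])
    b0 = float(y[-1])
    for tau0 in np.geomspace(span / 50.0, span * 2.0, 8):
        try:
            sol = least_squares(resid, x0=[a0, np.log10(tau0), b0],
                                method="lm", max_nfev=2000)
        except Exception:
            continue
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0] - 1e-15 or (
            abs(cost - best[0]) <= 1e-15 and 10.0 ** sol.x[1] < best[1][1]
        ):
            best = (cost, (sol.x[0], 10.0 ** sol.x[1], sol.x[2]))
    if best is None:
        raise FitError("CLS exponential fit did not converge",
                       diagnostics={"n_points": len(trace)})
    cost, (a, tau, b) = best
    rmse = float(np.sqrt(cost / len(trace)))
    # a indistinguishable from zero (relative to the scatter) => tau unidentifiable
    identifiable = abs(a) > max(0.02, 3.0 * rmse)
    return CLSFit(tau=float(tau), a=float(a), b=float(b), rmse=rmse,
                  tau_identifiable=bool(identifiable), n_points=len(trace))
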