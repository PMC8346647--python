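"""Raw thermogram conditioning: smoothing, conversion, DTG/DSC derivatives.

A thermogravimetric run records time, sample temperature, sample mass and
DSC heat flow.  Analysis operates on derived curves: the conversion degree

    x = (m₀ − m) / (m₀ − m∞)

with m₀ and m∞ the masses at the analysis-window boundaries, and its
temperature derivative dx/dT (the DTG curve).  Moisture removal and light
volatiles dominate below 200 °C, so the default analysis window is
200–600 °C and masses below it do not enter x.

Instrument noise is suppressed with a single mild Savitzky–Golay pass
(local least-squares polynomial, default window 21 / order 3) before
differentiation; aggressive filtering can erase minor DTG peaks, so the
filter is never applied twice and the parameters are configurable.

Sign convention for heat flow: exothermic positive, endothermic negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .constants import c_to_k
from .daem import RateCurve

__all__ = [
    "Thermogram",
    "savitzky_golay",
    "conversion_from_mass",
    "derivative_wrt_temperature",
    "truncate_window",
    "average_replicates",
    "dtg_curve",
    "dsc_curve",
    "dsc_derivative_curve",
    "DEFAULT_WINDOW_K",
    "DEFAULT_SMOOTH_WINDOW",
    "DEFAULT_SMOOTH_ORDER",
]

DEFAULT_WINDOW_K = (c_to_k(200.0), c_to_k(600.0))
DEFAULT_SMOOTH_WINDOW = 21
DEFAULT_SMOOTH_ORDER = 3


@dataclass
class Thermogram:
    """One TGA/DSC run: time (s), temperature (K), mass (mg), heat flow (mW)."""

    time: np.ndarray
    temperature: np.ndarray
    mass: np.ndarray
    heat_flow: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        for name in ("time", "temperature", "mass", "heat_flow"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.temperature.size
        if n < 10:
            raise ValueError(f"thermogram too short ({n} points; need ≥ 10)")
        for name in ("time", "mass", "heat_flow"):
            if getattr(self, name).size != n:
                raise ValueError("thermogram channels must have equal length")
        if np.any(np.diff(self.temperature) < 0):
            raise ValueError("temperature channel must be non-decreasing")
        if np.any(self.mass <= 0):
            raise ValueError("mass channel must be positive throughout")


def savitzky_golay(series, window: int, order: int) -> np.ndarray:
    """Savitzky–Golay least-squares polynomial smoothing.

    End points are handled by fitting the edge polynomial on the one-sided
    truncated window (scipy's ``mode='interp'``).  The filter is linear and
    reproduces polynomials of degree ≤ ``order`` exactly.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"window ({window}) must exceed order ({order})")
    if window > series.size:
        raise ValueError(
            f"window ({window}) exceeds series length ({series.size})"
        )
    return savgol_filter(series, window, order, mode="interp")


def conversion_from_mass(
    thermogram: Thermogram, window: tuple[float, float] = DEFAULT_WINDOW_K
) -> np.ndarray:
    """Conversion x = (m₀ − m)/(m₀ − m∞) with m₀, m∞ at the window edges.

    m₀ and m∞ are the masses interpolated at the window's start and end
    temperatures, so everything lost below the window (moisture, light
    volatiles) is excluded from x.  Tiny numerical excursions outside
    [0, 1] are clipped.
    """
    t_lo, t_hi = window
    t = thermogram.temperature
    if t_lo < t[0] - 1e-6 or t_hi > t[-1] + 1e-6:
        raise ValueError(
            f"window ({t_lo}, {t_hi}) K outside data range ({t[0]}, {t[-1]}) K"
        )
    m0 = float(np.interp(t_lo, t, thermogram.mass))
    m_inf = float(np.interp(t_hi, t, thermogram.mass))
    if abs(m0 - m_inf) < 1e-12 * m0:
        raise ValueError("no mass loss across the window (m0 == m_inf)")
    x = (m0 - thermogram.mass) / (m0 - m_inf)
    return np.clip(x, 0.0, 1.0)


def _dedupe(temperature: np.ndarray, *channels, tol: float = 1e-9):
    """Average samples whose temperatures coincide within ``tol``."""
    t = np.asarray(temperature, dtype=float)
    keys = np.concatenate([[0], np.cumsum(np.diff(t) > tol)])
    n_groups = keys[-1] + 1
    counts = np.bincount(keys, minlength=n_groups)
    t_out = np.bincount(keys, weights=t, minlength=n_groups) / counts
    outs = [
        np.bincount(keys, weights=np.asarray(c, dtype=float), minlength=n_groups)
        / counts
        for c in channels
    ]
    return (t_out, *outs)


def derivative_wrt_temperature(series, temperature) -> np.ndarray:
    """d(series)/dT by central differences on a (non-uniform) grid.

    Duplicate temperatures are merged by averaging first; one-sided
    second-order differences are used at the end points.
    """
    t = np.asarray(temperature, dtype=float)
    y = np.asarray(series, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("temperature grid must be increasing")
    if np.any(np.diff(t) <= 1e-9):
        t, y = _dedupe(t, y)
    if t.size < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("grid degenerate after de-duplication")
    return np.gradient(y, t, edge_order=2)


def truncate_window(obj, t_lo: float, t_hi: float):
    """Restrict a Thermogram or RateCurve to [t_lo, t_hi] (K).

    Boundary points within half a median grid step of the limits are kept.
    """
    if not t_lo < t_hi:
        raise ValueError(f"need t_lo < t_hi, got ({t_lo}, {t_hi})")
    t = obj.temperature
    half_step = 0.5 * float(np.median(np.diff(t))) if t.size > 1 else 0.0
    mask = (t >= t_lo - half_step) & (t <= t_hi + half_step)
    if not mask.any():
        raise ValueError("window leaves no data points")
    if isinstance(obj, Thermogram):
        return Thermogram(
            time=obj.time[mask],
            temperature=t[mask],
            mass=obj.mass[mask],
            heat_flow=obj.heat_flow[mask],
            replicate_id=obj.replicate_id,
        )
    if isinstance(obj, RateCurve):
        return replace(
            obj, temperature=t[mask], rate=obj.rate[mask], components=None
        )
    raise TypeError(f"cannot truncate object of type {type(obj).__name__}")


def average_replicates(thermograms: list[Thermogram]) -> Thermogram:
    """Point-wise mean thermogram on a common 0.5 K grid.

    Channels are linearly interpolated onto the intersection of the
    replicate temperature ranges.  Mass channels are first normalized by
    each replicate's initial mass so that runs with different sample
    loadings (10–20 mg) average comparably, then rescaled by the mean
    initial mass.
    """
    if not thermograms:
        raise ValueError("need at least one thermogram")
    t_lo = max(tg.temperature[0] for tg in thermograms)
    t_hi = min(tg.temperature[-1] for tg in thermograms)
    if t_hi - t_lo < 1.0:
        raise ValueError("replicate temperature ranges do not overlap")
    grid = np.arange(t_lo, t_hi + 1e-9, 0.5)
    if grid[-1] < t_hi - 1e-9:
        grid = np.append(grid, t_hi)

    def interp(tg, channel):
        t, y = _dedupe(tg.temperature, channel)
        return np.interp(grid, t, y)

    m0s = np.array([tg.mass[0] for tg in thermograms])
    mass_norm = np.mean([interp(tg, tg.mass) / m0 for tg, m0 in zip(thermograms, m0s)], axis=0)
    return Thermogram(
        time=np.mean([interp(tg, tg.time) for tg in thermograms], axis=0),
        temperature=grid,
        mass=mass_norm * m0s.mean(),
        heat_flow=np.mean([interp(tg, tg.heat_flow) for tg in thermograms], axis=0),
        replicate_id="mean",
    )


def dtg_curve(
    thermogram: Thermogram,
    window: tuple[float, float] = DEFAULT_WINDOW_K,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
) -> RateCurve:
    """Full DTG pipeline: smooth mass → conversion → d/dT → truncate.

    Returns dx/dT on the analysis window as a measured-provenance curve.
    """
    smoothed = replace(
        thermogram,
        mass=savitzky_golay(thermogram.mass, smooth_window, smooth_order),
    )
    x = conversion_from_mass(smoothed, window)
    dxdt = derivative_wrt_temperature(x, smoothed.temperature)
    t, y = _dedupe(smoothed.temperature, dxdt)
    curve = RateCurve(temperature=t, rate=y, source="measured")
    return truncate_window(curve, *window)


def dsc_curve(
    thermogram: Thermogram,
    window: tuple[float, float] = DEFAULT_WINDOW_K,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed, window-truncated heat flow: (temperature K, heat flow mW)."""
    hf = savitzky_golay(thermogram.heat_flow, smooth_window, smooth_order)
    t, y = _dedupe(thermogram.temperature, hf)
    curve = RateCurve(temperature=t, rate=y, source="measured")
    curve = truncate_window(curve, *window)
    return curve.temperature, curve.rate


def dsc_derivative_curve(
    thermogram: Thermogram,
    window: tuple[float, float] = DEFAULT_WINDOW_K,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
) -> RateCurve:
    """Temperature derivative of the smoothed DSC signal on the window."""
    hf = savitzky_golay(thermogram.heat_flow, smooth_window, smooth_order)
    d = derivative_wrt_temperature(hf, thermogram.temperature)
    t, y = _dedupe(thermogram.temperature, d)
    curve = RateCurve(temperature=t, rate=y, source="measured")
    return truncate_window(curve, *window)
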