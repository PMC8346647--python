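"""First-order DAEM forward model under a constant heating rate.

For a single activation energy E the conversion rate per Kelvin is

    dx/dT = (k₀/β) · exp[ −( E/(RT) + (k₀/β) ∫_{T₀}^{T} exp(−E/(RT′)) dT′ ) ]

and a pseudo-component integrates this kernel against its activation-energy
density F(E).  A sample is a mixture of pseudo-components with contribution
fractions cᵢ summing to 1:

    dx/dT = Σᵢ cᵢ · dx/dT|ᵢ ,   dx/dT|ᵢ = ∫ kernel(E) Fᵢ(E) dE .

The inner temperature integral has no elementary closed form; it is computed
by cumulative trapezoid on a refined grid (default step 0.25 K).  The
equivalent exponential-integral expression

    ∫ exp(−a/T) dT = T·exp(−a/T) − a·E₁(a/T),   a = E/R

is exposed only for cross-checking (see tests), not used in the main path.

At the rate maximum of a single first-order reaction the Kissinger condition
E·β/(R·Tp²) = k₀·exp(−E/(R·Tp)) holds; it is used to translate between peak
temperatures and activation energies (e.g. for fit initialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.special import exp1, lambertw

from .constants import DEFAULT_K0, GAS_CONSTANT, c_to_k
from .distributions import DistributionSpec, quadrature_nodes

__all__ = [
    "HeatingProgram",
    "PseudoComponent",
    "DAEMModel",
    "RateCurve",
    "default_grid",
    "temperature_integral",
    "temperature_integral_closed_form",
    "single_energy_rate",
    "component_rate",
    "mixture_rate",
    "conversion_curve",
    "peak_temperature",
    "kissinger_peak_energy",
    "kissinger_peak_temperature",
]

#: Refinement step of the inner temperature integral, K.
_INNER_STEP = 0.25

#: Exponent clip before exponentiation: graceful underflow, never non-finite.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class HeatingProgram:
    """Linear temperature program: rate β (K s⁻¹) from t_start to t_end (K)."""

    beta: float
    t_start: float = c_to_k(22.0)
    t_end: float = c_to_k(600.0)

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0 < self.t_start < self.t_end:
            raise ValueError(
                f"need 0 < t_start < t_end, got ({self.t_start}, {self.t_end})"
            )


@dataclass(frozen=True)
class PseudoComponent:
    """A reacting fraction with its own F(E) and frequency factor k₀ (s⁻¹)."""

    fraction: float
    dist: DistributionSpec
    k0: float = DEFAULT_K0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if not self.k0 > 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")


@dataclass(frozen=True)
class DAEMModel:
    """Ordered pseudo-components plus the heating program they run under."""

    components: tuple[PseudoComponent, ...]
    program: HeatingProgram

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("a DAEM model needs at least one pseudo-component")
        total = sum(c.fraction for c in comps)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"component fractions must sum to 1, got {total!r}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.fraction for c in self.components])


@dataclass
class RateCurve:
    """dx/dT (K⁻¹) on a strictly increasing temperature grid (K).

    ``components`` optionally carries the fraction-weighted per-component
    curves cᵢ·dx/dT|ᵢ of a mixture; they sum to ``rate``.
    """

    temperature: np.ndarray
    rate: np.ndarray
    source: str = "simulated"
    components: list["RateCurve"] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.temperature.shape != self.rate.shape:
            raise ValueError("temperature and rate must have equal length")
        if self.temperature.size >= 2 and not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.source not in ("measured", "simulated"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "simulated" and np.any(self.rate < -1e-9):
            raise ValueError("simulated rates must be non-negative")

    def total_conversion(self) -> float:
        """Trapezoid integral of the rate over the grid."""
        return float(np.trapezoid(self.rate, self.temperature))


def default_grid(t_lo_c: float = 200.0, t_hi_c: float = 600.0, step_k: float = 0.5) -> np.ndarray:
    """Analysis temperature grid in K (defaults: 200–600 °C at 0.5 K)."""
    n = int(round((t_hi_c - t_lo_c) / step_k)) + 1
    return c_to_k(t_lo_c) + step_k * np.arange(n)


#: Small cache of refined grids keyed by (t0, id of the output grid bytes);
#: fitting re-evaluates on one fixed grid thousands of times.
_GRID_CACHE: dict = {}
_GRID_CACHE_MAX = 8


def _refined_grid(t0: float, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """≤0.25 K-step ramp from t0 merged with ``t``; returns (grid, idx of t)."""
    key = (round(t0, 9), t.tobytes())
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    t_max = float(t[-1])
    n = max(int(np.ceil((t_max - t0) / _INNER_STEP)) + 1, 2)
    ramp = np.linspace(t0, t_max, n)
    tr = np.union1d(ramp, t)
    idx = np.searchsorted(tr, t)
    if len(_GRID_CACHE) >= _GRID_CACHE_MAX:
        _GRID_CACHE.clear()
    _GRID_CACHE[key] = (tr, idx)
    return tr, idx


def _psi_matrix(e_arr: np.ndarray, t0: float, t: np.ndarray) -> np.ndarray:
    """Rows of ∫_{t0}^{t} exp(−E/(R·T′)) dT′ for each energy (trapezoid)."""
    tr, idx = _refined_grid(t0, t)
    expo = -e_arr[:, None] / (GAS_CONSTANT * tr[None, :])
    integrand = np.exp(np.clip(expo, -_EXP_CLIP, 0.0))
    seg = 0.5 * (integrand[:, 1:] + integrand[:, :-1]) * np.diff(tr)[None, :]
    psi = np.empty_like(integrand)
    psi[:, 0] = 0.0
    np.cumsum(seg, axis=1, out=psi[:, 1:])
    return psi[:, idx]


def temperature_integral(e, t0: float, t: np.ndarray) -> np.ndarray:
    """Cumulative ∫_{t0}^{t} exp(−E/(R·T′)) dT′ on the grid ``t`` (K units).

    ``e`` may be a scalar (returns shape ``t.shape``) or a 1-D array of
    energies (returns shape ``(len(e), len(t))``).  Non-decreasing in t.
    """
    t = np.asarray(t, dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    if t[0] < t0 - 1e-9:
        raise ValueError(f"grid starts at {t[0]} K, below t0={t0} K")
    e_arr = np.atleast_1d(np.asarray(e, dtype=float))
    if np.any(e_arr < 0):
        raise ValueError("activation energies must be non-negative")
    out = _psi_matrix(e_arr, t0, t)
    return out[0] if np.isscalar(e) or np.ndim(e) == 0 else out


def temperature_integral_closed_form(e: float, t0: float, t) -> np.ndarray:
    """Exponential-integral form of the temperature integral (oracle only).

    ∫_{t0}^{t} exp(−a/T′) dT′ = [T′·e^{−a/T′} − a·E₁(a/T′)]_{t0}^{t}, a = E/R.
    """
    t = np.asarray(t, dtype=float)
    if e == 0:
        return t - t0
    a = e / GAS_CONSTANT

    def antider(tt):
        u = a / tt
        return tt * np.exp(-u) - a * exp1(u)

    return antider(t) - antider(t0)


def _rate_matrix(
    e: np.ndarray, k0: float, program: HeatingProgram, t: np.ndarray
) -> np.ndarray:
    """dx/dT kernel rows for each energy in ``e`` on the grid ``t``."""
    t = np.asarray(t, dtype=float)
    e = np.atleast_1d(np.asarray(e, dtype=float))
    psi = _psi_matrix(e, program.t_start, t)
    kob = k0 / program.beta
    expo = -(e[:, None] / (GAS_CONSTANT * t[None, :]) + kob * psi)
    return kob * np.exp(np.clip(expo, -_EXP_CLIP, _EXP_CLIP))


def single_energy_rate(
    e: float, k0: float, program: HeatingProgram, t: np.ndarray
) -> np.ndarray:
    """Conversion rate dx/dT of a single first-order reaction at energy E."""
    return _rate_matrix(e, k0, program, t)[0]


def component_rate(
    comp: PseudoComponent,
    program: HeatingProgram,
    t: np.ndarray,
    n_nodes: int = 201,
    coverage: float | None = None,
) -> RateCurve:
    """Unweighted dx/dT|ᵢ of one pseudo-component (quadrature over F(E))."""
    nodes, weights = quadrature_nodes(comp.dist, n=n_nodes, coverage=coverage)
    rates = _rate_matrix(nodes, comp.k0, program, t)
    return RateCurve(temperature=np.asarray(t, dtype=float), rate=weights @ rates)


def mixture_rate(
    model: DAEMModel,
    t: np.ndarray,
    n_nodes: int = 201,
) -> RateCurve:
    """Fraction-weighted mixture dx/dT with per-component curves attached.

    Components sharing one k₀ are evaluated in a single batched kernel
    matrix (one refined-grid pass for all their quadrature nodes).
    """
    t = np.asarray(t, dtype=float)
    n_comp = len(model.components)
    rates: list[np.ndarray | None] = [None] * n_comp

    by_k0: dict[float, list[int]] = {}
    for i, comp in enumerate(model.components):
        by_k0.setdefault(comp.k0, []).append(i)
    for k0, idxs in by_k0.items():
        nodes_list, weights_list = [], []
        for i in idxs:
            nodes, weights = quadrature_nodes(model.components[i].dist, n=n_nodes)
            nodes_list.append(nodes)
            weights_list.append(weights)
        kernel = _rate_matrix(np.concatenate(nodes_list), k0, model.program, t)
        row = 0
        for i, weights in zip(idxs, weights_list):
            block = kernel[row : row + weights.size]
            rates[i] = weights @ block
            row += weights.size

    parts = [
        RateCurve(temperature=t, rate=comp.fraction * rates[i])
        for i, comp in enumerate(model.components)
    ]
    total = np.sum([p.rate for p in parts], axis=0)
    return RateCurve(temperature=t, rate=total, components=parts)


def conversion_curve(curve: RateCurve) -> np.ndarray:
    """Cumulative conversion x(T): trapezoid integral of dx/dT, starts at 0."""
    return cumulative_trapezoid(curve.rate, curve.temperature, initial=0.0)


def peak_temperature(curve: RateCurve) -> float:
    """Temperature of the rate maximum, K, refined by 3-point parabola.

    Raises ``ValueError`` for curves with no peak (flat within numerical
    tolerance) or fewer than 5 points.
    """
    t, y = curve.temperature, curve.rate
    if t.size < 5:
        raise ValueError("need at least 5 points to locate a peak")
    span = float(y.max() - y.min())
    if span <= 1e-300 or span < 1e-12 * max(abs(float(y.max())), 1e-300):
        raise ValueError("curve is flat; no peak to locate")
    i = int(np.argmax(y))
    if i == 0 or i == t.size - 1:
        return float(t[i])
    a, b, c = np.polyfit(t[i - 1 : i + 2] - t[i], y[i - 1 : i + 2], 2)
    if a >= 0:
        return float(t[i])
    return float(t[i] - b / (2.0 * a))


def kissinger_peak_energy(tp: float, k0: float, beta: float) -> float:
    """Activation energy whose single-reaction rate peaks at ``tp`` (K).

    Solves E·β/(R·Tp²) = k₀·exp(−E/(R·Tp)): with u = E/(R·Tp) this is
    u·eᵘ = k₀·Tp/β, so u = W(k₀·Tp/β) on the principal Lambert branch.
    """
    u = float(np.real(lambertw(k0 * tp / beta)))
    return u * GAS_CONSTANT * tp


def kissinger_peak_temperature(
    e: float, k0: float, beta: float, bracket: tuple[float, float] = (150.0, 3000.0)
) -> float:
    """Peak temperature (K) of a single first-order reaction at energy E."""

    def g(t):
        return e * beta / (GAS_CONSTANT * t * t) - k0 * np.exp(
            -e / (GAS_CONSTANT * t)
        )

    return float(brentq(g, *bracket))
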