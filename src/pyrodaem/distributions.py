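"""Activation-energy distribution families for the DAEM.

The distributed activation energy model treats a decomposing pseudo-component
as a continuum of parallel first-order reactions whose activation energies E
follow a probability density F(E).  Four families are supported — Gaussian,
Logistic, Gumbel and Cauchy — parameterized by a location Ē (mean activation
energy) and a scale σ, both in J mol⁻¹.

At equal (Ē, σ) the families differ in peak height and tail weight: the
Gaussian has the tallest mode, 1/(σ√(2π)), followed by the Cauchy 1/(πσ),
the Gumbel 1/(eσ) and the Logistic 1/(4σ).  The Gumbel is the only
asymmetric family (right-skewed).  These contrasts are what make family
choice meaningful when deconvolving overlapping decomposition stages.

This module also provides the numerical plumbing for the outer energy
integral of the DAEM: truncated support selection from the quantile
function, and equally spaced trapezoid quadrature nodes on that support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "DEGENERATE_SIGMA",
    "ENERGY_FLOOR",
    "DistributionSpec",
    "DegenerateDistributionError",
    "density",
    "mode_height",
    "matched_sigma",
    "support_bounds",
    "quadrature_nodes",
]

FAMILIES = ("gaussian", "logistic", "gumbel", "cauchy")

#: Scale below which a family is treated as a delta function, J mol⁻¹.
DEGENERATE_SIGMA = 1.0

#: Physical lower bound for activation energies, J mol⁻¹ (1 kJ mol⁻¹):
#: negative or near-zero activation energies are unphysical for pyrolysis.
ENERGY_FLOOR = 1e3

#: Default truncation coverage per family.  The Cauchy has no finite
#: variance, and 201 equally spaced nodes cannot resolve its centre over a
#: near-total-coverage interval, so it is truncated much more aggressively
#: (±tan(0.49π) ≈ ±31.8σ) and the weights renormalized.
_DEFAULT_COVERAGE = {
    "gaussian": 0.9999,
    "logistic": 0.9999,
    "gumbel": 0.9999,
    "cauchy": 0.98,
}

_SQRT_2PI = np.sqrt(2.0 * np.pi)


class DegenerateDistributionError(ValueError):
    """Raised when a density is requested for a (near-)zero scale.

    Callers must take the delta-function path instead (a single energy
    node at Ē with unit weight, see :func:`quadrature_nodes`).
    """


@dataclass(frozen=True)
class DistributionSpec:
    """One activation-energy distribution: family tag, Ē and σ in J mol⁻¹."""

    family: str
    e_mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.e_mean > 0:
            raise ValueError(f"e_mean must be positive, got {self.e_mean}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def is_degenerate(self) -> bool:
        """True when σ is below the delta-function threshold."""
        return self.sigma < DEGENERATE_SIGMA


def _frozen(spec: DistributionSpec):
    """scipy.stats frozen distribution matching the family."""
    cls = {
        "gaussian": stats.norm,
        "logistic": stats.logistic,
        "gumbel": stats.gumbel_r,
        "cauchy": stats.cauchy,
    }[spec.family]
    return cls(loc=spec.e_mean, scale=spec.sigma)


def density(spec: DistributionSpec, e) -> np.ndarray:
    """Evaluate F(E) at energies ``e`` (J mol⁻¹), vectorized.

    Gaussian:  F(E) = exp(−z²/2) / (σ√(2π))
    Logistic:  F(E) = sech²(z/2) / (4σ)
    Gumbel:    F(E) = exp(−(z + exp(−z))) / σ
    Cauchy:    F(E) = 1 / (πσ(1 + z²))

    with z = (E − Ē)/σ.  Raises :class:`DegenerateDistributionError` for
    σ below the delta threshold.
    """
    if spec.is_degenerate:
        raise DegenerateDistributionError(
            f"sigma={spec.sigma} J/mol is below the delta threshold "
            f"({DEGENERATE_SIGMA} J/mol); use the single-energy path"
        )
    e = np.asarray(e, dtype=float)
    z = (e - spec.e_mean) / spec.sigma
    if spec.family == "gaussian":
        # z² capped at 1400 → exp underflows to 0, never overflows
        out = np.exp(-0.5 * np.minimum(z * z, 1400.0)) / (spec.sigma * _SQRT_2PI)
    elif spec.family == "logistic":
        # sech(u) = 2 e^{-|u|} / (1 + e^{-2|u|}): overflow-safe for large |z|
        u = np.abs(z / 2.0)
        sech = 2.0 * np.exp(-u) / (1.0 + np.exp(-2.0 * u))
        out = sech * sech / (4.0 * spec.sigma)
    elif spec.family == "gumbel":
        # z < −35 → true density exp(−e^{35}) underflows; the clip keeps
        # exp(−z) finite while preserving the underflow-to-zero result
        zc = np.clip(z, -35.0, 700.0)
        out = np.exp(-(zc + np.exp(-zc))) / spec.sigma
    else:  # cauchy: polynomial tails must never be clipped
        out = 1.0 / (np.pi * spec.sigma * (1.0 + z * z))
    return out


def mode_height(spec: DistributionSpec) -> float:
    """Density at the family's mode (closed form)."""
    s = spec.sigma
    return {
        "gaussian": 1.0 / (s * _SQRT_2PI),
        "logistic": 1.0 / (4.0 * s),
        "gumbel": 1.0 / (np.e * s),
        "cauchy": 1.0 / (np.pi * s),
    }[spec.family]


def matched_sigma(family: str, sigma_gaussian: float) -> float:
    """Scale that equalizes a family's mode height with a Gaussian's.

    Setting 1/(c_f·σ_f) = 1/(σ_g√(2π)) gives σ_f = σ_g·√(2π)/c_f with
    c_f ∈ {√(2π), 4, e, π}.  Used to compare family shapes at equal peak.
    """
    c = {"gaussian": _SQRT_2PI, "logistic": 4.0, "gumbel": np.e, "cauchy": np.pi}[family]
    return sigma_gaussian * _SQRT_2PI / c


def support_bounds(
    spec: DistributionSpec, coverage: float
) -> tuple[float, float]:
    """Interval holding at least ``coverage`` of the density's mass.

    Computed from the family's quantile function with equal tail mass on
    both sides; the lower edge is clamped to the physical floor of
    1 kJ mol⁻¹.  For a degenerate σ the interval collapses to Ē.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    if spec.is_degenerate:
        return (spec.e_mean, spec.e_mean)
    tail = (1.0 - coverage) / 2.0
    dist = _frozen(spec)
    e_lo = max(float(dist.ppf(tail)), ENERGY_FLOOR)
    e_hi = float(dist.ppf(1.0 - tail))
    return (e_lo, e_hi)


def quadrature_nodes(
    spec: DistributionSpec,
    n: int = 201,
    coverage: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced nodes with trapezoid weights on the truncated support.

    Weights are density × step (halved at the end points) and renormalized
    to sum to exactly 1, so the truncated family integrates like a proper
    probability density.  A degenerate σ yields a single node (Ē, 1.0).
    """
    if spec.is_degenerate:
        return np.array([spec.e_mean]), np.array([1.0])
    if n < 3:
        raise ValueError(f"need at least 3 quadrature nodes, got {n}")
    if coverage is None:
        coverage = _DEFAULT_COVERAGE[spec.family]
    e_lo, e_hi = support_bounds(spec, coverage)
    nodes = np.linspace(e_lo, e_hi, n)
    step = nodes[1] - nodes[0]
    weights = density(spec, nodes) * step
    weights[0] *= 0.5
    weights[-1] *= 0.5
    weights /= weights.sum()
    return nodes, weights
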