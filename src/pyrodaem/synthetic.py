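"""Synthetic TGA/DSC thermogram generator and printed-parameter fixtures.

Generates thermograms with the statistical structure the analysis assumes:
a mass channel following DAEM mixture kinetics, a heat-flow channel built
from the per-component conversion rates with configurable reaction-enthalpy
signs (exothermic positive), plus seeded instrument noise and a slow linear
DSC baseline drift.  Heat-flow magnitudes are arbitrary units: DSC is used
qualitatively (sign structure and event location), never calorimetrically.

The fixtures encode the published slow-pyrolysis kinetics of two model
feedstocks at 5 °C min⁻¹, 22–600 °C, k₀ = 1.67 × 10¹³ s⁻¹:

* cellulose — a single Gaussian pseudo-component (Ē = 178.6488 kJ mol⁻¹,
  σ = 1.6320 kJ mol⁻¹), decomposing endothermically with one DTG peak
  near 330 °C;
* lignin — four pseudo-components per family (Gaussian/Logistic/Gumbel/
  Cauchy parameter sets), with DTG structure near 260/310/372 °C plus a
  broad char-decomposition stage near 425 °C, components 1 and 4
  endothermic-leaning and 2 and 3 exothermic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_K0, c_to_k, kj_to_j
from .daem import DAEMModel, HeatingProgram, PseudoComponent, conversion_curve, mixture_rate
from .distributions import DistributionSpec
from .preprocessing import Thermogram

__all__ = [
    "NoiseSpec",
    "EnthalpyProfile",
    "simulate_thermogram",
    "cellulose_fixture",
    "lignin_fixture",
    "replicate_pair",
    "LIGNIN_PARAMETERS",
    "CELLULOSE_PARAMETERS",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument-noise settings for the generator.

    mass_noise_sd is a fraction of the initial mass; heatflow_noise_sd is
    in mW; baseline_drift is mW per 100 K, linear in temperature.
    Defaults are mild — enough to exercise smoothing without burying minor
    DTG peaks.
    """

    mass_noise_sd: float = 0.001
    heatflow_noise_sd: float = 0.01
    baseline_drift: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_noise_sd < 0 or self.heatflow_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @staticmethod
    def none(seed: int = 0) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, seed)


@dataclass(frozen=True)
class EnthalpyProfile:
    """Per-component reaction-enthalpy sign and magnitude (arbitrary units)."""

    signs: tuple[str, ...]
    magnitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.magnitudes):
            raise ValueError("signs and magnitudes must have equal length")
        for s in self.signs:
            if s not in ("endo", "exo"):
                raise ValueError(f"sign must be 'endo' or 'exo', got {s!r}")
        if any(m < 0 for m in self.magnitudes):
            raise ValueError("magnitudes must be non-negative")

    @property
    def signed_magnitudes(self) -> np.ndarray:
        return np.array(
            [m if s == "exo" else -m for s, m in zip(self.signs, self.magnitudes)]
        )


# Published kinetic parameters (kJ mol⁻¹) per distribution family.
CELLULOSE_PARAMETERS = {
    "gaussian": {"c": (1.0,), "e": (178.6488,), "sigma": (1.6320,)},
    "logistic": {"c": (1.0,), "e": (182.2636,), "sigma": (2.7686,)},
    "gumbel": {"c": (1.0,), "e": (177.8279,), "sigma": (1.6634,)},
    "cauchy": {"c": (1.0,), "e": (178.2789,), "sigma": (0.0052,)},
}

LIGNIN_PARAMETERS = {
    "gaussian": {
        "c": (0.4070, 0.4312, 0.0599, 0.1019),
        "e": (174.6626, 211.1543, 157.4708, 192.7969),
        "sigma": (4.6001, 22.6944, 0.0126, 2.6252),
    },
    "logistic": {
        "c": (0.1967, 0.4999, 0.0211, 0.2823),
        "e": (174.3412, 265.3994, 157.6159, 194.1333),
        "sigma": (1.3342, 50.6039, 0.0392, 6.8136),
    },
    "gumbel": {
        "c": (0.4832, 0.3696, 0.0705, 0.0767),
        "e": (173.5402, 209.1221, 157.5433, 193.2413),
        "sigma": (4.8764, 17.0193, 0.6483, 0.0002),
    },
    "cauchy": {
        "c": (0.5021, 0.2235, 0.0396, 0.2348),
        "e": (174.6224, 216.9202, 157.6159, 193.4639),
        "sigma": (3.5543, 8.6365, 0.0023, 4.9539),
    },
}

#: Component order of the lignin parameter sets: 1st ≈ 310 °C stage,
#: 2nd ≈ 425 °C char stage, 3rd ≈ 260 °C, 4th ≈ 372 °C.
#: Magnitudes are qualitative (arbitrary units), chosen so each stage is a
#: discernible DSC fluctuation: first-stage dip, broad char hump, sharp
#: third-stage rise, pronounced fourth-stage dip riding on the hump.
_LIGNIN_SIGNS = ("endo", "exo", "exo", "endo")
_LIGNIN_MAGNITUDES = (1200.0, 800.0, 2400.0, 3000.0)


def _default_program() -> HeatingProgram:
    return HeatingProgram(beta=5.0 / 60.0, t_start=c_to_k(22.0), t_end=c_to_k(600.0))


def _model_from_table(params: dict, family: str) -> DAEMModel:
    comps = tuple(
        PseudoComponent(
            fraction=c,
            dist=DistributionSpec(family, kj_to_j(e), kj_to_j(s)),
            k0=DEFAULT_K0,
        )
        for c, e, s in zip(params["c"], params["e"], params["sigma"])
    )
    return DAEMModel(components=comps, program=_default_program())


def cellulose_fixture(family: str = "gaussian") -> tuple[DAEMModel, EnthalpyProfile]:
    """Single-component cellulose model plus its endothermic enthalpy profile."""
    model = _model_from_table(CELLULOSE_PARAMETERS[family], family)
    return model, EnthalpyProfile(signs=("endo",), magnitudes=(1200.0,))


def lignin_fixture(family: str = "gaussian") -> tuple[DAEMModel, EnthalpyProfile]:
    """Four-component lignin model plus its mixed-sign enthalpy profile."""
    if family not in LIGNIN_PARAMETERS:
        raise ValueError(f"unknown family {family!r}")
    model = _model_from_table(LIGNIN_PARAMETERS[family], family)
    return model, EnthalpyProfile(signs=_LIGNIN_SIGNS, magnitudes=_LIGNIN_MAGNITUDES)


def simulate_thermogram(
    model: DAEMModel,
    m0: float,
    m_inf: float,
    enthalpy: EnthalpyProfile,
    noise: NoiseSpec,
    step_k: float = 0.5,
    replicate_id: str = "r1",
) -> Thermogram:
    """Simulate one TGA/DSC run of ``model`` over its heating program.

    mass(T)      = m₀ − (m₀ − m∞)·x(T) + ε_mass
    heat_flow(T) = β·Σᵢ signᵢ·magᵢ·cᵢ·(dx/dT|ᵢ) + drift·(T−T₀)/100 + ε_hf

    Deterministic for a given ``noise.seed``.
    """
    if not m0 > m_inf > 0:
        raise ValueError(f"need m0 > m_inf > 0, got ({m0}, {m_inf})")
    if len(enthalpy.signs) != len(model.components):
        raise ValueError("enthalpy profile must have one entry per component")
    program = model.program
    n = int(round((program.t_end - program.t_start) / step_k)) + 1
    t = program.t_start + step_k * np.arange(n)

    mix = mixture_rate(model, t)
    x = conversion_curve(mix)
    rng = np.random.default_rng(noise.seed)

    mass = m0 - (m0 - m_inf) * x
    mass = mass + rng.normal(0.0, noise.mass_noise_sd * m0, size=n) if noise.mass_noise_sd > 0 else mass

    signed = enthalpy.signed_magnitudes
    heat_flow = program.beta * sum(
        sm * part.rate for sm, part in zip(signed, mix.components)
    )
    heat_flow = heat_flow + noise.baseline_drift * (t - t[0]) / 100.0
    if noise.heatflow_noise_sd > 0:
        heat_flow = heat_flow + rng.normal(0.0, noise.heatflow_noise_sd, size=n)

    return Thermogram(
        time=(t - t[0]) / program.beta,
        temperature=t,
        mass=mass,
        heat_flow=np.asarray(heat_flow, dtype=float),
        replicate_id=replicate_id,
    )


def replicate_pair(
    model: DAEMModel,
    m0: float,
    m_inf: float,
    enthalpy: EnthalpyProfile,
    noise: NoiseSpec,
) -> list[Thermogram]:
    """Two noisy replicates of one experiment (different sub-seeds)."""
    return [
        simulate_thermogram(
            model,
            m0 * scale,
            m_inf * scale,
            enthalpy,
            NoiseSpec(
                noise.mass_noise_sd,
                noise.heatflow_noise_sd,
                noise.baseline_drift,
                seed=noise.seed * 2 + k,
            ),
            replicate_id=f"r{k + 1}",
        )
        for k, scale in enumerate((1.0, 1.15))
    ]
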