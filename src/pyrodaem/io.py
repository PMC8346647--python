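"""File formats, run configuration and pipeline orchestration.

Thermograms travel as comma-delimited text with unit-bearing headers
(time_s, temperature_C, mass_mg, heat_flow_mW, optional replicate_id);
rate curves as (temperature_C, dx_dT_perK, component_* columns).  All
user-facing temperatures are °C; everything internal is Kelvin.

``run_pipeline`` ties the stages together: read → average replicates →
DTG/DSC preprocessing → optional component-count suggestion → fit or scan
→ parameter/curve reports and a deconvolution plot.  Every artifact is
stamped with a hash of the configuration and the seed so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import c_to_k, k_to_c
from .daem import RateCurve, peak_temperature
from .fitting import (
    FitConfig,
    FitResult,
    fit_daem,
    model_scan,
    suggest_component_count,
)
from .preprocessing import (
    DEFAULT_SMOOTH_ORDER,
    DEFAULT_SMOOTH_WINDOW,
    Thermogram,
    average_replicates,
    dsc_derivative_curve,
    dtg_curve,
)

__all__ = [
    "ThermogramParseError",
    "RunConfig",
    "read_thermogram",
    "read_thermograms",
    "write_thermogram",
    "read_rate_curve",
    "write_rate_curve",
    "write_fit_report",
    "plot_fit",
    "run_pipeline",
]

log = logging.getLogger("pyrodaem")

_REQUIRED_COLUMNS = ("time_s", "temperature_C", "mass_mg", "heat_flow_mW")


class ThermogramParseError(ValueError):
    """Malformed thermogram file (missing column, bad cell, bad grid)."""


def _load_frame(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"thermogram file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ThermogramParseError(f"{path}: file is empty") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ThermogramParseError(f"{path}: missing column(s) {missing}")
    for col in _REQUIRED_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna() & frame[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ThermogramParseError(
                f"{path}: non-numeric value in column {col!r} "
                f"at line {bad[0] + 2}"
            )
        if values.isna().any():
            raise ThermogramParseError(
                f"{path}: empty cell in column {col!r} "
                f"at line {values.index[values.isna()][0] + 2}"
            )
        frame[col] = values
    return frame


def _frame_to_thermogram(frame: pd.DataFrame, replicate_id: str, origin) -> Thermogram:
    t = c_to_k(frame["temperature_C"].to_numpy())
    if np.any(np.diff(t) < -1e-9):
        raise ThermogramParseError(
            f"{origin}: temperature column is not non-decreasing"
        )
    try:
        return Thermogram(
            time=frame["time_s"].to_numpy(),
            temperature=t,
            mass=frame["mass_mg"].to_numpy(),
            heat_flow=frame["heat_flow_mW"].to_numpy(),
            replicate_id=replicate_id,
        )
    except ValueError as exc:
        raise ThermogramParseError(f"{origin}: {exc}") from exc


def read_thermograms(path) -> list[Thermogram]:
    """Read a thermogram file, one Thermogram per replicate_id group."""
    frame = _load_frame(path)
    if "replicate_id" not in frame.columns:
        return [_frame_to_thermogram(frame, "r1", path)]
    out = []
    for rid, group in frame.groupby("replicate_id", sort=True):
        out.append(_frame_to_thermogram(group.reset_index(drop=True), str(rid), path))
    return out


def read_thermogram(path) -> Thermogram:
    """Read a single-replicate thermogram file."""
    runs = read_thermograms(path)
    if len(runs) != 1:
        raise ThermogramParseError(
            f"{path}: expected a single replicate, found {len(runs)}; "
            "use read_thermograms()"
        )
    return runs[0]


def write_thermogram(thermograms, path) -> None:
    """Write one Thermogram (or a list of replicates) as delimited text."""
    if isinstance(thermograms, Thermogram):
        thermograms = [thermograms]
    frames = []
    for tg in thermograms:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tg.time,
                    "temperature_C": k_to_c(tg.temperature),
                    "mass_mg": tg.mass,
                    "heat_flow_mW": tg.heat_flow,
                    "replicate_id": tg.replicate_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_rate_curve(curve: RateCurve, path) -> None:
    """Write a rate curve (and any per-component columns) as CSV."""
    data = {
        "temperature_C": k_to_c(curve.temperature),
        "dx_dT_perK": curve.rate,
    }
    if curve.components:
        for i, part in enumerate(curve.components, start=1):
            data[f"component_{i}_perK"] = part.rate
    pd.DataFrame(data).to_csv(path, index=False)


def read_rate_curve(path, source: str = "measured") -> RateCurve:
    """Read a rate curve written by :func:`write_rate_curve`."""
    frame = pd.read_csv(path)
    for col in ("temperature_C", "dx_dT_perK"):
        if col not in frame.columns:
            raise ThermogramParseError(f"{path}: missing column {col!r}")
    return RateCurve(
        temperature=c_to_k(frame["temperature_C"].to_numpy()),
        rate=frame["dx_dT_perK"].to_numpy(),
        source=source,
    )


@dataclass
class RunConfig:
    """Whole-pipeline configuration (user units: °C, kJ mol⁻¹)."""

    inputs: list[str]
    window_C: tuple[float, float] = (200.0, 600.0)
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    smooth_order: int = DEFAULT_SMOOTH_ORDER
    n_components: int = 1
    family: str = "gaussian"
    scan: bool = False
    scan_n: tuple[int, ...] = (1, 2, 3, 4)
    scan_families: tuple[str, ...] = ("gaussian",)
    suggest: bool = True
    k0: float = 1.67e13
    beta_C_per_min: float = 5.0
    max_restarts: int = 3
    outdir: str = "daem_out"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not self.window_C[0] < self.window_C[1]:
            raise ValueError("analysis window must be ordered")

    @staticmethod
    def from_yaml(path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("window_C", "scan_n", "scan_families"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (not outdir/verbosity)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        payload.pop("verbosity", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _fit_config(config: RunConfig) -> FitConfig:
    from .daem import HeatingProgram

    program = HeatingProgram(beta=config.beta_C_per_min / 60.0)
    return FitConfig(
        n_components=config.n_components,
        family=config.family,
        k0=config.k0,
        program=program,
        seed=config.seed,
        max_restarts=config.max_restarts,
    )


def plot_fit(data: RateCurve, result: FitResult, path) -> None:
    """Deconvolution plot: experimental points, fitted mixture, components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    t_c = k_to_c(data.temperature)
    ax.plot(t_c, data.rate, ".", ms=2, color="0.4", label="experimental")
    sim_total = sum(p.rate for p in result.per_component_curves)
    ax.plot(t_c, sim_total, "-", color="crimson", lw=1.5, label="fitted mixture")
    for i, part in enumerate(result.per_component_curves, start=1):
        ax.plot(t_c, part.rate, "--", lw=1.0, label=f"component {i}")
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("dx/dT (K$^{-1}$)")
    ax.legend(fontsize=8)
    ax.set_title(f"{result.family} DAEM, R² = {result.r_squared:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> int:
    """Execute the full analysis; returns 0 on success.

    Artifacts written to ``config.outdir``: parameters.csv, dtg.csv,
    fit_curves.csv, fit.png, suggestion.csv (if enabled), run.json.
    """
    logging.basicConfig(level=config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    stage = "read"
    try:
        runs: list[Thermogram] = []
        for path in config.inputs:
            runs.extend(read_thermograms(path))
        log.info("read %d replicate run(s) from %d file(s)", len(runs), len(config.inputs))

        stage = "preprocess"
        mean_run = average_replicates(runs) if len(runs) > 1 else runs[0]
        window_k = (c_to_k(config.window_C[0]), c_to_k(config.window_C[1]))
        dtg = dtg_curve(mean_run, window_k, config.smooth_window, config.smooth_order)
        write_rate_curve(dtg, outdir / "dtg.csv")
        log.info("DTG peak at %.1f °C", k_to_c(peak_temperature(dtg)))

        if config.suggest:
            stage = "suggest"
            dscd = dsc_derivative_curve(
                mean_run, window_k, config.smooth_window, config.smooth_order
            )
            count, report = suggest_component_count(dtg, dscd)
            report.to_csv(outdir / "suggestion.csv", index=False)
            log.info("DTG/DSC concordance suggests %d pseudo-component(s)", count)

        stage = "fit"
        base = _fit_config(config)
        if config.scan:
            scan = model_scan(dtg, config.scan_n, config.scan_families, base)
            scan.table().to_csv(outdir / "scan.csv", index=False)
            (_, result) = scan.best()
        else:
            result = fit_daem(dtg, base)
        table = result.parameters_table()
        table.insert(0, "config_hash", stamp["config_hash"])
        table.insert(1, "seed", stamp["seed"])
        table.to_csv(outdir / "parameters.csv", index=False)

        stage = "report"
        sim = RateCurve(
            dtg.temperature,
            sum(p.rate for p in result.per_component_curves),
            source="simulated",
            components=result.per_component_curves,
        )
        write_rate_curve(sim, outdir / "fit_curves.csv")
        plot_fit(dtg, result, outdir / "fit.png")
        with open(outdir / "run.json", "w") as fh:
            json.dump(
                {
                    **stamp,
                    "r_squared": result.r_squared,
                    "converged": result.converged,
                    "n_evaluations": result.n_evaluations,
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        return 1
    return 0
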