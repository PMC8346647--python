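"""Parameter estimation, model scanning, and DTG/DSC concordance."""

import numpy as np
import pytest

from pyrodaem.constants import c_to_k, kj_to_j
from pyrodaem.daem import (
    DAEMModel,
    HeatingProgram,
    PseudoComponent,
    RateCurve,
    default_grid,
    mixture_rate,
    single_energy_rate,
)
from pyrodaem.distributions import FAMILIES, DistributionSpec
from pyrodaem.fitting import (
    FitConfig,
    _encode,
    classify_thermal_event,
    fit_daem,
    initialize_from_peaks,
    model_scan,
    r_squared,
    residual_vector,
    suggest_component_count,
)
from pyrodaem.preprocessing import dsc_curve, dsc_derivative_curve, dtg_curve
from pyrodaem.synthetic import (
    NoiseSpec,
    cellulose_fixture,
    lignin_fixture,
    simulate_thermogram,
)

BETA = 5.0 / 60.0
PROGRAM = HeatingProgram(beta=BETA)


def one_component_curve(family, e_j, sigma_j, grid):
    model = DAEMModel(
        (PseudoComponent(1.0, DistributionSpec(family, e_j, sigma_j)),), PROGRAM
    )
    return RateCurve(grid, mixture_rate(model, grid).rate, source="measured")


@pytest.fixture(scope="module")
def two_component_curve(grid):
    model = DAEMModel(
        (
            PseudoComponent(0.5, DistributionSpec("gaussian", 165e3, 3e3)),
            PseudoComponent(0.5, DistributionSpec("gaussian", 195e3, 5e3)),
        ),
        PROGRAM,
    )
    return RateCurve(grid, mixture_rate(model, grid).rate, source="measured")


class TestResidualAndR2:
    def test_self_residual_is_numerically_zero(self, cellulose_model, cellulose_curve):
        comp = cellulose_model.components[0]
        theta = _encode(
            np.array([comp.dist.e_mean]),
            np.array([comp.dist.sigma]),
            np.array([1.0]),
        )
        res = residual_vector(theta, cellulose_curve, FitConfig(n_components=1))
        assert np.max(np.abs(res)) < 1e-6 * cellulose_curve.rate.max()

    def test_sum_of_squares_matches_naive_loop(self, cellulose_curve):
        theta = _encode(np.array([160e3]), np.array([2e3]), np.array([1.0]))
        res = residual_vector(theta, cellulose_curve, FitConfig(n_components=1))
        naive = 0.0
        for r in res:
            naive += r * r
        assert float(res @ res) == pytest.approx(naive, rel=1e-12)

    def test_r_squared_extremes(self, cellulose_curve):
        assert r_squared(cellulose_curve, cellulose_curve) == pytest.approx(1.0)
        mean_curve = RateCurve(
            cellulose_curve.temperature,
            np.full_like(cellulose_curve.rate, cellulose_curve.rate.mean()),
        )
        assert r_squared(cellulose_curve, mean_curve) == pytest.approx(0.0, abs=1e-12)

    def test_r_squared_matches_longhand_five_points(self):
        t = np.array([500.0, 501.0, 502.0, 503.0, 504.0])
        y = RateCurve(t, np.array([1.0, 3.0, 2.0, 5.0, 4.0]), source="measured")
        f = RateCurve(t, np.array([1.5, 2.5, 2.5, 4.5, 4.0]), source="measured")
        # SS_res = .25+.25+.25+.25+0 = 1.0 ; mean y = 3, SS_tot = 4+0+1+4+1 = 10
        assert r_squared(y, f) == pytest.approx(1.0 - 1.0 / 10.0, rel=1e-12)

    def test_zero_variance_rejected(self):
        t = np.linspace(500.0, 600.0, 20)
        flat = RateCurve(t, np.ones(20), source="measured")
        with pytest.raises(ValueError):
            r_squared(flat, flat)


class TestInitialization:
    def test_single_energy_peak_inverts_to_energy(self, grid):
        e_true = 185e3
        rate = single_energy_rate(e_true, 1.67e13, PROGRAM, grid)
        data = RateCurve(grid, rate, source="measured")
        theta, info = initialize_from_peaks(data, 1, "gaussian")
        assert not info["fallback"]
        assert abs(theta[0] - e_true) < 1e3

    def test_multi_peak_init_is_ordered_with_simplex_fractions(self, lignin_curve):
        theta, info = initialize_from_peaks(lignin_curve, 4, "gaussian")
        e_init = theta[:4]
        assert np.all(np.diff(info["peak_temperatures_K"]) > 0)
        assert np.all(np.diff(e_init) > 0)
        logits = theta[8:]
        c = np.exp(np.append(logits, 0.0))
        assert np.sum(c / c.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_falls_back_to_quantiles(self, grid):
        flat = RateCurve(grid, np.zeros_like(grid), source="measured")
        theta, info = initialize_from_peaks(flat, 2, "gaussian")
        assert info["fallback"]
        assert theta.size == 5


class TestRecovery:
    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("e_kj,sigma_kj", [(160.0, 3.0), (200.0, 12.0)])
    def test_single_component_parameters_recovered(self, grid, family, e_kj, sigma_kj):
        """Noise-free recovery: Ē within 0.5 %, σ within 5 % (relative)."""
        data = one_component_curve(family, kj_to_j(e_kj), kj_to_j(sigma_kj), grid)
        res = fit_daem(data, FitConfig(n_components=1, family=family, seed=0))
        comp = res.model.components[0]
        assert abs(comp.dist.e_mean - kj_to_j(e_kj)) / kj_to_j(e_kj) < 0.005
        assert abs(comp.dist.sigma - kj_to_j(sigma_kj)) / kj_to_j(sigma_kj) < 0.05

    def test_self_fit_r_squared(self, cellulose_fit):
        assert cellulose_fit.r_squared > 0.9999

    def test_fit_is_deterministic(self, cellulose_curve):
        cfg = FitConfig(n_components=1, family="gaussian", seed=42, max_restarts=1)
        a = fit_daem(cellulose_curve, cfg)
        b = fit_daem(cellulose_curve, cfg)
        pa = [(c.fraction, c.dist.e_mean, c.dist.sigma) for c in a.model.components]
        pb = [(c.fraction, c.dist.e_mean, c.dist.sigma) for c in b.model.components]
        assert pa == pb

    def test_joint_replicate_fit_concatenates_residuals(self, cellulose_curve):
        """Two noisy replicates fit jointly recover the generating Ē."""
        rng = np.random.default_rng(3)
        peak = cellulose_curve.rate.max()
        reps = [
            RateCurve(
                cellulose_curve.temperature,
                cellulose_curve.rate + rng.normal(0.0, 0.01 * peak, cellulose_curve.rate.size),
                source="measured",
            )
            for _ in range(2)
        ]
        cfg = FitConfig(n_components=1, family="gaussian", seed=0, max_restarts=0)
        theta = _encode(np.array([170e3]), np.array([2e3]), np.array([1.0]))
        assert residual_vector(theta, reps, cfg).size == 2 * cellulose_curve.rate.size
        res = fit_daem(reps, cfg)
        assert abs(res.model.components[0].dist.e_mean - kj_to_j(178.6488)) < 2e3
        assert res.r_squared > 0.99

    def test_noise_robustness_over_seeds(self, cellulose_curve):
        """1 % peak-height Gaussian noise: Ē stays within 2 kJ mol⁻¹."""
        peak = cellulose_curve.rate.max()
        e_true = kj_to_j(178.6488)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = RateCurve(
                cellulose_curve.temperature,
                cellulose_curve.rate + rng.normal(0.0, 0.01 * peak, cellulose_curve.rate.size),
                source="measured",
            )
            res = fit_daem(
                noisy,
                FitConfig(n_components=1, family="gaussian", seed=seed, max_restarts=0),
            )
            e_fit = res.model.components[0].dist.e_mean
            assert abs(e_fit - e_true) < 2e3, f"seed {seed}: {e_fit}"


class TestModelScan:
    def test_r_squared_non_decreasing_in_n(self, two_component_curve):
        cfg = FitConfig(n_components=1, seed=0, max_restarts=0, max_nfev=80)
        scan = model_scan(two_component_curve, [1, 2], ["gaussian"], cfg)
        r1 = scan.results[(1, "gaussian")].r_squared
        r2 = scan.results[(2, "gaussian")].r_squared
        assert r2 >= r1 - 1e-9
        assert r2 > 0.999

    def test_parsimony_tie_breaks_toward_fewer_components(self, cellulose_curve):
        cfg = FitConfig(n_components=1, seed=0, max_restarts=0, max_nfev=80)
        scan = model_scan(cellulose_curve, [1, 2], ["gaussian"], cfg)
        (n_best, _), _ = scan.best(tol=1e-4)
        assert n_best == 1

    def test_generating_family_wins_family_comparison(self, cellulose_curve):
        cfg = FitConfig(n_components=1, seed=0, max_restarts=0)
        scan = model_scan(cellulose_curve, [1], list(FAMILIES), cfg)
        table = scan.table()
        assert table.iloc[0]["family"] == "gaussian"

    def test_failures_are_recorded_not_raised(self, cellulose_curve):
        cfg = FitConfig(n_components=1, seed=0, max_restarts=0)
        scan = model_scan(cellulose_curve, [1], ["gaussian", "weibull"], cfg)
        assert (1, "gaussian") in scan.results
        assert (1, "weibull") in scan.failures

    def test_empty_ranges_rejected(self, cellulose_curve):
        with pytest.raises(ValueError):
            model_scan(cellulose_curve, [], ["gaussian"])


class TestConcordance:
    def test_cellulose_suggests_single_component(self):
        model, enthalpy = cellulose_fixture()
        tg = simulate_thermogram(model, 15.0, 3.0, enthalpy, NoiseSpec(seed=0))
        count, report = suggest_component_count(
            dtg_curve(tg), dsc_derivative_curve(tg)
        )
        assert count == 1
        assert (report["channel"] == "dtg").sum() == 1

    def test_lignin_suggests_four_components(self):
        model, enthalpy = lignin_fixture()
        tg = simulate_thermogram(model, 15.0, 6.0, enthalpy, NoiseSpec(seed=0))
        count, report = suggest_component_count(
            dtg_curve(tg), dsc_derivative_curve(tg)
        )
        assert count == 4
        # char decomposition shows in DSC only: at least one unmatched
        # DSC event above 400 °C
        dsc_rows = report[report["channel"] == "dsc"]
        assert (dsc_rows["temperature_C"] > 400).any()

    def test_flat_channels_suggest_nothing(self, grid):
        flat = RateCurve(grid, np.zeros_like(grid), source="measured")
        count, report = suggest_component_count(flat, flat)
        assert count == 0
        assert report.empty


class TestThermalClassification:
    def test_strict_signs(self):
        t = np.linspace(500.0, 600.0, 200)
        assert classify_thermal_event(t, -0.5 * np.ones(200), (520, 580)) == "endothermic"
        assert classify_thermal_event(t, 0.5 * np.ones(200), (520, 580)) == "exothermic"

    def test_near_zero_mean_is_ambiguous(self):
        rng = np.random.default_rng(0)
        t = np.linspace(500.0, 600.0, 400)
        hf = rng.normal(0.0, 0.05, t.size)
        assert classify_thermal_event(t, hf, (520, 580)) == "ambiguous"

    def test_empty_window_rejected(self):
        t = np.linspace(500.0, 600.0, 50)
        with pytest.raises(ValueError):
            classify_thermal_event(t, np.ones(50), (700.0, 800.0))

    def test_lignin_windows_classify_with_published_signs(self):
        """260/425 °C exothermic; 310/372 °C endothermic-leaning."""
        model, enthalpy = lignin_fixture()
        tg = simulate_thermogram(
            model, 15.0, 6.0, enthalpy, NoiseSpec(0.001, 0.01, 0.0, seed=3)
        )
        t, hf = dsc_curve(tg)
        for center, allowed in [
            (260, {"exothermic"}),
            (425, {"exothermic"}),
            (310, {"endothermic", "ambiguous"}),
            (372, {"endothermic", "ambiguous"}),
        ]:
            verdict = classify_thermal_event(
                t, hf, (c_to_k(center - 10), c_to_k(center + 10))
            )
            assert verdict in allowed, f"{center} °C: {verdict}"

    def test_cellulose_main_event_is_endothermic(self):
        model, enthalpy = cellulose_fixture()
        tg = simulate_thermogram(
            model, 15.0, 3.0, enthalpy, NoiseSpec(0.001, 0.01, 0.0, seed=3)
        )
        t, hf = dsc_curve(tg)
        assert (
            classify_thermal_event(t, hf, (c_to_k(320), c_to_k(340)))
            == "endothermic"
        )
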