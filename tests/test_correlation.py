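"""Dose-series assembly, trapezoid accumulation and the OLS correlation layer."""

import numpy as np
import pandas as pd
import pytest

from soxdosim.correlation import (
    CoverageError,
    DoseTimeSeries,
    build_dose_series,
    correlate_cumulative,
    correlate_instantaneous,
    cumulative_trapezoid,
    fit_linear,
    photobleach_fit,
)
from soxdosim.pipeline import ExperimentConfig, run_experiment
from soxdosim.synthetic import NoiseConfig, make_fluorescence_basis, simulate_fluorescence_series
from soxdosim.unmixing import fluorescence_unmix


def closed_form_ols(x, y):
    """Mean/covariance textbook formulas (oracle)."""
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return slope, ym - slope * xm


class TestCumulativeTrapezoid:
    @pytest.mark.parametrize(
        "t,v,expected",
        [
            ([0, 1, 2, 3], [5, 5, 5, 5], [0, 5, 10, 15]),
            ([0.0], [7.0], [0.0]),
            ([0, 1], [0, 2], [0, 1]),
        ],
    )
    def test_known_values(self, t, v, expected):
        np.testing.assert_allclose(cumulative_trapezoid(t, v), expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cumulative_trapezoid([0, 1], [1.0])

    def test_refinement_invariance_for_linear_integrand(self):
        coarse = np.linspace(0, 10, 6)
        fine = np.linspace(0, 10, 51)
        f = lambda t: 3 * t + 1
        assert cumulative_trapezoid(coarse, f(coarse))[-1] == pytest.approx(
            cumulative_trapezoid(fine, f(fine))[-1], rel=1e-12
        )


class TestFitLinear:
    def test_exact_line(self):
        x = np.linspace(0, 1, 9)
        r = fit_linear(x, 500.0 * x)
        assert r.slope == pytest.approx(500.0, rel=1e-12)
        assert r.intercept == pytest.approx(0.0, abs=1e-9)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        r = fit_linear(np.arange(5.0), np.full(5, 2.0))
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            fit_linear([1.0], [1.0])

    def test_matches_closed_form_oracle_on_100_instances(self, rng):
        for _ in range(100):
            n = rng.integers(3, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            r = fit_linear(x, y)
            slope, intercept = closed_form_ols(x, y)
            assert r.slope == pytest.approx(slope, rel=1e-12, abs=1e-12)
            assert r.intercept == pytest.approx(intercept, rel=1e-12, abs=1e-12)

    def test_slope_recovery_within_3_se(self, rng):
        n = 10_000
        x = rng.uniform(0, 1, n)
        y = x + rng.normal(0, 0.01, n)
        r = fit_linear(x, y)
        assert abs(r.slope - 1.0) < 3 * r.slope_se


def _exact_series(kappa=500.0, n_phantoms=3):
    """Phantom series with exact amplitude = kappa * dose proportionality."""
    t = np.arange(0.0, 901.0, 100.0)
    out = []
    for i in range(1, n_phantoms + 1):
        inst = i * np.exp(-t / 300.0)
        amps = pd.DataFrame({"t_s": t, "o2": kappa * inst})
        out.append(build_dose_series(amps, inst, label=f"p{i}"))
    return out


class TestCorrelate:
    def test_exact_proportionality_recovers_kappa_at_every_time(self):
        series = _exact_series(kappa=500.0)
        fits = correlate_instantaneous(series, at_times=(1.0, 450.0, 900.0))
        for r in fits.values():
            assert r.slope == pytest.approx(500.0, rel=1e-8)
            assert abs(r.intercept) < 1e-8

    def test_tie_between_acquisitions_resolves_to_earlier(self):
        s = _exact_series()[0]
        row = s.at_time(450.0)  # equidistant from 400 and 500
        assert row["t_s"] == 400.0

    def test_missing_coverage_raises(self):
        s = _exact_series()[0]
        with pytest.raises(CoverageError):
            s.at_time(2000.0)

    def test_single_phantom_rejected(self):
        with pytest.raises(ValueError):
            correlate_instantaneous(_exact_series(n_phantoms=1))
        with pytest.raises(ValueError):
            correlate_cumulative([])

    def test_cumulative_exact_proportionality(self):
        r = correlate_cumulative(_exact_series(kappa=500.0))
        assert r.slope == pytest.approx(500.0, rel=1e-10)
        assert r.r_squared == pytest.approx(1.0, abs=1e-10)
        assert abs(r.intercept) < 1e-8

    def test_noisy_ensemble_recovers_kappa(self):
        # 5 phantoms, 2% spectral noise: parameter-recovery experiment
        cfg = ExperimentConfig(
            noise=NoiseConfig(model="gaussian_scaled", sigma=0.02), seed=11
        )
        rep = run_experiment(cfg)
        cum = rep.cumulative_fit
        assert cum.slope == pytest.approx(cfg.kappa_detect, rel=0.05)
        assert cum.r_squared > 0.99
        # the early-time fit is signal-dominated and recovers the scale;
        # late-time fits are noise-dominated and must say so via their SEs
        early = rep.instantaneous_fits[1.0]
        late = rep.instantaneous_fits[900.0]
        assert abs(early.slope - cfg.kappa_detect) < 3 * early.slope_se
        assert late.slope_se > 100 * early.slope_se

    def test_dose_series_validation(self):
        with pytest.raises(ValueError):
            DoseTimeSeries(pd.DataFrame({"t_s": [0.0, 1.0]}))
        bad = pd.DataFrame(
            {
                "t_s": [1.0, 0.0],
                "a_o2": [0, 0],
                "cum_msold": [0, 0],
                "inst_soed_uM": [0, 0],
                "cum_soed_uM_s": [0, 0],
            }
        )
        with pytest.raises(ValueError):
            DoseTimeSeries(bad)


class TestPhotobleachFit:
    def test_no_bleaching(self):
        t = np.arange(0.0, 901.0, 100.0)
        r = photobleach_fit(t, np.ones_like(t))
        assert r.slope == pytest.approx(0.0, abs=1e-15)
        assert r.intercept == pytest.approx(1.0, rel=1e-12)

    def test_exact_linear_decay(self):
        t = np.arange(0.0, 901.0, 100.0)
        r = photobleach_fit(t, 1.0 - 1e-4 * t)
        assert r.slope == pytest.approx(-1e-4, rel=1e-10)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_pipeline_matches_generator_least_squares_line(self, phantom6, protocol):
        # unmix the noiseless fluorescence series, then fit; must reproduce
        # the OLS line through the generator's own bleaching curve
        series, truth = simulate_fluorescence_series(phantom6, protocol)
        ps, bg = make_fluorescence_basis()
        amp = np.array(
            [fluorescence_unmix(s, ps, bg).amplitude("ps_fluorescence") for s in series]
        )
        t = truth["t_s"].to_numpy()
        fitted = photobleach_fit(t, amp / amp[0])
        oracle = photobleach_fit(t, truth["rel_S0"].to_numpy())
        assert fitted.slope == pytest.approx(oracle.slope, rel=1e-8, abs=1e-12)
        assert fitted.intercept == pytest.approx(oracle.intercept, rel=1e-8)
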