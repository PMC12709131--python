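"""SVD least-squares unmixing against closed-form and construction oracles."""

import numpy as np
import pytest

from soxdosim.soed import IrradiationProtocol, PhantomSpec
from soxdosim.spectra import GridMismatchError, Spectrum
from soxdosim.synthetic import (
    NoiseConfig,
    make_fluorescence_basis,
    simulate_fluorescence_series,
    simulate_quench_pair,
    simulate_series,
)
from soxdosim.unmixing import (
    BasisMatrix,
    CollinearityError,
    UnmixModel,
    fluorescence_unmix,
    quench_difference,
    svd_unmix,
    unmix_series,
)


def random_instance(rng, n=40, k=3, cond_max=1e3):
    """A well-conditioned random basis + amplitudes, for oracle checks."""
    while True:
        B = rng.normal(size=(n, k))
        sv = np.linalg.svd(B, compute_uv=False)
        if sv[0] / sv[-1] < cond_max:
            break
    a = rng.normal(size=k)
    return B, a


def normal_equations(B, y):
    """Closed-form least squares through the normal equations (oracle)."""
    return np.linalg.solve(B.T @ B, B.T @ y)


def as_basis(B):
    wl = np.linspace(1200.0, 1600.0, B.shape[0])
    return wl, BasisMatrix(tuple(f"c{i}" for i in range(B.shape[1])), wl, B)


class TestSvdUnmix:
    def test_exact_amplitudes_on_consistent_mixture(self, basis):
        y = 2.0 * basis.matrix[:, 0] + 3.0 * basis.matrix[:, 1] + 1.0 * basis.matrix[:, 2]
        res = svd_unmix(Spectrum(basis.wavelengths, y), basis)
        np.testing.assert_allclose(res.amplitudes, [2.0, 3.0, 1.0], atol=1e-10)
        assert res.residual_rms < 1e-10 * np.linalg.norm(y)

    def test_orthogonal_spectrum_gives_zero_amplitudes(self):
        wl = np.linspace(1200, 1600, 6)
        B = np.zeros((6, 2))
        B[:2, 0] = 1.0
        B[2:4, 1] = 1.0
        basis = BasisMatrix(("a", "b"), wl, B)
        y = np.zeros(6)
        y[4:] = 3.0  # supported where no basis component lives
        res = svd_unmix(Spectrum(wl, y), basis)
        np.testing.assert_allclose(res.amplitudes, 0.0, atol=1e-12)
        assert res.residual_rms == pytest.approx(np.sqrt(np.mean(y**2)))

    def test_agrees_with_normal_equations_on_100_instances(self, rng):
        for _ in range(100):
            B, a = random_instance(rng)
            y = B @ a + rng.normal(scale=0.1, size=B.shape[0])
            wl, basis = as_basis(B)
            res = svd_unmix(Spectrum(wl, y), basis)
            oracle = normal_equations(B, y)
            np.testing.assert_allclose(res.amplitudes, oracle, rtol=1e-8, atol=1e-10)

    def test_amplitudes_linear_in_input(self, rng, basis):
        wl = basis.wavelengths
        x = rng.normal(size=wl.size)
        y = rng.normal(size=wl.size)
        ax = svd_unmix(Spectrum(wl, x), basis).amplitudes
        ay = svd_unmix(Spectrum(wl, y), basis).amplitudes
        both = svd_unmix(Spectrum(wl, 2.0 * x - 0.5 * y), basis).amplitudes
        np.testing.assert_allclose(both, 2.0 * ax - 0.5 * ay, rtol=1e-8, atol=1e-10)

    def test_nonneg_constrains_active_set(self, rng):
        wl = np.linspace(1200, 1600, 30)
        b1 = np.exp(-((wl - 1300) / 60) ** 2)
        b2 = np.exp(-((wl - 1350) / 60) ** 2)  # strongly overlapping pair
        basis = BasisMatrix(("p", "q"), wl, np.column_stack([b1, b2]))
        y = b1 - 0.4 * b2
        free = svd_unmix(Spectrum(wl, y), basis)
        constrained = svd_unmix(Spectrum(wl, y), basis, nonneg=True)
        assert free.amplitudes[1] < 0
        assert np.all(constrained.amplitudes >= 0)
        assert constrained.residual_rms >= free.residual_rms

    def test_mean_recovery_under_noise(self, rng, basis):
        # 200 noisy realizations: mean amplitudes within 3 SE of truth
        truth = np.array([1.6, 1.4, 0.5])
        clean = basis.matrix @ truth
        sigma = 0.01 * clean.max()
        est = np.array(
            [
                svd_unmix(
                    Spectrum(basis.wavelengths, clean + rng.normal(0, sigma, clean.size)),
                    basis,
                ).amplitudes
                for _ in range(200)
            ]
        )
        se = est.std(axis=0, ddof=1) / np.sqrt(est.shape[0])
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * se + 1e-12)

    def test_grid_mismatch_rejected(self, basis):
        wl = np.linspace(1200, 1600, basis.wavelengths.size + 3)
        with pytest.raises(GridMismatchError):
            UnmixModel(Spectrum(wl, np.zeros(wl.size)), basis)

    def test_collinear_basis_rejected(self):
        wl = np.linspace(1200, 1600, 10)
        col = np.exp(-(wl - 1300) / 100)
        with pytest.raises(CollinearityError):
            BasisMatrix(("a", "b"), wl, np.column_stack([col, 2.0 * col]))

    def test_summary_mentions_all_components(self, basis):
        res = svd_unmix(Spectrum(basis.wavelengths, basis.matrix @ [1, 1, 1]), basis)
        text = res.summary()
        for name in basis.names:
            assert name in text


class TestQuenchDifference:
    def test_identity_gives_zero(self, basis):
        s = Spectrum(basis.wavelengths, basis.matrix @ [1.0, 2.0, 0.5])
        d = quench_difference(s, s)
        assert np.all(d.intensities == 0)

    def test_difference_isolates_the_o2_band(self, basis, phantom6, protocol):
        pre, post = simulate_quench_pair(
            phantom6, protocol, basis=basis, residual_fraction=0.0
        )
        d = quench_difference(pre, post)
        ratio = d.intensities @ basis.component("o2") / (
            basis.component("o2") @ basis.component("o2")
        )
        np.testing.assert_allclose(d.intensities, ratio * basis.component("o2"), atol=1e-12)

    def test_partial_quench_scales_linearly(self, basis, phantom6, protocol):
        full = quench_difference(
            *simulate_quench_pair(phantom6, protocol, basis=basis, residual_fraction=0.0)
        )
        partial = quench_difference(
            *simulate_quench_pair(phantom6, protocol, basis=basis, residual_fraction=0.05)
        )
        np.testing.assert_allclose(partial.intensities, 0.95 * full.intensities, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = Spectrum(np.linspace(1200, 1600, 5), np.zeros(5))
        b = Spectrum(np.linspace(1200, 1600, 6), np.zeros(6))
        with pytest.raises(GridMismatchError):
            quench_difference(a, b)


class TestUnmixSeries:
    def test_noiseless_series_recovers_ground_truth(self, basis, phantom6, protocol):
        series, gt = simulate_series(phantom6, protocol, basis=basis)
        amps = unmix_series(series, basis)
        a = amps["o2"].to_numpy()
        peak = np.abs(gt.a_o2).max()
        big = gt.a_o2 > 1e-6 * peak
        np.testing.assert_allclose(a[big], gt.a_o2[big], rtol=1e-8)
        np.testing.assert_allclose(a, gt.a_o2, atol=1e-10 * peak)

    def test_single_spectrum_and_sorting(self, basis):
        wl = basis.wavelengths
        mk = lambda t: Spectrum(wl, basis.matrix @ [t + 1.0, 0.0, 0.0], t_acq_s=t)
        one = unmix_series([mk(0.0)], basis)
        assert len(one) == 1
        shuffled = unmix_series([mk(200.0), mk(0.0), mk(100.0)], basis)
        assert list(shuffled["t_s"]) == [0.0, 100.0, 200.0]
        np.testing.assert_allclose(shuffled["o2"], [1.0, 101.0, 201.0], rtol=1e-10)

    def test_empty_series_rejected(self, basis):
        with pytest.raises(ValueError):
            unmix_series([], basis)

    def test_smoothing_flag_changes_noisy_fit_not_clean_constant(self, basis, rng):
        wl = basis.wavelengths
        y = basis.matrix @ [1.0, 1.0, 1.0] + rng.normal(0, 0.05, wl.size)
        raw = unmix_series([Spectrum(wl, y, t_acq_s=0.0)], basis)
        smoothed = unmix_series([Spectrum(wl, y, t_acq_s=0.0)], basis, smooth=True)
        assert raw["residual_rms"][0] != smoothed["residual_rms"][0]


class TestFluorescenceUnmix:
    def test_pure_ps_spectrum_recovers_amplitude(self):
        ps, bg = make_fluorescence_basis()
        res = fluorescence_unmix(
            Spectrum(ps.wavelengths, 4.0 * ps.intensities), ps, bg, n_fourier=1
        )
        assert res.amplitude("ps_fluorescence") == pytest.approx(4.0, abs=1e-10)
        for name in ("cos1", "sin1"):
            assert abs(res.amplitude(name)) < 1e-10

    def test_zero_fourier_reduces_to_two_components(self):
        ps, bg = make_fluorescence_basis()
        res = fluorescence_unmix(
            Spectrum(ps.wavelengths, 2.0 * ps.intensities + bg.intensities), ps, bg,
            n_fourier=0,
        )
        assert res.names == ("ps_fluorescence", "background")
        np.testing.assert_allclose(res.amplitudes, [2.0, 1.0], atol=1e-10)

    def test_bleaching_curve_recovered_end_to_end(self, phantom6, protocol):
        series, truth = simulate_fluorescence_series(phantom6, protocol)
        ps, bg = make_fluorescence_basis()
        amp = np.array(
            [fluorescence_unmix(s, ps, bg).amplitude("ps_fluorescence") for s in series]
        )
        rel = amp / amp[0]
        np.testing.assert_allclose(
            rel, truth["rel_S0"].to_numpy(), rtol=1e-8, atol=1e-8
        )
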