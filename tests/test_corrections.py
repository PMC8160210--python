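"""Pre-fit corrections: drift, ionic strength, CD smoothing, MST stitching."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from titrafit.corrections import (
    DriftRecord,
    IonicStrengthModel,
    Spectrum,
    differential_and_select,
    drift_correct,
    fit_drift_slopes,
    ionic_strength_correct,
    phosphate_ionic_strength,
    sg_smooth,
    stitch_ranges,
)
from titrafit.errors import (
    ExtrapolationError,
    InvalidInputError,
    UnidentifiableError,
)
from titrafit.simulate import SimulationConfig, simulate_fluorescence_series

from conftest import make_curve


class TestDriftSlopes:
    def test_constant_signal_zero_slope(self):
        ts = [np.column_stack([np.arange(5.0), np.full(5, 100.0)])] * 3
        rec = fit_drift_slopes(ts)
        assert np.allclose(rec.slopes, 0.0)

    def test_exact_line(self):
        t = np.linspace(0, 2, 6)
        ts = [np.column_stack([t, 100.0 - 0.5 * t])]
        rec = fit_drift_slopes(ts, interval=1.0)
        assert rec.slopes[0] == pytest.approx(-0.5, abs=1e-12)

    def test_noisy_line_within_3se(self, rng):
        t = np.linspace(0, 1, 40)
        slope = -0.4
        sigma = 0.05
        F = 100.0 + slope * t + rng.normal(scale=sigma, size=t.size)
        rec = fit_drift_slopes([np.column_stack([t, F])])
        se = sigma / (np.std(t) * np.sqrt(t.size))
        assert abs(rec.slopes[0] - slope) < 3 * se

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_drift_slopes([np.array([[0.0, 1.0]])])


class TestDriftCorrect:
    def test_zero_slopes_identity(self):
        F = np.array([10.0, 9.0, 8.0])
        out = drift_correct(F, DriftRecord(slopes=np.zeros(3)))
        assert np.array_equal(out, F)

    def test_direct_arithmetic(self):
        out = drift_correct(
            np.array([100.0, 98.0]), DriftRecord(slopes=np.array([0.5, 0.5]))
        )
        assert np.allclose(out, [100.5, 99.0])

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            drift_correct(np.zeros(3), DriftRecord(slopes=np.zeros(2)))

    def test_round_trip_with_generator(self):
        # drift-only degradation is inverted exactly using the true slopes
        cfg = SimulationConfig(seed=21, noise_sd=0.0)
        sim = simulate_fluorescence_series(
            cfg, with_noise=False, with_drift=True, with_quench=False
        )
        for obs, truth, drift in zip(
            sim.curves, sim.truth_curves, sim.drift_true
        ):
            corrected = drift_correct(obs.signal, drift, sign=-1)
            assert np.allclose(corrected, truth.signal, rtol=1e-12)


class TestPhosphateIonicStrength:
    def test_zero_concentration(self):
        assert phosphate_ionic_strength(0.0, pH=7.6) == 0.0

    def test_henderson_hasselbalch_midpoint(self):
        # at pH == pKa exactly half the phosphate is dibasic: I = 2c
        assert phosphate_ionic_strength(10.0, pH=7.2) == pytest.approx(20.0)

    def test_formula_arithmetic(self):
        I = phosphate_ionic_strength(10.0, pH=7.6, pKa=7.2)
        f2 = 1.0 / (1.0 + 10.0 ** (-0.4))
        assert f2 == pytest.approx(0.715, abs=5e-4)
        assert I == pytest.approx(24.3, abs=0.05)

    def test_linear_in_concentration(self):
        c = np.array([1.0, 2.0, 4.0, 8.0])
        I = phosphate_ionic_strength(c, pH=7.6)
        assert np.allclose(I / c, I[0] / c[0])


class TestIonicStrengthCorrect:
    def test_flat_reference_identity(self):
        model = IonicStrengthModel(
            I_mM=np.linspace(10, 200, 20), F=np.full(20, 55.0)
        )
        F = np.array([5.0, 4.0, 3.0])
        out = ionic_strength_correct(F, model, np.array([20.0, 50.0, 150.0]))
        assert np.allclose(out, F)

    def test_points_below_knee_unchanged(self):
        # WT-like reference: constant up to ~100 mM then a steep drop
        I = np.linspace(10, 300, 60)
        Fref = np.where(I <= 100, 80.0, 80.0 / (1 + ((I - 100) / 50) ** 2))
        model = IonicStrengthModel(I_mM=I, F=Fref)
        F_obs = np.array([7.0, 6.5, 6.0])
        out = ionic_strength_correct(
            F_obs, model, np.array([20.0, 50.0, 90.0])
        )
        assert np.allclose(out, F_obs, rtol=1e-9)

    def test_extrapolation_refused(self):
        model = IonicStrengthModel(I_mM=np.array([10.0, 100.0]),
                                   F=np.array([1.0, 1.0]))
        with pytest.raises(ExtrapolationError):
            ionic_strength_correct(
                np.array([1.0]), model, np.array([500.0])
            )

    def test_quench_round_trip(self):
        cfg = SimulationConfig(seed=22, noise_sd=0.0)
        sim = simulate_fluorescence_series(
            cfg, with_noise=False, with_drift=False, with_quench=True
        )
        for obs, truth in zip(sim.curves, sim.truth_curves):
            out = ionic_strength_correct(
                obs.signal, sim.reference, sim.ionic_strength_mM
            )
            assert np.allclose(out, truth.signal, rtol=1e-9)

    def test_wrong_correction_order_biases(self):
        # applying the multiplicative quench division before removing the
        # additive drift leaves a bias well above the (zero) noise floor
        # knee placed inside the titration range so the quench actually
        # bites and the operations visibly fail to commute
        cfg = SimulationConfig(seed=23, noise_sd=0.0, quench_knee_mM=60.0)
        sim = simulate_fluorescence_series(
            cfg, with_noise=False, with_drift=True, with_quench=True
        )
        i = 0
        obs, truth = sim.curves[i], sim.truth_curves[i]
        right = ionic_strength_correct(
            drift_correct(obs.signal, sim.drift_true[i], sign=-1),
            sim.reference,
            sim.ionic_strength_mM,
        )
        wrong = drift_correct(
            ionic_strength_correct(
                obs.signal, sim.reference, sim.ionic_strength_mM
            ),
            sim.drift_true[i],
            sign=-1,
        )
        assert np.allclose(right, truth.signal, rtol=1e-9)
        assert np.max(np.abs(wrong - truth.signal)) > 1e-3


class TestSavitzkyGolay:
    def _spec(self, values):
        wl = np.arange(230.0, 230.0 + 0.25 * len(values), 0.25)
        return Spectrum(wavelength_nm=wl, value=np.asarray(values))

    def test_quartic_reproduced_exactly(self):
        x = np.linspace(-1, 1, 81)
        quartic = 2 - x + 3 * x**2 - 0.5 * x**3 + x**4
        out = sg_smooth(self._spec(quartic))
        assert np.allclose(out.value[5:-5], quartic[5:-5], atol=1e-9)

    def test_constant_unchanged(self):
        out = sg_smooth(self._spec(np.full(40, 3.3)))
        assert np.allclose(out.value, 3.3)

    def test_noise_variance_reduction_gain(self, rng):
        # white-noise variance shrinks by the filter's sum of squared
        # coefficients; Monte-Carlo over 100 seeds within 10%
        gain = float(np.sum(savgol_coeffs(11, 4) ** 2))
        ratios = []
        for _ in range(100):
            noise = rng.standard_normal(400)
            sm = sg_smooth(self._spec(noise))
            ratios.append(np.var(sm.value[10:-10]) / np.var(noise))
        assert np.mean(ratios) == pytest.approx(gain, rel=0.10)

    def test_short_spectrum_rejected(self):
        with pytest.raises(InvalidInputError):
            sg_smooth(self._spec(np.zeros(8)))

    def test_bad_window(self):
        with pytest.raises(InvalidInputError):
            sg_smooth(self._spec(np.zeros(40)), poly_order=4, window=10)


class TestDifferentialSelect:
    def _pair(self, diff_values):
        wl = np.arange(230.0, 300.0 + 1e-9, 0.25)
        apo = Spectrum(wavelength_nm=wl, value=np.zeros_like(wl))
        cpx = Spectrum(wavelength_nm=wl, value=np.asarray(diff_values))
        return cpx, apo, wl

    def test_identical_spectra_signalled(self):
        cpx, apo, _ = self._pair(np.zeros(281))
        with pytest.raises(UnidentifiableError):
            differential_and_select(cpx, apo, k=2)

    def test_single_bump_center_selected(self):
        wl = np.arange(230.0, 300.0 + 1e-9, 0.25)
        bump = np.exp(-0.5 * ((wl - 262.0) / 3.0) ** 2)
        cpx, apo, _ = self._pair(bump)
        _, picks = differential_and_select(cpx, apo, k=1)
        assert picks[0] == pytest.approx(262.0, abs=0.25)

    def test_two_bumps_in_height_order(self):
        wl = np.arange(230.0, 300.0 + 1e-9, 0.25)
        two = 1.0 * np.exp(-0.5 * ((wl - 250.0) / 3.0) ** 2) - 0.6 * np.exp(
            -0.5 * ((wl - 285.0) / 3.0) ** 2
        )
        cpx, apo, _ = self._pair(two)
        # exclusion window wide enough to keep shoulder points of the
        # first band from outranking the second band
        _, picks = differential_and_select(cpx, apo, k=2, min_spacing_nm=12.0)
        assert picks[0] == pytest.approx(250.0, abs=0.25)
        assert picks[1] == pytest.approx(285.0, abs=0.25)

    def test_grid_mismatch(self):
        wl = np.arange(230.0, 300.0 + 1e-9, 0.25)
        a = Spectrum(wavelength_nm=wl, value=np.zeros_like(wl))
        b = Spectrum(wavelength_nm=wl + 1.0, value=np.ones_like(wl))
        with pytest.raises(InvalidInputError):
            differential_and_select(a, b, k=1)


class TestStitchRanges:
    def _curves(self, scale=1.0, offset=0.0, noise=None, rng=None):
        l = np.geomspace(1e-2, 1e4, 20)
        sig = 100.0 / (1.0 + 50.0 / l)  # any smooth monotone curve
        lo = make_curve(l[:12], sig[:12], modality="mst", p_total=0.1)
        hi_sig = scale * sig[8:] + offset
        if noise is not None:
            hi_sig = hi_sig + rng.normal(scale=noise, size=hi_sig.size)
        hi = make_curve(l[8:], hi_sig, modality="mst", p_total=0.1)
        return lo, hi, l, sig

    def test_identical_curves(self):
        lo, hi, l, sig = self._curves()
        merged, rep = stitch_ranges(lo, hi)
        assert rep.scale == pytest.approx(1.0, abs=1e-9)
        assert rep.offset == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(merged.l_total, l)
        assert np.allclose(merged.signal, sig)

    def test_exact_affine_recovered(self):
        lo, hi, l, sig = self._curves(scale=2.0, offset=5.0)
        merged, rep = stitch_ranges(lo, hi)
        assert rep.scale == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(merged.signal, sig, atol=1e-9)

    def test_noisy_overlap_merged_within_noise(self, rng):
        lo, hi, l, sig = self._curves(scale=1.3, offset=-2.0, noise=0.5,
                                      rng=rng)
        merged, rep = stitch_ranges(lo, hi)
        assert np.max(np.abs(merged.signal - sig)) < 5 * 0.5 / 1.3 + 0.5

    def test_insufficient_overlap(self):
        l = np.geomspace(1e-2, 1e4, 20)
        sig = np.linspace(0, 1, 20)
        lo = make_curve(l[:10], sig[:10], modality="mst", p_total=0.1)
        hi = make_curve(l[12:], sig[12:], modality="mst", p_total=0.1)
        with pytest.raises(InvalidInputError):
            stitch_ranges(lo, hi)
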