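"""Forward-model and phantom-assembly behaviour."""

import numpy as np
import pytest

from wmquant.gradients import GradientTable, default_gradient_table
from wmquant.phantom import (
    GRE_ECHO_TIMES,
    MicrostructureGroundTruth,
    PhantomSpec,
    add_rician_noise,
    build_phantom,
    simulate_cpmg_decay,
    simulate_dki_signal,
    simulate_gre_magnitudes,
    simulate_mt_pair,
    simulate_noddi_signal,
    simulate_orientation_series,
    simulate_tensor_signal,
)
from wmquant.watson import kappa_from_odi, watson_tau

from oracles import isochromat_cpmg, mc_watson_stick


def _gt(**kw):
    defaults = dict(eigenvalues=(1.0, 0.5, 0.5))
    defaults.update(kw)
    return MicrostructureGroundTruth(**defaults)


class TestGroundTruthValidation:
    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            _gt(eigenvalues=(0.5, 1.0, 0.5))

    def test_full_saturation_mtr_rejected(self):
        with pytest.raises(ValueError):
            _gt(mtr_true=100.0)

    def test_t2_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _gt(t2_components=((20.0, 0.5), (80.0, 0.6)))


class TestTensorSignal:
    def test_b0_returns_s0(self, gtab):
        gt = _gt(eigenvalues=(0.810, 0.810, 0.810))
        sig = simulate_tensor_signal(gt, gtab)
        np.testing.assert_allclose(sig[gtab.b0_mask], gt.s0)

    def test_axial_attenuation_closed_form(self):
        # gradient along the fibre at b=700: S = S0 exp(-0.7 * 1.611)
        gt = _gt(eigenvalues=(1.611, 0.318, 0.318), principal_orientation=(0, 0, 1))
        gtab = GradientTable(np.array([0.0, 700.0]), np.array([[0, 0, 0], [0, 0, 1.0]]))
        sig = simulate_tensor_signal(gt, gtab)
        np.testing.assert_allclose(sig[1], gt.s0 * np.exp(-0.7 * 1.611), rtol=1e-12)

    def test_signal_decreases_monotonically_with_b(self):
        gt = _gt()
        bvals = np.array([0.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0])
        bvecs = np.vstack([np.zeros(3), np.tile([0, 0, 1.0], (5, 1))])
        sig = simulate_tensor_signal(gt, GradientTable(bvals, bvecs))
        assert np.all(np.diff(sig) < 0)


class TestKurtosisSignal:
    def test_zero_kurtosis_reduces_to_tensor(self, gtab):
        gt = _gt(kurtosis_iso=0.0)
        np.testing.assert_allclose(
            simulate_dki_signal(gt, gtab), simulate_tensor_signal(gt, gtab), rtol=1e-14
        )

    def test_isotropic_closed_form_at_b2000(self):
        d, k = 0.752, 1.392
        gt = _gt(eigenvalues=(d, d, d), kurtosis_iso=k)
        gtab = GradientTable(np.array([0.0, 2000.0]), np.array([[0, 0, 0], [0, 1.0, 0]]))
        sig = simulate_dki_signal(gt, gtab)
        expected = gt.s0 * np.exp(-2.0 * d + (1.0 / 6.0) * 4.0 * d**2 * k)
        np.testing.assert_allclose(sig[1], expected, rtol=1e-12)

    def test_linear_in_s0(self, gtab):
        lo = _gt(kurtosis_iso=1.0, s0=100.0)
        hi = _gt(kurtosis_iso=1.0, s0=200.0)
        np.testing.assert_allclose(
            simulate_dki_signal(hi, gtab), 2.0 * simulate_dki_signal(lo, gtab)
        )

    def test_negative_kurtosis_rejected(self, gtab):
        gt = _gt()
        object.__setattr__(gt, "kurtosis_iso", -0.5)
        with pytest.raises(ValueError):
            simulate_dki_signal(gt, gtab)


class TestNoddiSignal:
    def test_pure_ball_when_iso_is_one(self, gtab):
        gt = _gt(iso_fraction=1.0)
        sig = simulate_noddi_signal(gt, gtab, d_iso=3.0)
        np.testing.assert_allclose(sig, gt.s0 * np.exp(-gtab.bvals_ms * 3.0), rtol=1e-10)

    def test_b0_independent_of_parameters(self, gtab, plic):
        sig = simulate_noddi_signal(plic, gtab)
        np.testing.assert_allclose(sig[gtab.b0_mask], plic.s0, rtol=1e-12)

    def test_zero_dispersion_parallel_stick_closed_form(self, gtab):
        # ODI=0 (kappa -> inf): stick exp(-b d (g.mu)^2), zeppelin with tau=1
        gt = _gt(odi=0.0, icvf=0.7, iso_fraction=0.0, principal_orientation=(0, 0, 1))
        sig = simulate_noddi_signal(gt, gtab, d_par=1.7)
        b, c2 = gtab.bvals_ms, (gtab.bvecs @ [0, 0, 1.0]) ** 2
        a_ic = np.exp(-b * 1.7 * c2)
        d_perp = 1.7 * (1 - 0.7)
        a_ec = np.exp(-b * (d_perp + (1.7 - d_perp) * c2))
        expected = gt.s0 * (0.7 * a_ic + 0.3 * a_ec)
        np.testing.assert_allclose(sig, expected, rtol=1e-9)

    def test_no_neurites_no_iso_is_pure_zeppelin(self, gtab):
        gt = _gt(icvf=0.0, iso_fraction=0.0, odi=0.2, principal_orientation=(0, 0, 1))
        sig = simulate_noddi_signal(gt, gtab, d_par=1.7)
        # ICVF=0: tortuosity d_perp = d_par, i.e. the dispersed zeppelin is
        # the isotropic ball with diffusivity d_par
        np.testing.assert_allclose(sig, gt.s0 * np.exp(-gtab.bvals_ms * 1.7), rtol=1e-9)

    def test_watson_quadrature_against_monte_carlo(self, plic):
        # dispersed-stick kernel vs rejection-sampled Watson average
        from wmquant.watson import watson_stick_attenuation

        rng = np.random.default_rng(42)
        kappa = kappa_from_odi(plic.odi)
        for bd, cb in [(2.0 * 1.7, 1.0), (0.7 * 1.7, 0.4), (3.4, 0.0)]:
            mc = mc_watson_stick(
                bd, np.array([np.sqrt(1 - cb**2), 0.0, cb]), kappa, 10**6, rng
            )
            quad = watson_stick_attenuation(np.array([bd]), np.array([cb]), kappa)[0]
            assert quad == pytest.approx(mc, abs=3e-3)


class TestCpmgDecay:
    def test_mono_exponential_limit_at_180(self):
        gt = _gt(t2_components=((80.0, 1.0),), flip_angle=180.0)
        dec = simulate_cpmg_decay(gt, n_echoes=32, echo_spacing=10.0)
        te = 10.0 * np.arange(1, 33)
        np.testing.assert_allclose(dec, gt.s0 * np.exp(-te / 80.0), rtol=1e-10)

    def test_first_echo_single_component(self):
        gt = _gt(t2_components=((80.0, 1.0),), flip_angle=180.0)
        dec = simulate_cpmg_decay(gt, n_echoes=2, echo_spacing=10.0)
        assert dec[0] == pytest.approx(gt.s0 * np.exp(-10.0 / 80.0), rel=1e-12)

    def test_two_component_train_matches_isochromat_oracle(self, cst_cs):
        dec = simulate_cpmg_decay(cst_cs, n_echoes=32, echo_spacing=10.0)
        oracle = np.zeros(32)
        for t2, frac in cst_cs.t2_components:
            oracle += frac * isochromat_cpmg(
                cst_cs.flip_angle, t2, cst_cs.t1, 10.0, 32
            )
        np.testing.assert_allclose(dec, cst_cs.s0 * oracle, rtol=1e-10)

    def test_too_few_echoes_rejected(self, cst_cs):
        with pytest.raises(ValueError):
            simulate_cpmg_decay(cst_cs, n_echoes=1)


class TestMtPairAndGre:
    def test_mt_pair_values(self, plic):
        non_mt, mt = simulate_mt_pair(plic)
        assert (non_mt, mt) == (100.0, pytest.approx(59.06))

    def test_zero_mtr_identity(self):
        gt = _gt(mtr_true=0.0)
        non_mt, mt = simulate_mt_pair(gt)
        assert non_mt == mt

    def test_gre_closed_form_at_last_echo(self, frontal):
        mags = simulate_gre_magnitudes(frontal, GRE_ECHO_TIMES)
        assert mags[-1] == pytest.approx(frontal.s0 * np.exp(-17.97 * 0.046), rel=1e-12)

    def test_halving_r2star_raises_magnitudes(self, frontal):
        slow = _gt(r2star_true=frontal.r2star_true / 2.0)
        m_fast = simulate_gre_magnitudes(frontal, GRE_ECHO_TIMES)
        m_slow = simulate_gre_magnitudes(slow, GRE_ECHO_TIMES)
        assert np.all(m_slow > m_fast)


class TestOrientationSeries:
    @pytest.mark.parametrize(
        "n, theta, expected",
        [(2.0, 0.0, 10.0), (2.0, 90.0, 13.0), (4.0, 45.0, 10.75)],
    )
    def test_closed_form_values(self, n, theta, expected):
        v = simulate_orientation_series(10.0, 3.0, n, np.array([theta]))
        assert v[0] == pytest.approx(expected, rel=1e-12)

    def test_angles_outside_quadrant_rejected(self):
        with pytest.raises(ValueError):
            simulate_orientation_series(0.0, 1.0, 2.0, np.array([120.0]))


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        s = np.linspace(0, 10, 11)
        np.testing.assert_array_equal(add_rician_noise(s, 0.0, 1), s)

    def test_high_snr_limit_is_unbiased(self):
        out = add_rician_noise(np.full(10**5, 1000.0), 1.0, 123)
        assert out.mean() == pytest.approx(1000.0, abs=0.05)

    def test_zero_signal_rayleigh_mean(self):
        out = add_rician_noise(np.zeros(10**5), 2.0, 456)
        assert out.mean() == pytest.approx(2.0 * np.sqrt(np.pi / 2.0), rel=5e-3)


class TestBuildPhantom:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(voxels_per_region=3, noise_sigma=2.0, seed=11)
        a, b = build_phantom(spec), build_phantom(spec)
        for attr in ("dwi_tensor", "dwi_kurtosis", "dwi_noddi", "cpmg", "gre"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_noise_free_voxels_identical_within_region(self, small_phantom):
        for arr in (small_phantom.dwi_tensor, small_phantom.cpmg):
            assert np.all(arr == arr[:1])  # every row equals the first

    def test_labels_partition_the_slab(self, small_phantom):
        assert sorted(np.unique(small_phantom.labels)) == [1, 2, 3]
        assert small_phantom.labels.shape == (2, 3, 1)

    def test_truth_table_carries_generating_values(self, small_phantom):
        t = small_phantom.truth
        val = t[(t.region == "cst_plic") & (t.parameter == "icvf")].value.iloc[0]
        assert val == 0.745

    def test_watson_tau_limits(self):
        assert watson_tau(0.0) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert watson_tau(np.inf) == 1.0
        assert watson_tau(2000.0) == pytest.approx(1.0, abs=1e-3)
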