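"""Diffusion model fitting: recovery, constraints, oracle equivalences."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from wmquant.dwi import D_MIN, fit_dki, fit_dti, fit_noddi, map_volume
from wmquant.gradients import GradientTable, default_gradient_table
from wmquant.phantom import (
    MicrostructureGroundTruth,
    add_rician_noise,
    simulate_dki_signal,
    simulate_noddi_signal,
    simulate_tensor_signal,
)

from oracles import spherical_average


def _rotation(seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.linalg.det(q))


class TestDti:
    def test_plic_eigenvalue_recovery(self, gtab_low, plic):
        sig = simulate_tensor_signal(plic, gtab_low)
        fit = fit_dti(sig, gtab_low)
        assert fit.axial == pytest.approx(1.611, abs=1e-6)
        assert fit.radial == pytest.approx(0.318, abs=1e-6)

    def test_isotropic_fa_is_zero(self, gtab_low):
        gt = MicrostructureGroundTruth(eigenvalues=(0.810, 0.810, 0.810))
        fit = fit_dti(simulate_tensor_signal(gt, gtab_low), gtab_low)
        assert fit.md == pytest.approx(0.810, abs=1e-6)
        assert fit.fa == pytest.approx(0.0, abs=1e-6)

    def test_loglinear_equals_nonlinear_refit(self, gtab_low, plic):
        # independent oracle: nonlinear LSQ of S itself (not log S)
        sig = simulate_tensor_signal(plic, gtab_low)
        fit = fit_dti(sig, gtab_low)
        b, g = gtab_low.bvals_ms, gtab_low.bvecs

        def resid(x):
            D = np.array(
                [[x[1], x[4], x[5]], [x[4], x[2], x[6]], [x[5], x[6], x[3]]]
            )
            return x[0] * np.exp(-b * np.einsum("ij,nj,ni->n", D, g, g)) - sig

        x0 = np.array([90.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = least_squares(resid, x0, xtol=1e-15, ftol=1e-15)
        D_nl = np.array(
            [
                [res.x[1], res.x[4], res.x[5]],
                [res.x[4], res.x[2], res.x[6]],
                [res.x[5], res.x[6], res.x[3]],
            ]
        )
        np.testing.assert_allclose(fit.d_tensor, D_nl, atol=1e-6)

    def test_nonpositive_signal_flags_voxel(self, gtab_low):
        sig = np.ones(len(gtab_low))
        sig[3] = 0.0
        fit = fit_dti(sig, gtab_low)
        assert not fit.valid and np.isnan(fit.md)

    def test_full_table_rejected(self, gtab):
        with pytest.raises(ValueError, match="one shell"):
            fit_dti(np.ones(len(gtab)), gtab)

    def test_fa_bounded_on_noisy_fits(self, gtab_low, plic):
        sig = simulate_tensor_signal(plic, gtab_low)
        for seed in range(5):
            noisy = add_rician_noise(sig, 3.0, seed)
            fit = fit_dti(noisy, gtab_low)
            assert 0.0 <= fit.fa <= 1.0 and fit.md > 0


class TestDki:
    def test_isotropic_kurtosis_recovery(self, gtab):
        gt = MicrostructureGroundTruth(
            eigenvalues=(0.752, 0.752, 0.752), kurtosis_iso=1.392
        )
        fit = fit_dki(simulate_dki_signal(gt, gtab), gtab)
        assert fit.mk == pytest.approx(1.392, abs=1e-3)
        assert np.trace(fit.d_tensor) / 3.0 == pytest.approx(0.752, abs=1e-6)

    def test_kurtosis_free_signal_gives_zero_mk(self, gtab, plic):
        sig = simulate_tensor_signal(plic, gtab)
        fit = fit_dki(sig, gtab)
        assert fit.mk == pytest.approx(0.0, abs=1e-3)

    def test_mk_equals_independent_spherical_average(self, gtab, frontal):
        gt = MicrostructureGroundTruth(
            eigenvalues=frontal.eigenvalues,
            principal_orientation=frontal.principal_orientation,
            kurtosis_iso=0.972,
        )
        fit = fit_dki(simulate_dki_signal(gt, gtab), gtab)
        oracle_mk = spherical_average(fit.k_app)
        assert fit.mk == pytest.approx(oracle_mk, abs=1e-3)

    def test_constraints_hold_on_noisy_fits(self, gtab):
        gt = MicrostructureGroundTruth(
            eigenvalues=(0.752, 0.752, 0.752), kurtosis_iso=1.392, s0=100.0
        )
        sig = simulate_dki_signal(gt, gtab)
        dirs = gtab.bvecs[gtab.dwi_mask]
        b_max_ms = gtab.b_max / 1000.0
        n_constrained = 0
        for seed in range(8):
            fit = fit_dki(add_rician_noise(sig, 8.0, seed), gtab)
            if not fit.valid:
                continue
            d = fit.d_app(dirs)
            k = fit.k_app(dirs)
            assert np.all(d >= D_MIN - 1e-9)
            assert np.all(k >= -1e-8)
            assert np.all(k * d * b_max_ms <= 3.0 + 1e-7)
            n_constrained += fit.constrained
        assert n_constrained >= 1  # the QP path was actually exercised

    def test_rotation_equivariance_of_invariants(self, gtab, plic):
        gt_k = MicrostructureGroundTruth(
            eigenvalues=plic.eigenvalues,
            principal_orientation=plic.principal_orientation,
            kurtosis_iso=0.8,
        )
        fit0 = fit_dki(simulate_dki_signal(gt_k, gtab), gtab)
        R = _rotation(5)
        mu_rot = tuple(R @ np.asarray(plic.principal_orientation))
        gt_rot = MicrostructureGroundTruth(
            eigenvalues=plic.eigenvalues,
            principal_orientation=mu_rot,
            kurtosis_iso=0.8,
        )
        gtab_rot = GradientTable(gtab.bvals, gtab.bvecs @ R.T)
        fit1 = fit_dki(simulate_dki_signal(gt_rot, gtab_rot), gtab_rot)
        assert fit1.mk == pytest.approx(fit0.mk, abs=1e-6)
        assert np.trace(fit1.d_tensor) == pytest.approx(np.trace(fit0.d_tensor), abs=1e-6)


class TestNoddi:
    def test_plic_parameter_recovery(self, gtab, plic):
        fit = fit_noddi(simulate_noddi_signal(plic, gtab), gtab)
        assert fit.icvf == pytest.approx(0.745, abs=1e-3)
        assert fit.odi == pytest.approx(0.104, abs=1e-3)
        assert fit.iso_fraction == pytest.approx(0.106, abs=1e-3)

    def test_pure_ball_collapses_to_iso(self, gtab):
        gt = MicrostructureGroundTruth(eigenvalues=(1.0, 0.5, 0.5), iso_fraction=1.0)
        fit = fit_noddi(simulate_noddi_signal(gt, gtab), gtab)
        assert fit.iso_fraction >= 0.99

    def test_fitted_objective_at_least_as_good_as_truth(self, gtab, cst_cs):
        sig = simulate_noddi_signal(cst_cs, gtab)
        fit = fit_noddi(sig, gtab)
        truth_sse = 0.0  # signal was generated by the same forward model
        assert fit.fit_residual <= truth_sse + 1e-8

    def test_rotation_equivariance(self, gtab, cst_cs):
        fit0 = fit_noddi(simulate_noddi_signal(cst_cs, gtab), gtab)
        R = _rotation(9)
        from dataclasses import replace

        gt_rot = replace(
            cst_cs, principal_orientation=tuple(R @ cst_cs.principal_orientation)
        )
        gtab_rot = GradientTable(gtab.bvals, gtab.bvecs @ R.T)
        fit1 = fit_noddi(simulate_noddi_signal(gt_rot, gtab_rot), gtab_rot)
        for attr in ("icvf", "odi", "iso_fraction"):
            assert getattr(fit1, attr) == pytest.approx(getattr(fit0, attr), abs=1e-6)


class TestMapVolume:
    def test_empty_mask_gives_all_missing(self, gtab_low, plic):
        vol = np.tile(simulate_tensor_signal(plic, gtab_low), (2, 2, 1, 1))
        maps = map_volume(fit_dti, vol, gtab_low, np.zeros((2, 2, 1), bool))
        assert maps == {}

    def test_single_voxel_equals_direct_call(self, gtab_low, plic):
        sig = simulate_tensor_signal(plic, gtab_low)
        vol = sig[None, None, None, :]
        mask = np.ones((1, 1, 1), bool)
        maps = map_volume(fit_dti, vol, gtab_low, mask)
        direct = fit_dti(sig, gtab_low).as_scalars()
        for name, value in direct.items():
            assert maps[name][0, 0, 0] == pytest.approx(value, rel=1e-15)

    def test_shape_mismatch_raises(self, gtab_low):
        with pytest.raises(ValueError, match="mask shape"):
            map_volume(
                fit_dti, np.ones((2, 2, 1, 31)), gtab_low, np.ones((3, 2, 1), bool)
            )

    def test_noise_free_region_maps_have_zero_spread(self, small_phantom):
        low = small_phantom.gtab.bvals <= 750.0
        maps = map_volume(
            fit_dti,
            small_phantom.dwi_tensor[..., low],
            small_phantom.gtab.subset(low),
            small_phantom.labels > 0,
        )
        for j in range(3):
            region_vals = maps["fa"][:, j, 0]
            assert np.ptp(region_vals) == pytest.approx(0.0, abs=1e-12)
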