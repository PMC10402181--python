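"""Unrolled reconstructor: proximal algebra, gradients, and the
gradient-descent reduction oracle."""

import numpy as np
import pytest

import relaxmore as rm
from relaxmore.signal import spgr_signal_at_angles
from relaxmore.unrolled import (
    UnrolledModel,
    coil_combine,
    data_fidelity_gradient,
    delta_init,
    normalization_scale,
    prox_step,
    reconstruct,
    soft_threshold,
)


def small_model(**kw):
    args = dict(
        n_coils=1,
        n_flip=2,
        n_phases=3,
        alpha0=0.1,
        beta0=1e-5,
        init_width=4,
        init_depth=2,
        prox_width=4,
        prox_depth=2,
        seed=0,
    )
    args.update(kw)
    return UnrolledModel.create(**args)


def fidelity(delta, kdata):
    x = rm.spgr_signal(delta, kdata.acq)
    r = rm.forward_encode(x, kdata.coils, kdata.mask) - kdata.f
    return 0.5 * float(np.sum(np.abs(r) ** 2))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "y,beta,expected",
        [(2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5), (0.5, 0.5, 0.0)],
    )
    def test_closed_form(self, y, beta, expected):
        assert soft_threshold(np.array([y]), beta)[0] == expected

    def test_beta_zero_is_identity(self):
        y = np.random.default_rng(0).standard_normal(20)
        np.testing.assert_array_equal(soft_threshold(y, 0.0), y)

    def test_composition_adds_thresholds(self):
        y = np.random.default_rng(1).standard_normal(50) * 3
        a, b = 0.4, 0.7
        np.testing.assert_allclose(
            soft_threshold(soft_threshold(y, a), b),
            soft_threshold(y, a + b),
            atol=1e-15,
        )

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros(3), -0.1)


class TestCoilCombine:
    def test_output_shape_and_finiteness(self):
        model = small_model(n_coils=3, n_flip=2)
        imgs = np.random.default_rng(2).standard_normal((8, 8, 1, 3, 2)) + 0j
        out = coil_combine(imgs, model)
        assert out.shape == (8, 8, 1, 2)
        assert np.iscomplexobj(out)
        assert np.isfinite(coil_combine(np.zeros((8, 8, 1, 3, 2), complex), model)).all()

    def test_wrong_coil_count_rejected(self):
        model = small_model(n_coils=3, n_flip=2)
        with pytest.raises(ValueError):
            coil_combine(np.zeros((8, 8, 1, 5, 2), complex), model)

    def test_deterministic_given_seed(self):
        imgs = np.random.default_rng(3).standard_normal((6, 6, 1, 2, 2)) + 0j
        a = coil_combine(imgs, small_model(n_coils=2, seed=11))
        b = coil_combine(imgs, small_model(n_coils=2, seed=11))
        np.testing.assert_array_equal(a, b)


class TestDeltaInit:
    def test_t1_within_bounds_and_shape(self):
        model = small_model(n_flip=2, t1_min=1.0, t1_max=5000.0)
        combined = (
            np.random.default_rng(4).standard_normal((8, 8, 1, 2)) * 10
        ).astype(complex)
        acq = rm.AcquisitionSpec([10.0, 30.0], 40.0)
        maps, x0 = delta_init(combined, model, acq)
        assert maps.shape == (8, 8, 1)
        assert np.all(maps.t1 >= 1.0) and np.all(maps.t1 <= 5000.0)

    def test_x0_consistent_with_signal_model(self):
        model = small_model(n_flip=2)
        combined = np.random.default_rng(5).standard_normal((6, 6, 1, 2)) + 0j
        acq = rm.AcquisitionSpec([10.0, 30.0], 40.0)
        maps, x0 = delta_init(combined, model, acq)
        np.testing.assert_array_equal(x0, rm.spgr_signal(maps, acq))

    def test_wrong_flip_count_rejected(self):
        model = small_model(n_flip=2)
        acq = rm.AcquisitionSpec([10.0, 20.0, 30.0], 40.0)
        with pytest.raises(ValueError):
            delta_init(np.zeros((6, 6, 1, 3), complex), model, acq)


class TestDataFidelityGradient:
    def test_zero_at_global_minimum(self, tiny_instance):
        truth, kdata = tiny_instance
        g_t1, g_i0 = data_fidelity_gradient(truth, kdata)
        assert np.abs(g_t1).max() < 1e-10
        assert np.abs(g_i0).max() < 1e-10

    def test_zero_for_zero_i0_and_zero_data(self, tiny_instance):
        _, kdata = tiny_instance
        zero_k = rm.KSpaceData(
            np.zeros_like(kdata.f), kdata.mask, kdata.coils, kdata.acq
        )
        delta = rm.ParameterMaps(
            np.full(kdata.grid_shape, 1000.0), np.zeros(kdata.grid_shape, complex)
        )
        g_t1, g_i0 = data_fidelity_gradient(delta, zero_k)
        assert np.abs(g_t1).max() == 0.0
        assert np.abs(g_i0).max() == 0.0

    def test_matches_finite_differences(self, tiny_instance):
        """Central-difference check on a seeded 8x8, 1-coil, 2-FA instance."""
        truth, kdata = tiny_instance
        rng = np.random.default_rng(17)
        delta = rm.ParameterMaps(
            truth.t1 * rng.uniform(0.8, 1.2, truth.shape),
            truth.i0 + 0.3 * (rng.standard_normal(truth.shape)
                              + 1j * rng.standard_normal(truth.shape)),
        )
        g_t1, g_i0 = data_fidelity_gradient(delta, kdata)
        for _ in range(6):
            idx = tuple(rng.integers(s) for s in truth.shape)
            h = 1e-3 * delta.t1[idx]
            for arr, grad, step in (
                (delta.t1, g_t1[idx].real, h),
            ):
                up, dn = delta.t1.copy(), delta.t1.copy()
                up[idx] += step
                dn[idx] -= step
                fd = (
                    fidelity(rm.ParameterMaps(up, delta.i0), kdata)
                    - fidelity(rm.ParameterMaps(dn, delta.i0), kdata)
                ) / (2 * step)
                assert grad == pytest.approx(fd, rel=1e-4)
            h = 1e-5
            for comp, part in ((1.0, "real"), (1j, "imag")):
                up = delta.i0.copy()
                dn = delta.i0.copy()
                up[idx] += comp * h
                dn[idx] -= comp * h
                fd = (
                    fidelity(rm.ParameterMaps(delta.t1, up), kdata)
                    - fidelity(rm.ParameterMaps(delta.t1, dn), kdata)
                ) / (2 * h)
                assert getattr(g_i0[idx], part) == pytest.approx(fd, rel=1e-4)

    def test_multicoil_poisson_gradient_also_matches(self):
        """FD agreement is not specific to the toy single-coil instance."""
        rng = np.random.default_rng(23)
        grid = (8, 8, 1)
        acq = rm.AcquisitionSpec([8.0, 25.0, 40.0], 40.0)
        coils = rm.simulate_coils(grid, 3, seed=9)
        mask = rm.make_poisson_disk_mask(8, 8, 1.5, center_size=2, nk=3, seed=10)
        t1 = rng.uniform(500, 2500, grid)
        i0 = rng.standard_normal(grid) + 1j * rng.standard_normal(grid)
        truth = rm.ParameterMaps(t1, i0)
        f = rm.forward_encode(rm.spgr_signal(truth, acq), coils, mask)
        f += 0.05 * (rng.standard_normal(f.shape) + 1j * rng.standard_normal(f.shape))
        f *= mask.u[:, :, :, None, :]
        kdata = rm.KSpaceData(f, mask, coils, acq)
        g_t1, g_i0 = data_fidelity_gradient(truth, kdata)
        idx = (3, 5, 0)
        h = 1e-3 * t1[idx]
        up, dn = t1.copy(), t1.copy()
        up[idx] += h
        dn[idx] -= h
        fd = (
            fidelity(rm.ParameterMaps(up, i0), kdata)
            - fidelity(rm.ParameterMaps(dn, i0), kdata)
        ) / (2 * h)
        assert g_t1[idx] == pytest.approx(fd, rel=1e-4)

    def test_invalid_t1_rejected(self, tiny_instance):
        _, kdata = tiny_instance
        bad = rm.ParameterMaps(
            np.full(kdata.grid_shape, -5.0), np.ones(kdata.grid_shape, complex)
        )
        with pytest.raises(ValueError):
            data_fidelity_gradient(bad, kdata)


class TestProxStep:
    def test_zero_networks_are_identity(self, tiny_instance):
        truth, _ = tiny_instance
        model = small_model(zero_prox=True)
        out = prox_step(truth, model, phase=0)
        np.testing.assert_allclose(out.t1, np.clip(truth.t1, 1.0, 5000.0), rtol=1e-14)
        np.testing.assert_allclose(out.i0, truth.i0, rtol=1e-14)

    def test_output_shape_matches_input(self, tiny_instance):
        truth, _ = tiny_instance
        out = prox_step(truth, small_model(), phase=1)
        assert out.shape == truth.shape

    def test_saturated_threshold_collapses_features(self, tiny_instance):
        """With beta >> max |D(x)| every feature is zeroed; since the Dtilde
        output layer starts at zero, the step reduces to the identity."""
        truth, _ = tiny_instance
        model = small_model()
        model.log_beta_t1.data[:] = np.log(1e9)
        model.log_beta_i0.data[:] = np.log(1e9)
        out = prox_step(truth, model, phase=0)
        np.testing.assert_allclose(out.t1, np.clip(truth.t1, 1.0, 5000.0), rtol=1e-12)
        np.testing.assert_allclose(out.i0, truth.i0, rtol=1e-12)


class TestReconstruct:
    def test_phase_count(self, tiny_instance):
        _, kdata = tiny_instance
        model = small_model(n_phases=8)
        res = reconstruct(kdata, model)
        assert len(res.delta_per_phase) == 9
        assert len(res.x_per_phase) == 9

    def test_x_invariant_every_phase(self, tiny_instance):
        _, kdata = tiny_instance
        res = reconstruct(kdata, small_model())
        for delta, x in zip(res.delta_per_phase, res.x_per_phase):
            np.testing.assert_allclose(
                x, rm.spgr_signal(delta, kdata.acq), rtol=1e-10, atol=1e-12
            )

    def test_zero_alpha_zero_networks_keep_delta0(self, tiny_instance):
        truth, kdata = tiny_instance
        model = small_model(zero_prox=True, n_phases=4)
        model.log_alpha_t1.data[:] = -np.inf
        model.log_alpha_i0.data[:] = -np.inf
        res = reconstruct(kdata, model, delta0=truth, normalize=False)
        np.testing.assert_allclose(res.final_maps.t1, np.clip(truth.t1, 1, 5000))
        np.testing.assert_allclose(res.final_maps.i0, truth.i0)

    def test_bit_identical_reruns(self, tiny_instance):
        _, kdata = tiny_instance
        model = small_model(seed=33)
        a = reconstruct(kdata, model)
        b = reconstruct(kdata, model)
        np.testing.assert_array_equal(a.final_maps.t1, b.final_maps.t1)
        np.testing.assert_array_equal(a.final_maps.i0, b.final_maps.i0)

    def test_gradient_descent_oracle(self, tiny_instance):
        """Zeroed regularizer networks + supplied delta0 must reproduce an
        independent hand-coded preconditioned gradient-descent loop."""
        truth, kdata = tiny_instance
        rng = np.random.default_rng(29)
        t1 = truth.t1 * rng.uniform(0.9, 1.1, truth.shape)
        i0 = truth.i0 * rng.uniform(0.9, 1.1, truth.shape)
        delta0 = rm.ParameterMaps(t1, i0)
        T = 8
        alpha = 0.05
        model = small_model(zero_prox=True, n_phases=T, alpha0=alpha)
        res = reconstruct(kdata, model, delta0=delta0, normalize=False)

        # independent loop: analytic-free FD gradient of the fidelity
        def fd_grad(delta):
            g_t1 = np.zeros(delta.shape)
            g_re = np.zeros(delta.shape)
            g_im = np.zeros(delta.shape)
            for idx in np.ndindex(*delta.shape):
                h = 1e-2
                for g, comp in ((g_re, 1.0), (g_im, 1j)):
                    up, dn = delta.i0.copy(), delta.i0.copy()
                    up[idx] += comp * h
                    dn[idx] -= comp * h
                    g[idx] = (
                        fidelity(rm.ParameterMaps(delta.t1, up), kdata)
                        - fidelity(rm.ParameterMaps(delta.t1, dn), kdata)
                    ) / (2 * h)
                ht = 1e-2 * delta.t1[idx]
                up, dn = delta.t1.copy(), delta.t1.copy()
                up[idx] += ht
                dn[idx] -= ht
                g_t1[idx] = (
                    fidelity(rm.ParameterMaps(up, delta.i0), kdata)
                    - fidelity(rm.ParameterMaps(dn, delta.i0), kdata)
                ) / (2 * ht)
            return g_t1, g_re + 1j * g_im

        pre = model.t1_scale_ms**2
        cur = rm.ParameterMaps(delta0.t1.copy(), delta0.i0.copy())
        for _ in range(T):
            g_t1, g_i0 = fd_grad(cur)
            t1_new = np.clip(cur.t1 - alpha * pre * g_t1, 1.0, 5000.0)
            i0_new = cur.i0 - alpha * g_i0
            cur = rm.ParameterMaps(t1_new, i0_new)
        np.testing.assert_allclose(res.final_maps.t1, cur.t1, rtol=2e-5)
        np.testing.assert_allclose(res.final_maps.i0, cur.i0, rtol=2e-5)

    def test_model_data_mismatch_rejected(self, tiny_instance):
        _, kdata = tiny_instance
        with pytest.raises(ValueError):
            reconstruct(kdata, small_model(n_coils=4))

    def test_all_zero_kspace_warns_but_runs(self, tiny_instance):
        _, kdata = tiny_instance
        zero = rm.KSpaceData(
            np.zeros_like(kdata.f), kdata.mask, kdata.coils, kdata.acq
        )
        with pytest.warns(UserWarning):
            res = reconstruct(zero, small_model())
        assert np.isfinite(res.final_maps.t1).all()


class TestModelState:
    def test_state_round_trip(self):
        m1 = small_model(seed=1)
        m2 = small_model(seed=2)
        m2.load_state(m1.state())
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_architecture_mismatch_diff(self):
        m1 = small_model(prox_width=4)
        m2 = small_model(prox_width=8)
        with pytest.raises(ValueError, match="d_t1"):
            m2.load_state(m1.state())

    def test_mirror_architecture_enforced(self):
        m = small_model()
        m.dt_t1.widths = [1, 2, 3]
        with pytest.raises(ValueError, match="mirror"):
            m.validate()

    def test_normalization_scale_positive(self, tiny_instance):
        _, kdata = tiny_instance
        assert normalization_scale(kdata) > 0
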