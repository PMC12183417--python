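"""Model families: complex convolution arithmetic, linearity properties,
closed-form GRAPPA calibration, and parameter accounting."""

import numpy as np
import pytest

import cobraki as ck
from cobraki.kspace import kspace_to_image
from cobraki.models import (
    ModelSpec,
    ModelWeights,
    complex_conv,
    conv_valid,
    fit_grappa_tikhonov,
    leaky_relu,
    parameter_count,
    _stack_forward,
)
from cobraki.training import init_weights


class TestLeakyRelu:
    def test_negative_slope(self):
        assert leaky_relu(np.array(-2.0), 0.1) == pytest.approx(-0.2)

    def test_c_one_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(leaky_relu(x, 1.0), x)

    def test_c_zero_is_relu(self):
        np.testing.assert_array_equal(
            leaky_relu(np.array([-3.0, 5.0]), 0.0), [0.0, 5.0]
        )

    def test_complex_split_application(self):
        z = np.array(-1.0 + 2.0j)
        assert leaky_relu(z, 0.5) == pytest.approx(-0.5 + 2.0j)


class TestComplexConv:
    def test_identity_kernel(self, rng):
        z = rng.normal(size=(1, 5, 5)) + 1j * rng.normal(size=(1, 5, 5))
        w = np.ones((1, 1, 1, 1))
        np.testing.assert_allclose(complex_conv(z, w, 0 * w), z)

    def test_imaginary_kernel_rotates_by_i(self, rng):
        z = rng.normal(size=(1, 5, 5)) + 1j * rng.normal(size=(1, 5, 5))
        w = np.ones((1, 1, 1, 1))
        np.testing.assert_allclose(complex_conv(z, 0 * w, w), 1j * z)

    def test_scalar_complex_multiplication(self):
        z = np.full((1, 1, 1), 2.0 + 1.0j)
        wr, wi = np.full((1, 1, 1, 1), 1.0), np.full((1, 1, 1, 1), -1.0)
        # (1 - i)(2 + i) = 3 - i
        assert complex_conv(z, wr, wi)[0, 0, 0] == pytest.approx(3.0 - 1.0j)

    def test_kernel_larger_than_input_rejected(self):
        z = np.zeros((1, 2, 2), dtype=complex)
        w = np.zeros((1, 1, 3, 3))
        with pytest.raises(ValueError):
            complex_conv(z, w, w)


def _random_stack(rng, nc=4, nx=12, nlines=8):
    return rng.normal(size=(nc, nx, nlines)) + 1j * rng.normal(size=(nc, nx, nlines))


def _spec_for(family, nc=4):
    if family == "grappa":
        return ModelSpec.grappa(nc, kernel=(5, 2))
    if family == "rraki":
        return ModelSpec.rraki(nc, d1=4, d2=2, c=1.0)
    return ModelSpec.crraki(nc, d1=4, d2=4, c=1.0)


class TestLinearity:
    @pytest.mark.parametrize("family", ["grappa", "rraki", "crraki"])
    def test_superposition_holds_at_c_one(self, family, rng):
        spec = _spec_for(family)
        if family != "grappa":
            spec = spec.with_linearity(1.0)
        w = init_weights(spec, seed=2)
        s1, s2 = _random_stack(rng), _random_stack(rng)
        a, b = 1.3 - 0.2j, -0.4 + 0.9j
        if spec.family == "rraki":
            a, b = 1.3, -0.4  # real net is linear over real scalars
        f = lambda s: _stack_forward(s, w, spec, mode="valid")[0]
        np.testing.assert_allclose(
            f(a * s1 + b * s2), a * f(s1) + b * f(s2), atol=1e-8
        )

    @pytest.mark.parametrize("family", ["rraki", "crraki"])
    def test_superposition_fails_at_c_zero(self, family, rng):
        spec = _spec_for(family).with_linearity(0.0)
        w = init_weights(spec, seed=2)
        s1, s2 = _random_stack(rng), _random_stack(rng)
        f = lambda s: _stack_forward(s, w, spec, mode="valid")[0]
        err = np.abs(f(s1 + s2) - (f(s1) + f(s2))).max()
        assert err > 1e-4

    def test_crraki_scalar_i_equivariance_at_c_one(self, rng):
        spec = _spec_for("crraki")
        w = init_weights(spec, seed=3)
        s = _random_stack(rng)
        f = lambda x: _stack_forward(x, w, spec, mode="valid")[0]
        np.testing.assert_allclose(f(1j * s), 1j * f(s), atol=1e-8)


class TestResidualArchitecture:
    def test_zero_cnn_reduces_to_short_connection(self, rng):
        spec = ModelSpec.crraki(4, d1=4, d2=4, residual=(1, 1), c=1.0)
        w = init_weights(spec, seed=1)
        for i in range(len(w.layers)):
            w.layers[i] = np.zeros_like(w.layers[i])
        s = _random_stack(rng)
        pred, short, box = _stack_forward(s, w, spec, mode="valid")
        np.testing.assert_allclose(pred, short, atol=1e-12)
        # and the 1x1 residual is a pure complex coil mixture of the input,
        # cropped to the common support of the two paths
        mix = np.einsum("ck,kij->cij", w.residual[:, :, 0, 0], s)
        a0, a1, b0, b1 = box
        np.testing.assert_allclose(short, mix[:, a0:a1, b0:b1], atol=1e-10)

    def test_relu_dead_zone_silences_cnn_path(self):
        spec = ModelSpec.rraki(2, d1=2, d2=2, c=0.0)
        w = init_weights(spec, seed=0)
        # force strongly negative pre-activations in layer 1
        w.layers[0] = -np.abs(w.layers[0]) * 100
        stack = np.ones((2, 8, 8), dtype=complex)  # positive input
        pred, short, _ = _stack_forward(stack, w, spec, mode="valid")
        np.testing.assert_allclose(pred, short, atol=1e-12)

    def test_crraki_equals_real_embedded_rraki(self, rng):
        """A complex network is exactly a real network whose kernels are the
        2x2 real embedding [[Wr, -Wi], [Wi, Wr]] of the complex kernels."""
        nc, c = 4, 0.3
        cspec = ModelSpec.crraki(nc, d1=3, d2=5, residual=(1, 1), c=c)
        cw = init_weights(cspec, seed=7)
        rspec = ModelSpec(
            family="rraki",
            n_coils=nc,
            kernel_sizes=cspec.kernel_sizes,
            depths=tuple((2 * a, 2 * b) for a, b in cspec.depths),
            residual_kernel=cspec.residual_kernel,
            c=c,
        )

        def embed(W):
            top = np.concatenate([W.real, -W.imag], axis=1)
            bot = np.concatenate([W.imag, W.real], axis=1)
            return np.concatenate([top, bot], axis=0)

        rw = ModelWeights(
            layers=[embed(W) for W in cw.layers], residual=embed(cw.residual)
        )
        s = _random_stack(rng, nc=nc)
        pred_c, short_c, _ = _stack_forward(s, cw, cspec, mode="valid")
        pred_r, short_r, _ = _stack_forward(s, rw, rspec, mode="valid")
        np.testing.assert_allclose(pred_r, pred_c, atol=1e-10)
        np.testing.assert_allclose(short_r, short_c, atol=1e-10)


class TestGrappaCalibration:
    def test_large_ridge_shrinks_weights(self, smooth_dataset):
        _, _, full = smooth_dataset
        acs = ck.make_acs(full, 24)
        spec = ModelSpec.grappa(8, kernel=(3, 2))
        w_small = fit_grappa_tikhonov(acs, 2, 1, spec, lambda_reg=1e-6)
        w_huge = fit_grappa_tikhonov(acs, 2, 1, spec, lambda_reg=1e6)
        assert np.linalg.norm(w_huge.residual) < 1e-4 * np.linalg.norm(
            w_small.residual
        )

    def test_matches_dense_normal_equation_oracle(self, rng):
        """Brute-force patch extraction + normal equations on a 3-coil ACS."""
        nc, nxacs, nyacs, R, m = 3, 16, 16, 2, 1
        data = rng.normal(size=(nc, nxacs, nyacs)) + 1j * rng.normal(
            size=(nc, nxacs, nyacs)
        )
        acs = ck.ACSBlock(data)
        nx, ny = 3, 2
        spec = ModelSpec.grappa(nc, kernel=(nx, ny))
        lam = 1e-4
        rows, tgts = [], []
        for y0 in range(nyacs - R * (ny - 1)):
            y_t = y0 + R * ((ny - 1) // 2) + m
            if y_t >= nyacs:
                continue
            for x0 in range(nxacs - nx + 1):
                patch = [
                    data[c, x0 + a, y0 + R * b]
                    for c in range(nc)
                    for a in range(nx)
                    for b in range(ny)
                ]
                rows.append(patch)
                tgts.append([data[c, x0 + (nx - 1) // 2, y_t] for c in range(nc)])
        A, B = np.array(rows), np.array(tgts)
        AhA = A.conj().T @ A
        mu = lam * np.trace(AhA).real / AhA.shape[0]
        expected = np.linalg.solve(AhA + mu * np.eye(AhA.shape[0]), A.conj().T @ B)
        got = fit_grappa_tikhonov(acs, R, m, spec, lambda_reg=lam)
        np.testing.assert_allclose(
            got.residual, expected.T.reshape(nc, nc, nx, ny), atol=1e-10
        )

    def test_exact_interpolation_on_bandlimited_coils(self, oracle_dataset):
        _, _, full = oracle_dataset
        R = 2
        und = ck.undersample(full, R, 1)
        acs = ck.make_acs(full, 24)
        spec = ModelSpec.grappa(4, kernel=(5, 2))
        w = fit_grappa_tikhonov(acs, R, 1, spec, lambda_reg=0.0)
        pred = ck.predict_offset(und, w, spec, 1)
        truth = full.data[:, :, 1::2]
        err = np.linalg.norm(pred[:, :, 1::2] - truth) / np.linalg.norm(truth)
        assert err < 1e-6

    def test_empty_calibration_set_rejected(self):
        acs = ck.ACSBlock(np.zeros((2, 8, 3), dtype=complex))
        spec = ModelSpec.grappa(2, kernel=(3, 4))
        with pytest.raises(ValueError):
            fit_grappa_tikhonov(acs, 4, 1, spec)


class TestParameterCount:
    def test_published_grappa_count(self):
        spec = ModelSpec.grappa(52, kernel=(5, 4))
        assert parameter_count(spec) == 108_160

    def test_published_crraki_count(self):
        spec = ModelSpec.crraki(52)  # [5,2,Nc,16], [1,1,16,32], [3,2,32,Nc], [1,1]
        assert parameter_count(spec) == 43_040

    def test_crraki_more_compact_than_grappa(self):
        assert parameter_count(ModelSpec.crraki(52)) < parameter_count(
            ModelSpec.grappa(52, kernel=(5, 4))
        )

    def test_no_bias_parameters_anywhere(self):
        for spec in (
            ModelSpec.grappa(4),
            ModelSpec.rraki(4),
            ModelSpec.crraki(4),
        ):
            w = init_weights(spec, seed=0)
            arrays = list(w.layers) + [w.residual]
            # every parameter array is a 4-D kernel; nothing 1-D (bias) exists
            assert all(a.ndim == 4 for a in arrays)
            factor = 2 if spec.is_complex else 1
            assert sum(factor * a.size for a in arrays) == parameter_count(spec)


class TestCircularApplication:
    def test_circular_matches_valid_in_interior(self, rng):
        spec = ModelSpec.crraki(4, d1=3, d2=3, c=0.4)
        w = init_weights(spec, seed=4)
        s = _random_stack(rng, nc=4, nx=16, nlines=12)
        pred_v, _, box = _stack_forward(s, w, spec, mode="valid")
        pred_c, _, _ = _stack_forward(s, w, spec, mode="circular")
        a0, a1, b0, b1 = box
        np.testing.assert_allclose(pred_c[:, a0:a1, b0:b1], pred_v, atol=1e-10)
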