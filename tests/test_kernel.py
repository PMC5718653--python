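"""Triple-Gaussian kernel: normalization, convolution, fitting, lookup."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import fftconvolve

import transitdose as td
from transitdose.errors import GridMismatchError, TruncationWarning
from transitdose.kernel import ScatterKernelParams


def blurred_box_profile(half_field, sigma, spacing=0.125, half_width=7.5):
    """1D cut of a square field with Gaussian penumbra (erf closed form)."""
    from scipy.special import erf

    x = spacing * np.arange(-int(half_width / spacing), int(half_width / spacing) + 1)
    vals = 0.5 * (erf((x + half_field) / (np.sqrt(2) * sigma))
                  - erf((x - half_field) / (np.sqrt(2) * sigma)))
    return x, vals


def convolved_cut_2d(x, profile, params):
    """Reference action of a kernel on the separable square field."""
    spacing = x[1] - x[0]
    c = int(np.argmin(np.abs(x)))
    plane = np.outer(profile, profile) / profile[c]
    ker = td.kernel_evaluate(params, spacing)
    return fftconvolve(plane, ker.values, mode="same")[c, :] * spacing**2


class TestKernelEvaluate:
    @pytest.mark.parametrize(
        "params",
        [
            ScatterKernelParams(0.4, 0.0, 2.0, 0.0, 1.0),  # single Gaussian
            ScatterKernelParams(0.4, 0.1, 2.0, 0.05, 1.2),
            ScatterKernelParams(1.0, 0.5, 0.3, 0.2, 3.0),
        ],
    )
    def test_discrete_integral_is_unity(self, params):
        for spacing in (0.2, 0.125):
            ker = td.kernel_evaluate(params, spacing)
            assert abs(ker.values.sum() * spacing**2 - 1.0) < 1e-12

    def test_center_amplitude_and_analytic_mass(self):
        """Center of the normalized kernel times the analytic integral
        π(A² + B·C² + D·E²) recovers 1 + B + D for fine grids — checking the
        formula at r=0 and the Gaussian integral at once."""
        params = ScatterKernelParams(0.5, 0.3, 1.0, 0.1, 2.0)
        spacing = 0.5 / 10  # spacing << A
        ker = td.kernel_evaluate(params, spacing)
        c = ker.values.shape[0] // 2
        got = ker.values[c, c] * params.analytic_integral()
        assert got == pytest.approx(1.0 + params.B + params.D, rel=1e-3)

    def test_truncation_warning_for_small_support(self):
        params = ScatterKernelParams(1.0, 0.0, 1.0, 0.0, 1.0)
        with pytest.warns(TruncationWarning):
            td.kernel_evaluate(params, 0.1, half_width=1.0)

    @given(
        a=st.floats(0.1, 2.0),
        b=st.floats(0.0, 1.0),
        d=st.floats(0.0, 1.0),
    )
    def test_normalization_property(self, a, b, d):
        params = ScatterKernelParams(a, b, 2 * a, d, 3 * a)
        ker = td.kernel_evaluate(params, a / 4)
        assert abs(ker.values.sum() * ker.spacing**2 - 1.0) < 1e-12


class TestConvolve:
    def test_delta_kernel_is_identity(self, uniform_transit):
        out = td.convolve(uniform_transit, td.delta_kernel(uniform_transit.spacing))
        np.testing.assert_allclose(out.values, uniform_transit.values, rtol=1e-12)

    def test_matches_nested_loop_oracle(self):
        """Direct O(n²m²) quadruple-loop convolution on a tiny instance."""
        rng = np.random.default_rng(7)
        plane_vals = rng.uniform(0.0, 5.0, (5, 5))
        kvals = rng.uniform(0.0, 1.0, (3, 3))
        kvals /= kvals.sum() * 0.2**2
        plane = td.DosePlane(plane_vals, 0.2, (-0.4, -0.4), 100.0)
        kernel = td.DosePlane(kvals, 0.2, (-0.2, -0.2), None)

        oracle = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                acc = 0.0
                for ki in range(3):
                    for kj in range(3):
                        ii, jj = i - (ki - 1), j - (kj - 1)
                        if 0 <= ii < 5 and 0 <= jj < 5:
                            acc += plane_vals[ii, jj] * kvals[ki, kj]
                oracle[i, j] = acc * 0.2**2
        out = td.convolve(plane, kernel)
        np.testing.assert_allclose(out.values, oracle, atol=1e-9)

    def test_uniform_interior_unchanged(self, uniform_transit):
        ker = td.kernel_evaluate(ScatterKernelParams(0.4, 0.1, 0.8, 0.0, 0.6),
                                 uniform_transit.spacing)
        out = td.convolve(uniform_transit, ker)
        m = ker.values.shape[0] // 2 + 1
        interior = out.values[m:-m, m:-m]
        np.testing.assert_allclose(interior, 10.0, rtol=1e-9)

    def test_integral_conserved_with_padding(self):
        rng = np.random.default_rng(3)
        core = rng.uniform(0, 2, (21, 21))
        ker = td.kernel_evaluate(ScatterKernelParams(0.3, 0.2, 0.6, 0.0, 0.9), 0.2)
        pad = ker.values.shape[0]
        vals = np.pad(core, pad)
        plane = td.DosePlane(vals, 0.2, (0.0, 0.0), 100.0)
        out = td.convolve(plane, ker)
        assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-6)

    def test_spacing_mismatch_rejected(self, uniform_transit):
        ker = td.delta_kernel(0.125)
        with pytest.raises(GridMismatchError):
            td.convolve(uniform_transit, ker)


class TestFitKernel:
    TRUE = ScatterKernelParams(0.4, 0.1, 2.0, 0.0, 1.0)

    def test_recovers_generating_kernel_action(self):
        """Round trip: reference built with known parameters, fitted kernel's
        action on the profile matches the generator within 0.5% RMS."""
        x, u = blurred_box_profile(2.5, 0.3)
        ref = convolved_cut_2d(x, u, self.TRUE)
        fitted, rms = td.fit_kernel_single(x, u, ref)
        assert rms <= 5e-3
        got = convolved_cut_2d(x, u, fitted)
        c = int(np.argmin(np.abs(x)))
        resid = got / got[c] - ref / ref[c]
        assert np.sqrt(np.mean(resid**2)) <= 5e-3

    def test_identity_target_yields_near_delta(self):
        x, u = blurred_box_profile(2.5, 0.3)
        fitted, _ = td.fit_kernel_single(x, u, u.copy())
        got = convolved_cut_2d(x, u, fitted)
        c = int(np.argmin(np.abs(x)))
        resid = got / got[c] - u / u[c]
        assert np.sqrt(np.mean(resid**2)) < 2e-3

    def test_broader_reference_gives_wider_kernel(self):
        """Depth-like broadening: the fitted second moment grows when the
        reference profile is more smeared."""
        x, u = blurred_box_profile(2.5, 0.3)
        shallow = convolved_cut_2d(x, u, ScatterKernelParams(0.3, 0.1, 0.6, 0.05, 0.9))
        deep = convolved_cut_2d(x, u, ScatterKernelParams(0.8, 0.1, 1.6, 0.05, 2.4))
        k_shallow, _ = td.fit_kernel_single(x, u, shallow)
        k_deep, _ = td.fit_kernel_single(x, u, deep)
        assert k_deep.second_moment() > k_shallow.second_moment()

    def test_mismatched_pairs_rejected(self):
        x, u = blurred_box_profile(2.5, 0.3)
        with pytest.raises(td.errors.InvalidInputError):
            td.fit_kernel([(x, u, 5.0, 10.0)], [(x, u, 3.0, 10.0)])


class TestKernelInterpolate:
    @pytest.fixture()
    def table(self):
        fs = np.array([3.0, 10.0])
        dp = np.array([2.0, 15.0])
        params = np.zeros((2, 2, 5))
        for i, f in enumerate(fs):
            for j, d in enumerate(dp):
                params[i, j] = [0.4 + 0.02 * d, 0.1, 1.0 + 0.05 * f, 0.05, 2.0]
        return td.ScatterTables(fs, dp, np.zeros((2, 2)), params)

    def test_node_exact(self, table):
        got = td.kernel_interpolate(table, 3.0, 2.0)
        np.testing.assert_allclose(got.as_array(), table.kernel_params[0, 0])

    def test_midpoint_linear(self, table):
        got = td.kernel_interpolate(table, 6.5, 8.5)
        expected = table.kernel_params.mean(axis=(0, 1))
        np.testing.assert_allclose(got.as_array(), expected, rtol=1e-12)

    def test_out_of_range_clamps_to_edge(self, table):
        got = td.kernel_interpolate(table, 30.0, 40.0)
        np.testing.assert_allclose(got.as_array(), table.kernel_params[1, 1])
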