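"""Profile metrics and the 2D gamma index."""

import numpy as np
import pytest

import transitdose as td
from transitdose.errors import InvalidReferenceError, OpenFieldEdgeError


def trapezoid_profile(half_field=5.0, ramp=0.4, top=100.0, spacing=0.2, extent=8.0):
    x = np.arange(-extent, extent + spacing / 2, spacing)
    vals = np.clip((half_field + ramp / 2 - np.abs(x)) / ramp, 0.0, 1.0) * top
    return td.Profile(x, vals)


class TestCaxPercentDiff:
    def test_identical_profiles(self):
        p = trapezoid_profile()
        assert td.cax_percent_diff(p, p) == pytest.approx(0.0)

    def test_proportional_scaling(self):
        p = trapezoid_profile()
        q = td.Profile(p.positions, 0.98 * p.doses)
        assert td.cax_percent_diff(q, p) == pytest.approx(-2.0, abs=1e-12)

    def test_interpolated_cax_manual_oracle(self):
        """CAX between samples: hand-interpolated 3-point profiles.

        ref:  (-1, 80), (1, 120)  -> ref(0) = 100
        test: (-1, 90), (1, 120)  -> test(0) = 105  => +5%
        """
        ref = td.Profile([-1.0, 1.0, 2.0], [80.0, 120.0, 120.0])
        tst = td.Profile([-1.0, 1.0, 2.0], [90.0, 120.0, 120.0])
        assert td.cax_percent_diff(tst, ref) == pytest.approx(5.0, abs=1e-12)

    def test_nonpositive_reference_rejected(self):
        ref = td.Profile([-1.0, 1.0], [0.0, 0.0])
        with pytest.raises(InvalidReferenceError):
            td.cax_percent_diff(ref, ref)


class TestFieldEdges:
    def test_symmetric_trapezoid(self):
        p = trapezoid_profile(half_field=5.2, ramp=0.4)
        left, right = td.field_edges_50(p)
        assert left == pytest.approx(-5.2, abs=1e-9)
        assert right == pytest.approx(5.2, abs=1e-9)

    def test_flat_profile_rejected(self):
        p = td.Profile(np.linspace(-5, 5, 11), np.full(11, 50.0))
        with pytest.raises(OpenFieldEdgeError):
            td.field_edges_50(p)

    def test_asymmetric_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        x = np.linspace(-8, 8, 81)
        vals = 100.0 * np.exp(-((x - 0.7) ** 4) / 300.0) + rng.uniform(0, 1, x.size)
        p = td.Profile(x, vals)
        left, right = td.field_edges_50(p)

        half = p.at(0.0) / 2.0
        crossings = []
        for i in range(x.size - 1):
            lo, hi = vals[i], vals[i + 1]
            if (lo - half) * (hi - half) < 0 or lo == half:
                t = (half - lo) / (hi - lo)
                crossings.append(x[i] + t * (x[i + 1] - x[i]))
        assert left == pytest.approx(min(c for c in crossings if c < 0), abs=1e-9)
        assert right == pytest.approx(max(c for c in crossings if c > 0), abs=1e-9)


class TestAverageDifference:
    def test_identical(self):
        p = trapezoid_profile()
        mean, sd = td.average_difference(p, p)
        assert mean == 0.0 and sd == 0.0

    def test_uniform_offset(self):
        p = trapezoid_profile()
        q = td.Profile(p.positions, 1.02 * p.doses)
        mean, sd = td.average_difference(q, p)
        assert mean == pytest.approx(2.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_five_point_hand_computation(self):
        """Differences {+1, −1, +2, 0, +3}% → mean 1.0, sample SD √2.5.

        The reference carries penumbra ramps so its 50% edges sit at ±2.5 and
        exactly the five plateau points enter the average.
        """
        x = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        ref = td.Profile(x, np.array([0.0, 100.0, 100.0, 100.0, 100.0, 100.0, 0.0]))
        tst = td.Profile(x, np.array([0.0, 101.0, 99.0, 102.0, 100.0, 103.0, 0.0]))
        mean, sd = td.average_difference(tst, ref)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert sd == pytest.approx(np.sqrt(2.5), abs=1e-12)


def gamma_brute_force(test, reference, dose_pct, dta_mm, norm_dose, step_cm=0.01,
                      radius_factor=3.0):
    """Exhaustive 0.1 mm-step gamma search oracle (slow; tiny planes only)."""
    dta = dta_mm / 10.0
    dcrit = dose_pct / 100.0 * norm_dose
    radius = radius_factor * dta
    n = int(round(radius / step_cm))
    offs = step_cm * np.arange(-n, n + 1)  # contains exactly 0.0
    dxg, dyg = np.meshgrid(offs, offs)
    keep = dxg**2 + dyg**2 <= radius**2 + 1e-12
    dx, dy = dxg[keep], dyg[keep]
    dist2 = (dx**2 + dy**2) / dta**2
    out = np.zeros(reference.values.shape)
    for i, y in enumerate(reference.y):
        for j, x in enumerate(reference.x):
            tvals = test.sample(x + dx, y + dy)
            g2 = ((tvals - reference.values[i, j]) / dcrit) ** 2 + dist2
            out[i, j] = np.sqrt(g2.min())
    return out


class TestGammaIndex:
    def test_self_comparison(self, uniform_transit):
        res = td.gamma_index(uniform_transit, uniform_transit)
        assert res.pass_rate == 100.0
        np.testing.assert_allclose(res.gamma_map, 0.0, atol=1e-12)

    def test_uniform_three_percent_offset_passes_at_exactly_one(self):
        plane = td.centered_plane(2.0, 0.2, 100.0)
        ref = plane.with_values(np.full(plane.shape, 100.0))
        tst = plane.with_values(np.full(plane.shape, 103.0))
        res = td.gamma_index(tst, ref, dose_pct=3.0, dta_mm=3.0)
        assert res.pass_rate == 100.0
        np.testing.assert_allclose(res.gamma_map, 1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        """Shifted + rescaled + smoothly modulated test plane: the sub-grid
        search agrees with an exhaustive 0.1 mm search within 0.05."""
        grid = td.centered_plane(1.0, 0.2, 100.0)
        x = grid.x
        xx, yy = x[None, :], x[:, None]
        ref = grid.with_values(100.0 * np.exp(-(xx**2 + yy**2) / 8.0))
        tst_vals = (102.0 * np.exp(-((xx - 0.08) ** 2 + (yy + 0.05) ** 2) / 8.0)
                    * (1.0 + 0.02 * np.sin(2.0 * xx) * np.cos(1.5 * yy)))
        tst = grid.with_values(tst_vals)
        res = td.gamma_index(tst, ref, norm="global-value", norm_value=100.0)
        oracle = gamma_brute_force(tst, ref, 3.0, 3.0, 100.0)
        assert np.max(np.abs(res.gamma_map - oracle)) <= 0.05

    def test_step_edge_translated_by_exactly_dta(self):
        """An edge moved by exactly the DTA stays at γ <= 1 everywhere."""
        grid = td.centered_plane(2.0, 0.1, 100.0)
        x = grid.x
        ref = grid.with_values(np.broadcast_to(100.0 * (x >= 0.0), grid.shape).copy())
        tst = grid.with_values(np.broadcast_to(100.0 * (x >= 0.3), grid.shape).copy())
        res = td.gamma_index(tst, ref, dose_pct=3.0, dta_mm=3.0,
                             norm="global-value", norm_value=100.0,
                             low_dose_pct=0.0)
        assert res.gamma_map.max() <= 1.0 + 1e-9
        assert res.pass_rate == 100.0

    def test_refining_search_never_increases_gamma(self):
        rng = np.random.default_rng(9)
        grid = td.centered_plane(1.0, 0.2, 100.0)
        base = 50.0 + 10.0 * rng.standard_normal(grid.shape)
        ref = grid.with_values(np.abs(base))
        tst = grid.with_values(np.abs(base + rng.standard_normal(grid.shape)))
        # step factors chosen so the fine offset lattice nests the coarse one
        coarse = td.gamma_index(tst, ref, step_factor=0.1)
        fine = td.gamma_index(tst, ref, step_factor=0.05)
        assert np.all(fine.gamma_map <= coarse.gamma_map + 1e-12)

    def test_pass_rate_invariant_under_common_rescaling(self, conformal_config):
        cfg = conformal_config
        ref = td.ground_truth_plane(cfg, 10.0)
        rng = np.random.default_rng(4)
        tst = ref.with_values(ref.values * (1.0 + 0.02 * rng.standard_normal(ref.shape)))
        a = td.gamma_index(tst, ref)
        b = td.gamma_index(tst.with_values(5.0 * tst.values),
                           ref.with_values(5.0 * ref.values))
        assert a.pass_rate == pytest.approx(b.pass_rate, abs=1e-12)

    def test_zero_normalization_rejected(self, uniform_transit):
        zero = uniform_transit.with_values(np.zeros(uniform_transit.shape))
        with pytest.raises(InvalidReferenceError):
            td.gamma_index(uniform_transit, zero)
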