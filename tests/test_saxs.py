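"""Debye scattering, chi-square fitting, Guinier/P(r)/Dmax diagnostics,
and the benchmark noise model."""

import numpy as np
import pytest

from rnasaxs import geometry as geo
from rnasaxs.saxs import (NoiseParams, SaxsError, ScatteringCurve, chi2_fit,
                          debye_intensity, dmax_from_model, guinier_fit,
                          pr_from_model, read_saxs_dat, rg_from_model,
                          simulate_benchmark_curve, write_saxs_dat)


def brute_force_debye(coords, f, q):
    out = np.zeros_like(q)
    for k, qq in enumerate(q):
        s = 0.0
        for i in range(len(coords)):
            for j in range(len(coords)):
                d = np.linalg.norm(coords[i] - coords[j])
                s += f[i] * f[j] * (np.sinc(qq * d / np.pi))
        out[k] = s
    return out


QGRID = np.linspace(0.0, 0.5, 40)


class TestDebye:
    def test_single_scatterer_is_flat(self):
        curve = debye_intensity(np.zeros((1, 3)), QGRID)
        assert np.allclose(curve.I, 1.0)

    def test_two_scatterers_closed_form(self):
        d = 7.3
        coords = np.array([[0.0, 0, 0], [0, 0, d]])
        curve = debye_intensity(coords, QGRID)
        expected = 2 * (1 + np.sinc(QGRID * d / np.pi))
        assert np.allclose(curve.I, expected, rtol=1e-12)

    def test_zero_angle_is_total_weight_squared(self, rng):
        coords = rng.normal(size=(17, 3)) * 10
        curve = debye_intensity(coords, np.array([0.0]))
        assert curve.I[0] == pytest.approx(17.0 ** 2)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.normal(size=(20, 3)) * 12
        f = np.ones(20)
        curve = debye_intensity(coords, QGRID)
        assert np.allclose(curve.I, brute_force_debye(coords, f, QGRID),
                           rtol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3)) * 8
        rot = geo.rotation_about_axis(np.array([1.0, 2, 3]), 1.1)
        moved = coords @ rot.T + np.array([5.0, -3, 9])
        assert np.allclose(debye_intensity(coords, QGRID).I,
                           debye_intensity(moved, QGRID).I, rtol=1e-9)

    def test_binned_approximation_close_to_exact(self, rng):
        coords = rng.normal(size=(50, 3)) * 10
        exact = debye_intensity(coords, QGRID).I
        approx = debye_intensity(coords, QGRID, bin_width=0.05).I
        assert np.allclose(approx, exact, rtol=2e-3)

    def test_empty_model_rejected(self):
        with pytest.raises(SaxsError):
            debye_intensity(np.empty((0, 3)), QGRID)


class TestChi2:
    def _curve(self, rng, n=80):
        q = np.linspace(0.01, 0.5, n)
        intensity = 100 * np.exp(-(q * 15) ** 2 / 3)
        return ScatteringCurve(q, intensity, 0.02 * intensity)

    def test_exact_match_gives_zero(self, rng):
        exp = self._curve(rng)
        fit = chi2_fit(exp, exp)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
        assert fit.scale == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        exp = self._curve(rng)
        theor = ScatteringCurve(exp.q, 3.7 * exp.I, exp.sigma)
        fit = chi2_fit(exp, theor)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
        assert fit.scale == pytest.approx(1 / 3.7)
        for k in (0.1, 2.0, 41.0):
            scaled = ScatteringCurve(exp.q, k * exp.I, exp.sigma)
            assert chi2_fit(exp, scaled).chi2 == pytest.approx(0.0, abs=1e-18)

    def test_chi2_near_one_under_own_noise(self, rng):
        clean = self._curve(rng, n=400)
        noisy = ScatteringCurve(
            clean.q, clean.I + rng.normal(size=len(clean)) * clean.sigma,
            clean.sigma)
        fit = chi2_fit(noisy, clean)
        assert abs(fit.chi2 - 1.0) < 3 / np.sqrt(len(clean))

    def test_input_validation(self):
        one = ScatteringCurve(np.array([0.1]), np.array([1.0]), np.array([1.0]))
        with pytest.raises(SaxsError):
            chi2_fit(one, one)
        bad = ScatteringCurve(np.linspace(0, 1, 5), np.ones(5), np.zeros(5))
        with pytest.raises(SaxsError):
            chi2_fit(bad, bad)


class TestGuinierAndShape:
    def test_recovers_exact_guinier_law(self):
        q = np.linspace(0.0, 0.3, 150)
        rg = 20.0
        curve = ScatteringCurve(q, 100 * np.exp(-(q * rg) ** 2 / 3),
                                np.ones_like(q))
        res = guinier_fit(curve)
        assert res.rg == pytest.approx(20.0, abs=0.1)
        assert res.i0 == pytest.approx(100.0, rel=0.01)

    def test_guinier_consistent_with_model_rg(self, two_helix_system):
        _, native, _, _ = two_helix_system
        curve = debye_intensity(native, np.linspace(0.0, 0.3, 200),
                                )
        res = guinier_fit(curve)
        assert res.rg == pytest.approx(rg_from_model(native), rel=0.05)

    def test_rg_of_two_point_dumbbell(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert rg_from_model(coords) == pytest.approx(5.0)

    def test_rg_rigid_invariance(self, two_helix_system):
        _, native, _, _ = two_helix_system
        rot = geo.rotation_about_axis(np.array([1.0, 1, 0]), 0.7)
        moved = native.copy()
        moved.coords = native.coords @ rot.T + 4.0
        assert rg_from_model(moved) == pytest.approx(rg_from_model(native))
        assert dmax_from_model(moved) == pytest.approx(dmax_from_model(native))

    def test_dmax_examples_and_oracle(self, rng):
        coords = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        assert dmax_from_model(coords) == pytest.approx(8.0)
        pts = rng.normal(size=(100, 3)) * 10
        brute = max(np.linalg.norm(a - b) for a in pts for b in pts)
        assert dmax_from_model(pts) == pytest.approx(brute)

    def test_pr_properties(self, rng):
        coords = np.array([[0.0, 0, 0], [0, 0, 6.3]])
        r, p = pr_from_model(coords, bin_width=1.0)
        assert p.sum() == pytest.approx(2.0)  # 2 * f_i f_j
        occupied = r[p > 0]
        assert len(occupied) == 1 and abs(occupied[0] - 6.3) < 1.0
        pts = rng.normal(size=(40, 3)) * 10
        r, p = pr_from_model(pts, bin_width=2.0)
        assert np.all(p >= 0)
        dmax = dmax_from_model(pts)
        assert np.all(r[p > 0] <= dmax + 2.0)
        assert p.sum() == pytest.approx(40 * 40 - 40)


class TestNoiseModel:
    def test_zero_noise_is_exact(self, stemloop_native):
        _, native = stemloop_native
        clean = debye_intensity(native, np.linspace(0, 0.5, 50))
        sim = simulate_benchmark_curve(native, n_points=50, q_max=0.5,
                                       noise=NoiseParams(0.0, 0.0, 1))
        assert np.allclose(sim.I, clean.I)

    def test_noise_law_standardized_residuals(self, stemloop_native):
        """sigma_sim = sqrt[(2% I)^2 + (5% min I)^2]; standardized residuals
        over many replicate points are standard normal."""
        _, native = stemloop_native
        clean = debye_intensity(native, np.linspace(0, 0.5, 200))
        resid = []
        for seed in range(10):
            sim = simulate_benchmark_curve(native, n_points=200,
                                           noise=NoiseParams(seed=seed))
            expected_sigma = np.sqrt((0.02 * clean.I) ** 2
                                     + (0.05 * clean.I.min()) ** 2)
            assert np.allclose(sim.sigma, expected_sigma)
            resid.extend((sim.I - clean.I) / sim.sigma)
        resid = np.asarray(resid)
        assert len(resid) >= 1000
        assert abs(resid.mean()) < 0.05
        assert abs(resid.std() - 1.0) < 0.1

    def test_same_seed_reproducible(self, stemloop_native):
        _, native = stemloop_native
        a = simulate_benchmark_curve(native, noise=NoiseParams(seed=9))
        b = simulate_benchmark_curve(native, noise=NoiseParams(seed=9))
        assert np.array_equal(a.I, b.I)


class TestDatFiles:
    def test_three_column_roundtrip(self, tmp_path):
        q = np.linspace(0.01, 0.5, 20)
        curve = ScatteringCurve(q, np.exp(-q), 0.01 * np.exp(-q))
        path = tmp_path / "toy.dat"
        write_saxs_dat(path, curve, header="toy")
        back = read_saxs_dat(path)
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.I, curve.I)
        assert np.allclose(back.sigma, curve.sigma)

    def test_comments_skipped_and_two_columns_imputed(self, tmp_path):
        path = tmp_path / "two.dat"
        path.write_text("# header\n0.01 100.0\n0.02 90.0\n# trailing\n")
        curve = read_saxs_dat(path)
        assert len(curve) == 2
        assert np.allclose(curve.sigma, [1.0, 0.9])

    def test_descending_q_sorted(self, tmp_path):
        path = tmp_path / "desc.dat"
        path.write_text("0.3 1.0 0.1\n0.1 3.0 0.1\n0.2 2.0 0.1\n")
        curve = read_saxs_dat(path)
        assert np.all(np.diff(curve.q) > 0)
        assert np.allclose(curve.I, [3.0, 2.0, 1.0])

    def test_bad_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.01 1.0 0.1\nnot numbers here\n")
        with pytest.raises(SaxsError, match=":2"):
            read_saxs_dat(path)
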