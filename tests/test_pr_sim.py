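"""Ray tracing, Bragg-curve construction, range mixing, and PR simulation."""

import dataclasses

import numpy as np
import pytest

from prorad.calibration import default_curve, hu_to_rsp
from prorad.pr_sim import (
    BeamConfig,
    IddCurve,
    Ray,
    apply_range_mixing,
    compute_wet,
    pristine_idd,
    simulate_pr,
    spot_idd_from_wet,
)

from conftest import make_slab_ct


class TestPristineIdd:
    def test_peak_at_water_range(self, desk_beam):
        idd = pristine_idd(desk_beam)
        assert abs(idd.peak_depth_mm - desk_beam.water_range_r0_mm) <= desk_beam.depth_step_mm
        assert idd.dose.max() == pytest.approx(1.0)

    def test_distal_falloff(self, desk_beam):
        idd = pristine_idd(desk_beam)
        r0 = desk_beam.water_range_r0_mm
        assert np.interp(r0 + 20.0, idd.z, idd.dose) < 0.01

    def test_entrance_plateau_below_peak(self, desk_beam):
        idd = pristine_idd(desk_beam)
        assert 0.0 < idd.dose[0] < 0.5

    def test_strictly_unimodal(self, desk_beam):
        idd = pristine_idd(desk_beam)
        k = int(np.argmax(idd.dose))
        assert np.all(np.diff(idd.dose[: k + 1]) > 0)
        assert np.all(np.diff(idd.dose[k:][idd.dose[k:] > 1e-12]) < 0)


class TestComputeWet:
    def test_water_slab_closed_form(self, curve):
        ct = make_slab_ct([(100.0, 0.0)])
        ray = Ray((-5.0, 32.0, 32.0), (1.0, 0.0, 0.0))
        assert compute_wet(ct, curve, ray) == pytest.approx(100.0, abs=1e-9)

    def test_soft_plus_bone_slabs(self, curve):
        # 50 mm at rsp 1.02 plus 20 mm at rsp 1.40 -> 79.0 mm water
        ct = make_slab_ct([(50.0, 30.0), (20.0, 700.0)])
        ray = Ray((-5.0, 32.0, 32.0), (1.0, 0.0, 0.0))
        assert compute_wet(ct, curve, ray) == pytest.approx(79.0, abs=1e-9)

    def test_air_ray_near_zero(self, curve, phantom):
        ray = Ray((-5.0, 2.0, 2.0), (1.0, 0.0, 0.0))
        assert compute_wet(ct=phantom, curve=curve, ray=ray) < 0.5

    def test_miss_returns_zero(self, curve, phantom):
        ray = Ray((-5.0, -50.0, 2.0), (1.0, 0.0, 0.0))
        assert compute_wet(phantom, curve, ray) == 0.0

    def test_oblique_ray_through_slab(self, curve):
        # 45-degree ray through a 100 mm water slab: path length 100*sqrt(2)
        ct = make_slab_ct([(100.0, 0.0)], ny=128)
        ray = Ray((-1.0, 19.0, 32.0), (1.0, 1.0, 0.0))
        w = compute_wet(ct, curve, ray)
        assert w == pytest.approx(100.0 * np.sqrt(2.0), rel=1e-6)

    def test_matches_dense_quadrature_on_random_rays(self, curve, phantom):
        """Siddon traversal vs 0.01 mm Riemann quadrature, 50 random rays."""
        rng = np.random.default_rng(42)
        origin = np.asarray(phantom.origin_mm)
        spacing = np.asarray(phantom.spacing_mm)
        extent = np.asarray(phantom.extent_mm)
        for _ in range(50):
            target = origin + extent * rng.uniform(0.25, 0.75, 3)
            entry = origin + np.array(
                [-5.0, rng.uniform(0, extent[1]), rng.uniform(0, extent[2])]
            )
            d = target - entry
            ray = Ray(tuple(entry), tuple(d))
            w = compute_wet(phantom, curve, ray)

            d = d / np.linalg.norm(d)
            step = 0.01
            t = np.arange(0.0, np.linalg.norm(extent) + 10.0, step)
            pts = entry[None, :] + t[:, None] * d[None, :]
            idx = np.floor((pts - origin) / spacing).astype(int)
            inside = np.all((idx >= 0) & (idx < phantom.hu.shape), axis=1)
            hu = phantom.hu[tuple(idx[inside].T)].astype(float)
            w_ref = float(np.sum(hu_to_rsp(curve, hu)) * step)
            assert w == pytest.approx(w_ref, abs=0.1)


class TestSpotIdd:
    def test_zero_wet_is_identity(self, desk_beam):
        p = pristine_idd(desk_beam)
        out = spot_idd_from_wet(0.0, p)
        np.testing.assert_allclose(out.dose, p.dose)

    def test_wet_shifts_peak_proximally(self, desk_beam):
        p = pristine_idd(desk_beam)
        out = spot_idd_from_wet(30.0, p)
        assert out.peak_depth_mm == pytest.approx(
            desk_beam.water_range_r0_mm - 30.0, abs=desk_beam.depth_step_mm
        )

    def test_wet_difference_moves_peaks_apart(self, desk_beam):
        p = pristine_idd(desk_beam)
        a = spot_idd_from_wet(40.0, p)
        b = spot_idd_from_wet(45.0, p)
        assert a.peak_depth_mm - b.peak_depth_mm == pytest.approx(
            5.0, abs=desk_beam.depth_step_mm
        )

    def test_shoot_through_warns_and_zeroes(self, desk_beam):
        p = pristine_idd(desk_beam)
        with pytest.warns(UserWarning, match="shoot-through"):
            out = spot_idd_from_wet(1000.0, p)
        assert out.dose.max() == 0.0


class TestRangeMixing:
    def _grids(self, n=21, pitch=2.0):
        coords = np.arange(n) * pitch
        return coords, coords

    def test_uniform_field_equals_unmixed(self, desk_beam):
        u, v = self._grids()
        fine = np.full((v.size, u.size), 55.0)
        spots_u, spots_v = u[8:13], v[8:13]
        p = pristine_idd(desk_beam)
        curves = apply_range_mixing(fine, u, v, spots_u, spots_v, desk_beam, p)
        expected = spot_idd_from_wet(55.0, p)
        for c in curves:
            np.testing.assert_allclose(c.dose, expected.dose, atol=1e-12)

    def test_sigma_zero_degenerates_to_spot_curve(self, desk_beam):
        cfg = dataclasses.replace(desk_beam, mixing_sigma_mm=0.0)
        u, v = self._grids()
        rng = np.random.default_rng(0)
        fine = rng.uniform(20, 80, (v.size, u.size))
        p = pristine_idd(cfg)
        curves = apply_range_mixing(fine, u, v, u[10:11], v[10:11], cfg, p)
        expected = spot_idd_from_wet(float(fine[10, 10]), p)
        np.testing.assert_allclose(curves[0].dose, expected.dose, atol=1e-12)

    def test_half_plane_step_gives_bimodal_two_curve_mixture(self, desk_beam):
        """A spot at a w step boundary sees a bimodal mixture of exactly the
        two shifted curves, weighted by the Gaussian mass on each side."""
        u, v = self._grids(n=41)
        w1, w2 = 40.0, 70.0
        pitch = 2.0
        fine = np.where(np.arange(41)[None, :] <= 20, w1, w2) * np.ones((41, 1))
        p = pristine_idd(desk_beam)
        curves = apply_range_mixing(fine, u, v, u[20:21], v[20:21], desk_beam, p)

        # Gaussian mass of the member columns on each side of the step
        sigma = desk_beam.mixing_sigma_mm
        reach = int(np.ceil(3 * sigma / pitch))
        offs = np.arange(-reach, reach + 1)
        dv, du = np.meshgrid(offs, offs, indexing="ij")
        d2 = (dv**2 + du**2) * pitch**2
        keep = d2 <= (3 * sigma) ** 2
        wgt = np.exp(-d2[keep] / (2 * sigma**2))
        alpha = wgt[du[keep] <= 0].sum() / wgt.sum()
        expected = alpha * spot_idd_from_wet(w1, p).dose + (1 - alpha) * spot_idd_from_wet(w2, p).dose
        np.testing.assert_allclose(curves[0].dose, expected, atol=1e-6)

        # bimodal: a local maximum near each of the two shifted Bragg peaks
        r0 = desk_beam.water_range_r0_mm
        d = curves[0].dose
        for w in (w1, w2):
            k = int(round(r0 - w))
            lo, hi = k - 5, k + 5
            kk = lo + int(np.argmax(d[lo:hi]))
            assert d[kk] >= d[kk - 1] and d[kk] >= d[kk + 1]
            assert d[kk] > 1.2 * d[int(r0 - (w1 + w2) / 2)]  # valley between peaks

    def test_mixing_conserves_dose_area(self, desk_beam):
        """Area under the mixed curve = Gaussian-weighted mean of member areas."""
        u, v = self._grids(n=31)
        rng = np.random.default_rng(3)
        fine = rng.uniform(30, 60, (v.size, u.size))
        p = pristine_idd(desk_beam)
        curves = apply_range_mixing(fine, u, v, u[15:16], v[15:16], desk_beam, p)

        sigma, pitch = desk_beam.mixing_sigma_mm, 2.0
        reach = int(np.ceil(3 * sigma / pitch))
        offs = np.arange(-reach, reach + 1)
        dv, du = np.meshgrid(offs, offs, indexing="ij")
        d2 = (dv**2 + du**2) * pitch**2
        keep = d2 <= (3 * sigma) ** 2
        wgt = np.exp(-d2[keep] / (2 * sigma**2))
        wgt /= wgt.sum()
        areas = [
            np.trapezoid(spot_idd_from_wet(fine[15 + a, 15 + b], p).dose, p.z)
            for a, b in zip(dv[keep], du[keep])
        ]
        expected = float(np.sum(wgt * np.asarray(areas)))
        got = float(np.trapezoid(curves[0].dose, p.z))
        assert got == pytest.approx(expected, rel=1e-9)


class TestSimulatePr:
    def test_deterministic(self, phantom, curve, desk_beam):
        a = simulate_pr(phantom, curve, desk_beam)
        b = simulate_pr(phantom, curve, desk_beam)
        np.testing.assert_array_equal(a.wet_mm, b.wet_mm)

    def test_spot_count_formula(self):
        assert BeamConfig().n_spots() == (261, 261)
        assert BeamConfig.desk().n_spots() == (33, 33)

    def test_fast_path_matches_siddon_per_ray(self, phantom, curve, desk_beam):
        pr = simulate_pr(phantom, curve, desk_beam)
        for iv, iu in [(16, 16), (10, 20), (25, 8)]:
            ray = Ray(
                (-5.0, float(pr.spot_v_mm[iv]), float(pr.spot_u_mm[iu])),
                (1.0, 0.0, 0.0),
            )
            w = compute_wet(phantom, curve, ray)
            assert pr.wet_mm[iv, iu] == pytest.approx(w, abs=1e-6)

    def test_translation_equivariance_on_grid_multiples(self, phantom, curve, desk_beam):
        """A setup shift by whole fine-grid steps equals shifting the WET field."""
        pitch = max(phantom.spacing_mm[1], 1.0)
        pr0 = simulate_pr(phantom, curve, desk_beam)
        pr1 = simulate_pr(phantom, curve, desk_beam, shift=(2 * pitch, pitch))
        f0 = pr0.fine_wet_mm
        f1 = pr1.fine_wet_mm
        # interior region unaffected by edge fill
        np.testing.assert_allclose(f1[5:-5, 5:-5], f0[7:-3, 6:-4], atol=1e-9)

    def test_uniform_cylinder_constant_wet(self, curve, desk_beam):
        ct = make_slab_ct([(120.0, 0.0)], ny=64, nz=64)
        pr = simulate_pr(ct, curve, desk_beam)
        inside = pr.wet_mm[pr.wet_mm > 0]
        assert np.allclose(inside, 120.0, atol=1e-9)

    def test_h5_round_trip(self, tmp_path, phantom, curve, desk_beam):
        pr = simulate_pr(phantom, curve, desk_beam)
        pr.save_h5(tmp_path / "pr.h5")
        from prorad.pr_sim import PrImage

        back = PrImage.load_h5(tmp_path / "pr.h5")
        np.testing.assert_allclose(back.wet_mm, pr.wet_mm, atol=1e-5)
        assert back.cfg.spot_spacing_mm == desk_beam.spot_spacing_mm
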