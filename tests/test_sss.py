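"""Single scatter simulation: estimator, up-sampling, tail fit."""

import numpy as np
import pytest

import petchain.physics as physics
from petchain.corrections import EstimationError
from petchain.geometry import build_scanner, desk_layout
from petchain.phantoms import MATERIAL_NAMES, PhantomSpec, VoxelPhantom, build_phantom
from petchain.recon import ImageGrid, ReconImage
from petchain.sss import (MU_SCATTER_POINT_MIN, coarse_detectors,
                          downsample_to_coarse, _efficiency_table,
                          fit_scatter_tails, sss_scatter_estimate,
                          upsample_scatter)


def _sphere_phantom(radius_mm, emission_radius_mm=0.0, voxel=4.0):
    n = int(2 * (radius_mm + 12) / voxel)
    xs = (np.arange(n) + 0.5) * voxel - n * voxel / 2
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= radius_mm**2
    mu = np.where(inside, 0.0958, 0.0).astype(np.float32)
    act = np.zeros_like(mu)
    if emission_radius_mm > 0:
        act[X**2 + Y**2 + Z**2 <= emission_radius_mm**2] = 1.0
    mat = np.where(inside, MATERIAL_NAMES.index("water"), 0).astype(np.uint8)
    origin = np.full(3, -n * voxel / 2)
    return VoxelPhantom(act, mat, mu, voxel, origin)


class TestEstimate:
    def test_zero_emission_zero_scatter(self, model, rng):
        ph = _sphere_phantom(60.0, emission_radius_mm=0.0)
        grid = ImageGrid(*ph.shape, ph.voxel_size, ph.voxel_size)
        coarse, meta = sss_scatter_estimate(
            ReconImage(ph.activity.astype(float), grid), ph, model, rng,
            include_liner=False)
        assert np.all(coarse == 0.0)

    def test_mu_threshold_excludes_faint_cells(self, model, rng):
        ph = _sphere_phantom(60.0, emission_radius_mm=20.0)
        ph.mu_511[ph.mu_511 > 0] = 0.03  # below the 0.04 cm^-1 cut
        grid = ImageGrid(*ph.shape, ph.voxel_size, ph.voxel_size)
        coarse, meta = sss_scatter_estimate(
            ReconImage(ph.activity.astype(float), grid), ph, model, rng,
            include_liner=False)
        assert meta["n_points"] == 0

    def test_azimuthal_symmetry(self, model, rng):
        """A centred cylindrical phantom yields an azimuthally uniform
        scatter estimate up to sampling noise."""
        spec = PhantomSpec(kind="uniform_cylinder", body_half_axes=(90.0, 90.0),
                           body_length=160.0, background_concentration=5.0,
                           wall_thickness=0.0, couch=False)
        ph = build_phantom(spec, voxel_size=4.0)
        grid = ImageGrid(*ph.shape, ph.voxel_size, ph.voxel_size)
        coarse, meta = sss_scatter_estimate(
            ReconImage(ph.activity.astype(float), grid), ph, model, rng,
            include_liner=False)
        prof = coarse.sum(axis=(0, 2))
        assert prof.std() / prof.mean() < 0.1

    def test_against_analytic_double_integration(self, model):
        """Jittered coarse-cell sampling with marched ray sums agrees with
        a deterministic fine-grid double integration using analytic
        sphere chords, within 2% in total (point-like source at the
        centre of a uniform water sphere)."""
        R = 80.0
        r_emis = 22.0
        ph = _sphere_phantom(R, emission_radius_mm=r_emis, voxel=4.0)
        grid = ImageGrid(*ph.shape, ph.voxel_size, ph.voxel_size)
        oracle = _oracle_total(model, ph, R, r_emis)
        # deterministic cell-centre evaluation isolates the estimator's
        # discretisation (march + binning) from sampling noise
        rng = np.random.default_rng(99)
        coarse, meta = sss_scatter_estimate(
            ReconImage(ph.activity.astype(float), grid), ph, model, rng,
            include_liner=False, n_march=96, jitter=False)
        assert meta["sampled"].sum() == pytest.approx(oracle, rel=0.02)
        # the jittered estimator fluctuates around the same value (the
        # emission blob spans only a few coarse cells here)
        rng = np.random.default_rng(99)
        coarse_j, meta_j = sss_scatter_estimate(
            ReconImage(ph.activity.astype(float), grid), ph, model, rng,
            include_liner=False, n_march=96)
        assert meta_j["sampled"].sum() == pytest.approx(oracle, rel=0.08)


def _oracle_total(model, ph, R, r_emis):
    """Independent SSS total: subdivide the supported coarse cells into a
    deterministic fine grid and evaluate the two scatter terms with exact
    (Siddon) path integrals through the coarse emission and attenuation
    model -- no jitter, no fixed-step marching."""
    extent = (700.0, 700.0, model.axial_extent)
    mu_c, cell = downsample_to_coarse(ph.mu_511, ph.origin, ph.voxel_size,
                                      (32, 32, 4), extent)
    lam_c, _ = downsample_to_coarse(ph.activity, ph.origin, ph.voxel_size,
                                    (32, 32, 4), extent)
    support = np.argwhere(mu_c >= MU_SCATTER_POINT_MIN)
    ext_half = np.asarray(extent) / 2.0
    # subdivide each supported cell 3x3x3
    sub = (np.stack(np.meshgrid(*[np.arange(3)] * 3, indexing="ij"), -1)
           .reshape(-1, 3) + 0.5) / 3.0
    pts = ((support[:, None, :] + sub[None, :, :]) * cell - ext_half).reshape(-1, 3)
    mu_pts = np.repeat(mu_c[support[:, 0], support[:, 1], support[:, 2]], 27)
    w_pt = 1.0 / 27.0  # cell-equivalent weight per sub-point

    det_pos, det_nrm, det_area, det_tax, det_ax = coarse_detectors(model)
    n_det = det_pos.shape[0]
    eff = _efficiency_table()
    eff511 = eff[511 - 50]
    kn_tot = float(physics.klein_nishina_total(511.0))

    from petchain.corrections import siddon_ray_sum

    coarse_origin = -ext_half
    pair_sum = np.zeros((n_det, n_det))
    sec_step = model.spec.n_rsector
    min_dtax = int(round(model.spec.min_sector_difference * 68 / sec_step))
    # precompute per-point, per-detector legs
    for chunk in range(0, pts.shape[0], 400):
        P = pts[chunk:chunk + 400]
        nP = P.shape[0]
        D = det_pos[None, :, :] - P[:, None, :]
        L = np.linalg.norm(D, axis=2)
        U = D / L[..., None]
        cosw = np.abs(np.sum(U * (-det_nrm)[None, :, :], axis=2))
        p0 = P[:, None, :].repeat(n_det, 1).reshape(-1, 3)
        p1 = np.broadcast_to(det_pos, (nP, n_det, 3)).reshape(-1, 3)
        Lmu = np.asarray(siddon_ray_sum(mu_c, coarse_origin, cell, p0, p1)
                         ).reshape(nP, n_det)
        Llam = np.asarray(siddon_ray_sum(lam_c, coarse_origin, cell, p0, p1)
                          ).reshape(nP, n_det)
        mu_p = mu_pts[chunk:chunk + 400]
        for d1 in range(n_det):
            dt = (det_tax[d1] - det_tax) % 68
            dtm = np.minimum(dt, 68 - dt)
            cand = np.nonzero((np.arange(n_det) > d1) & (dtm >= min_dtax))[0]
            if cand.size == 0:
                continue
            x1, y1 = det_pos[d1, 0], det_pos[d1, 1]
            x2, y2 = det_pos[cand, 0], det_pos[cand, 1]
            alpha = np.mod(np.arctan2(y2 - y1, x2 - x1), np.pi)
            s = x1 * np.sin(alpha) - y1 * np.cos(alpha)
            cand = cand[np.abs(s) <= 350.0]
            if cand.size == 0:
                continue
            cos_t = -np.sum(U[:, d1, None, :] * U[:, cand, :], axis=2)
            ratio = 1.0 / (2.0 - cos_t)
            e_sc = 511.0 * ratio
            ie = np.clip(e_sc.astype(int) - 50, 0, 650)
            kn = 0.5 * physics.R_E_SQ * ratio**2 * (ratio + 1.0 / ratio
                                                    - (1.0 - cos_t**2))
            om1 = np.minimum(det_area * cosw[:, d1, None] / L[:, d1, None]**2, 2.0)
            om2 = np.minimum(det_area * cosw[:, cand] / L[:, cand]**2, 2.0)
            geom = om1 * om2 / (4.0 * np.pi)
            phys_f = mu_p[:, None] * kn / kn_tot * geom
            rt = np.interp(e_sc, physics.ENERGY_GRID,
                           physics.water_mu_ratio_table())
            att1 = np.exp(-Lmu[:, d1, None])
            att2 = np.exp(-Lmu[:, cand])
            term_a = Llam[:, d1, None] * att1 * np.exp(-Lmu[:, cand] * rt) \
                * eff511 * eff[ie]
            term_b = Llam[:, cand] * att2 * np.exp(-Lmu[:, d1, None] * rt) \
                * eff511 * eff[ie]
            pair_sum[d1, cand] += np.sum(phys_f * (term_a + term_b) * w_pt,
                                         axis=0)
    # bin the per-pair rates exactly like the estimator (mean per coarse
    # sinogram bin, then total)
    radial_bin_c = 700.0 / 34
    n_rad_c = 2 * int(np.ceil(350.0 / radial_bin_c)) + 1
    out = np.zeros((n_rad_c, 34, 7))
    cnt = np.zeros((n_rad_c, 34, 7))
    for d1 in range(n_det):
        for d2 in range(d1 + 1, n_det):
            dt = (det_tax[d1] - det_tax[d2]) % 68
            if min(dt, 68 - dt) < min_dtax:
                continue
            x1, y1 = det_pos[d1, 0], det_pos[d1, 1]
            x2, y2 = det_pos[d2, 0], det_pos[d2, 1]
            alpha = np.mod(np.arctan2(y2 - y1, x2 - x1), np.pi)
            sval = x1 * np.sin(alpha) - y1 * np.cos(alpha)
            if abs(sval) > 350.0:
                continue
            rb = int(round(sval / radial_bin_c)) + n_rad_c // 2
            vb = min(int(alpha / np.pi * 34), 33)
            pb = det_ax[d1] + det_ax[d2]
            out[rb, vb, pb] += pair_sum[d1, d2]
            cnt[rb, vb, pb] += 1
    return float(np.where(cnt > 0, out / np.maximum(cnt, 1), 0.0).sum())


class TestUpsample:
    def _meta(self, model):
        n_rad_c, n_azim_c, n_pl = 35, 34, 7
        return dict(
            s_centers=(np.arange(n_rad_c) - 17) * (700.0 / 34),
            phi_centers=(np.arange(n_azim_c) + 0.5) * np.pi / 34,
            z_planes=(np.arange(n_pl) - 3.0) * (190.8 / 8),
            n_points=1)

    def test_constant_preserved(self, model, layout):
        meta = self._meta(model)
        coarse = np.full((35, 34, 7), 3.14)
        up = upsample_scatter(coarse, meta, model, layout)
        assert up.shape == layout.shape
        assert np.allclose(up, 3.14, rtol=1e-9)

    def test_azimuthal_linear_ramp(self, model, layout):
        """A sawtooth-free linear ramp in azimuth is reproduced exactly by
        the periodic linear interpolation (interior views)."""
        meta = self._meta(model)
        ramp = np.sin(2 * (np.arange(34) + 0.5) * np.pi / 34)
        coarse = np.broadcast_to(ramp[None, :, None], (35, 34, 7)).copy() + 2.0
        up = upsample_scatter(coarse, meta, model, layout)
        phi_f = (np.arange(layout.n_azimuthal) + 0.5) * np.pi / layout.n_azimuthal
        interior = (phi_f >= meta["phi_centers"][0]) & (phi_f <= meta["phi_centers"][-1])
        expected = np.interp(phi_f[interior], meta["phi_centers"], ramp + 2.0)
        assert np.allclose(up[17, interior, 35], expected, atol=1e-9)

    def test_coarse_nodes_preserved(self, model, layout):
        meta = self._meta(model)
        rng = np.random.default_rng(4)
        coarse = rng.random((35, 34, 7)) + 1.0
        up = upsample_scatter(coarse, meta, model, layout)
        # fine bin nearest to a coarse node in all three axes
        s_f = (np.arange(layout.n_radial) - 177) * layout.radial_bin_mm
        i_f = int(np.argmin(np.abs(s_f - meta["s_centers"][17])))
        z_f = layout.plane_z(build_scanner(model.spec))
        k_f = int(np.argmin(np.abs(z_f - meta["z_planes"][3])))
        # radial spline and axial spline pass through the nodes; azimuth
        # bins differ, so compare against the azimuthal interpolant
        phi_f = (np.arange(layout.n_azimuthal) + 0.5) * np.pi / layout.n_azimuthal
        v_f = int(np.argmin(np.abs(phi_f - meta["phi_centers"][10])))
        assert up[i_f, v_f, k_f] == pytest.approx(coarse[17, 10, 3], rel=0.02)


class TestTailFit:
    def _acf(self, layout):
        from petchain.corrections import AttenuationSinogram
        mu_path = np.zeros(layout.shape)
        mu_path[100:255] = 2.0  # object region
        return AttenuationSinogram(np.exp(mu_path), mu_path, layout)

    def test_exact_fit(self, layout):
        acf = self._acf(layout)
        s = np.random.default_rng(0).random(layout.shape) + 0.5
        beta, q, tails = fit_scatter_tails(s, 1.0 * s, acf)
        assert beta == pytest.approx(1.0, rel=1e-12)
        assert q == 0.0
        assert not np.any(tails & (acf.mu_path > 1e-3))

    def test_recovers_known_scale(self, layout, rng):
        acf = self._acf(layout)
        s = rng.random(layout.shape) * 10 + 5
        y = rng.poisson(2.0 * s)
        beta, q, tails = fit_scatter_tails(s, y, acf)
        n = tails.sum()
        sd = np.sqrt((2 * s)[tails].sum()) / s[tails].sum() * 2.0
        assert abs(beta - 2.0) < 3 * sd * 2

    def test_intercept_forced_zero_without_prompt_gamma(self, layout, rng):
        acf = self._acf(layout)
        s = rng.random(layout.shape) + 1.0
        y = 2.0 * s + 5.0  # constant offset present in the data
        beta, q, _ = fit_scatter_tails(s, y, acf, prompt_gamma=False)
        assert q == 0.0
        beta2, q2, _ = fit_scatter_tails(s, y, acf, prompt_gamma=True)
        assert q2 == pytest.approx(5.0, rel=0.05)
        assert beta2 == pytest.approx(2.0, rel=0.05)

    def test_no_tails_raises(self, layout):
        from petchain.corrections import AttenuationSinogram
        mu_path = np.full(layout.shape, 2.0)
        acf = AttenuationSinogram(np.exp(mu_path), mu_path, layout)
        with pytest.raises(EstimationError):
            fit_scatter_tails(np.ones(layout.shape), np.ones(layout.shape), acf)
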