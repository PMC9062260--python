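"""Attenuation, randoms, normalisation and calibration."""

import numpy as np
import pytest

from petchain.corrections import (EstimationError, NormalisationComponents,
                                  accumulate_pair_sinogram,
                                  attenuation_correction_sinogram,
                                  estimate_normalisation, randoms_from_singles,
                                  siddon_ray_sum, well_counter_calibrate)
from petchain.geometry import (ScannerSpec, SinogramLayout, bin_lors,
                               build_scanner, desk_layout)
from petchain.phantoms import PhantomSpec, build_phantom
from petchain.simulate import Acquisition, CoincidenceList


@pytest.fixture(scope="module")
def water_cylinder():
    spec = PhantomSpec(kind="uniform_cylinder", body_half_axes=(100.0, 100.0),
                       body_length=200.0, background_concentration=1.0,
                       wall_thickness=0.0, couch=False)
    return build_phantom(spec, voxel_size=2.0)


class TestSiddon:
    def test_ray_missing_grid(self, water_cylinder):
        vp = water_cylinder
        v = siddon_ray_sum(vp.mu_511, vp.origin, vp.voxel_size,
                           [500, 500, 0], [500, -500, 0])
        assert v == 0.0

    def test_coincident_endpoints(self, water_cylinder):
        vp = water_cylinder
        assert siddon_ray_sum(vp.mu_511, vp.origin, vp.voxel_size,
                              [0, 0, 0], [0, 0, 0]) == 0.0

    def test_diametral_chord(self, water_cylinder):
        """20 cm of water at 0.0958 cm^-1 gives an optical depth of 1.916."""
        vp = water_cylinder
        v = siddon_ray_sum(vp.mu_511, vp.origin, vp.voxel_size,
                           [-300, 0, 0], [300, 0, 0])
        assert v == pytest.approx(1.916, rel=0.005)

    def test_against_dense_sampling(self, water_cylinder, rng):
        """Exact voxel path agrees with a dense numeric integral to <0.1%
        on random rays."""
        vp = water_cylinder
        for _ in range(100):
            p0 = rng.uniform(-250, 250, 3)
            p1 = rng.uniform(-250, 250, 3)
            p0[2] = rng.uniform(-90, 90)
            p1[2] = rng.uniform(-90, 90)
            sv = siddon_ray_sum(vp.mu_511, vp.origin, vp.voxel_size, p0, p1)
            ts = np.linspace(0, 1, 40001)
            pts = p0[None] + (p1 - p0)[None] * ts[:, None]
            idx = np.floor((pts - vp.origin) / vp.voxel_size).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(vp.shape)), axis=1)
            mu = np.zeros(ts.size)
            mu[ok] = vp.mu_511[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            dense = mu.sum() * np.linalg.norm(p1 - p0) / ts.size * 0.1
            # the dense estimator carries its own boundary-quantisation
            # error; allow it as an absolute floor on top of the 0.1%
            if dense > 0.05:
                assert abs(sv - dense) < 1e-3 * dense + 5e-4


class TestAttenuation:
    def test_empty_phantom_unity(self, model):
        spec = PhantomSpec(kind="uniform_cylinder", body_half_axes=(50.0, 50.0),
                           body_length=50.0, background_concentration=0.0,
                           wall_thickness=0.0, couch=False)
        vp = build_phantom(spec, voxel_size=4.0)
        vp.mu_511[:] = 0.0
        layout = desk_layout()
        acfs = attenuation_correction_sinogram(vp, model, layout,
                                               include_liner=False)
        assert np.allclose(acfs.acf, 1.0)
        assert np.all(acfs.acf >= 1.0)

    def test_water_chord_value(self, model, water_cylinder):
        """A central LOR through 20 cm of water has acf ~ e^1.916 = 6.79."""
        layout = desk_layout()
        acfs = attenuation_correction_sinogram(water_cylinder, model, layout,
                                               include_liner=False)
        central = acfs.acf[layout.n_radial // 2, :, 35]
        # voxelised boundary adds ~half a voxel of chord jitter per end
        assert np.allclose(central, np.exp(1.916), rtol=0.025)
        assert np.median(central) == pytest.approx(np.exp(1.916), rel=0.01)

    def test_radial_monotone(self, model, water_cylinder):
        layout = desk_layout()
        acfs = attenuation_correction_sinogram(water_cylinder, model, layout,
                                               include_liner=False)
        prof = acfs.acf[:, 3, 35]
        half = layout.n_radial // 2
        right = prof[half:]
        assert np.all(np.diff(right) <= 1e-9)

    def test_mu_scaling_property(self, model, water_cylinder):
        """Scaling mu by c scales log(acf) by c."""
        layout = desk_layout()
        a1 = attenuation_correction_sinogram(water_cylinder, model, layout,
                                             include_liner=False)
        import copy
        vp2 = copy.deepcopy(water_cylinder)
        vp2.mu_511 = vp2.mu_511 * 2.0
        a2 = attenuation_correction_sinogram(vp2, model, layout,
                                             include_liner=False)
        assert np.allclose(np.log(a2.acf), 2.0 * np.log(a1.acf), atol=1e-4)


class TestRandoms:
    def test_zero_singles(self, model, layout):
        r = randoms_from_singles(np.zeros((36, 544)), 600.0, 4.9e-9, model,
                                 layout)
        assert r.expected.sum() == 0.0

    def test_closed_form_single_pair(self, model, layout):
        """S1 = S2 = 1e6 counts, T = 600 s, 2tau = 4.9 ns -> 8.17 expected
        randoms on that LOR."""
        S = np.zeros((36, 544))
        S[18, 0] = 1e6
        S[18, 272] = 1e6
        r = randoms_from_singles(S, 600.0, 4.9e-9, model, layout)
        assert r.expected.sum() == pytest.approx(4.9e-9 * 1e12 / 600.0, rel=1e-6)
        assert r.expected.sum() == pytest.approx(8.17, rel=2e-3)

    def test_bilinearity(self, model, layout, rng):
        S = rng.poisson(50, (36, 544)).astype(float)
        r1 = randoms_from_singles(S, 600.0, 4.9e-9, model, layout)
        r2 = randoms_from_singles(2 * S, 600.0, 4.9e-9, model, layout)
        assert np.allclose(r2.expected, 4 * r1.expected, rtol=1e-6)

    def test_invalid_duration(self, model, layout):
        with pytest.raises(ValueError):
            randoms_from_singles(np.zeros((36, 544)), 0.0, 4.9e-9, model, layout)

    def test_total_matches_bruteforce_toy_scanner(self, rng):
        """Sum over the randoms sinogram equals the brute-force sum of
        2 tau S1 S2 / T over every accepted crystal pair (toy scanner,
        100 crystals)."""
        spec = ScannerSpec(n_rsector=10, n_module_axial=1,
                           n_submodule_transaxial=1, n_crystal_transaxial=2,
                           n_crystal_axial=5, crystal_size=(3.95, 5.3, 25.0),
                           min_sector_difference=2)
        toy = build_scanner(spec)
        layout = SinogramLayout(n_radial=21, n_azimuthal=10, radial_bin_mm=40.0,
                                axial_mode="ssrb", n_rings=5)
        S = rng.poisson(100, (5, 20)).astype(float)
        r = randoms_from_singles(S, 100.0, 4.9e-9, toy, layout)
        total = 0.0
        for t1 in range(20):
            for t2 in range(t1 + 1, 20):
                for u in range(5):
                    for v in range(5):
                        ok, *_ = bin_lors(toy, layout, [u], [t1], [v], [t2])
                        if ok[0]:
                            total += 4.9e-9 * S[u, t1] * S[v, t2] / 100.0
        assert r.expected.sum() == pytest.approx(total, rel=1e-6)


def _synthetic_acquisition(model, rng, n_events, eps=None, radial_limit=None):
    """Event-level stand-in for a calibration acquisition: crystal pairs
    drawn uniformly over accepted LORs, thinned by the product of the two
    crystal efficiencies."""
    n_tax = model.spec.crystals_per_ring
    n_rings = model.spec.n_rings
    cols = dict(ring1=[], tax1=[], ring2=[], tax2=[])
    got = 0
    while got < n_events:
        m = min(int((n_events - got) * 2.5) + 1000, 4_000_000)
        t1 = rng.integers(0, n_tax, m, dtype=np.int16)
        t2 = rng.integers(0, n_tax, m, dtype=np.int16)
        a1 = rng.integers(0, n_rings, m, dtype=np.int16)
        a2 = rng.integers(0, n_rings, m, dtype=np.int16)
        ok, r, v, p, _ = bin_lors(model, desk_layout(), a1, t1, a2, t2)
        if radial_limit is not None:
            s = (r - 177) * 1.975
            ok = ok & (np.abs(s) < radial_limit)
        if eps is not None:
            keep = rng.random(m) < eps[a1, t1] * eps[a2, t2] / eps.max() ** 2
            ok = ok & keep
        take = min(int(ok.sum()), n_events - got)
        idx = np.flatnonzero(ok)[:take]
        cols["ring1"].append(a1[idx])
        cols["tax1"].append(t1[idx])
        cols["ring2"].append(a2[idx])
        cols["tax2"].append(t2[idx])
        got += take
    arrs = {k: np.concatenate(v).astype(np.int16) for k, v in cols.items()}
    n = arrs["ring1"].size
    z32 = np.zeros(n, np.float32)
    coin = CoincidenceList(
        ring1=arrs["ring1"], tax1=arrs["tax1"], ring2=arrs["ring2"],
        tax2=arrs["tax2"], e1=z32, e2=z32, tof_delta=z32,
        label=np.zeros(n, np.uint8), lu=np.zeros(n, bool),
        time1=z32, scat1=np.zeros(n, np.uint16),
        scat2=np.zeros(n, np.uint16))
    return Acquisition(coin, np.zeros((n_rings, n_tax), np.int64), 100.0,
                       1.0, 0, {})


class TestNormalisation:
    def test_eta_assembly_identity(self, layout):
        """The per-LOR correction equals the product of its stored
        components."""
        rng = np.random.default_rng(0)
        comp = NormalisationComponents(
            eps=rng.uniform(0.8, 1.2, (36, 544)),
            b_axial=rng.uniform(0.9, 1.1, 36),
            g_axial=rng.uniform(0.9, 1.1, (36, 36)),
            r_radial=rng.uniform(0.8, 1.2, layout.n_radial),
            f_interference=rng.uniform(0.9, 1.1, (4, layout.n_radial)),
            layout=layout)
        val = comp.pair_eta(3, 100, 17, 400, 50, 9)
        expected = (comp.eps[3, 100] * comp.eps[17, 400] * comp.b_axial[3]
                    * comp.b_axial[17] * comp.g_axial[3, 17]
                    * comp.r_radial[50] * comp.f_interference[1, 50])
        assert val == pytest.approx(expected, rel=1e-12)

    def test_empty_acquisition_raises(self, model, layout):
        from petchain.simulate import _empty_coincidences
        empty = Acquisition(_empty_coincidences(), np.zeros((36, 544)), 1.0,
                            1.0, 0, {})
        with pytest.raises(EstimationError):
            estimate_normalisation(empty, empty, model, layout)

    def test_uniform_detector_components_near_one(self, model, layout, rng):
        """With uniform crystal efficiencies the estimated epsilon, b and g
        scatter tightly around 1."""
        central = _synthetic_acquisition(model, rng, 2_000_000,
                                         radial_limit=100.0)
        annulus = _synthetic_acquisition(model, rng, 1_000_000)
        comp = estimate_normalisation(central, annulus, model, layout,
                                      annulus_radius=1e9)
        assert abs(np.mean(comp.eps) - 1.0) < 0.01
        assert np.std(comp.eps) < 0.12
        assert np.allclose(comp.b_axial, 1.0, atol=0.05)

    def test_epsilon_recovery_correlation(self, model, layout):
        """Crystals with efficiencies ~ N(1, 0.05^2): the fan-sum estimate
        correlates with the truth (r > 0.95)."""
        rng = np.random.default_rng(5)
        eps_true = rng.normal(1.0, 0.05, (36, 544)).clip(0.7, 1.3)
        central = _synthetic_acquisition(model, rng, 50_000_000, eps=eps_true)
        annulus = _synthetic_acquisition(model, rng, 500_000)
        comp = estimate_normalisation(central, annulus, model, layout,
                                      annulus_radius=1e9)
        est_sens = 1.0 / comp.eps
        r = np.corrcoef(eps_true.ravel(), est_sens.ravel())[0, 1]
        assert r > 0.95


class TestWellCounter:
    def test_identity(self):
        img = np.full((64, 64, 20), 4.4)
        z = (np.arange(20) - 9.5) * 10.0
        w = well_counter_calibrate(img, 5.0, z, 4.4)
        assert w.wcc == pytest.approx(1.0)

    def test_half_scale(self):
        img = np.full((64, 64, 20), 8.8)
        z = (np.arange(20) - 9.5) * 10.0
        w = well_counter_calibrate(img, 5.0, z, 4.4)
        assert w.wcc == pytest.approx(0.5)

    def test_zero_mean_raises(self):
        img = np.zeros((64, 64, 20))
        z = (np.arange(20) - 9.5) * 10.0
        with pytest.raises(ValueError):
            well_counter_calibrate(img, 5.0, z, 4.4)
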