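"""Correction chain: attenuation, component-based normalisation, randoms
from singles, and well-counter calibration.

The per-LOR normalisation correction factorises into crystal efficiencies
(epsilon), axial block profiles (b), an axial geometric factor per ring
pair (g), a radial profile (r) and a crystal-interference factor (f);
the factors are estimated from two dedicated acquisitions (a central
cylinder for the axial components and crystal efficiencies, an annulus
beyond the transaxial FOV for the transaxial components).  Randoms are
estimated per LOR as 2*tau*S1*S2/T from the singles counts of the two
crystals.  Scatter lives in :mod:`petchain.sss`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import physics
from .geometry import (AXIAL_SSRB, ScannerModel, SinogramLayout,
                       all_bin_endpoints, bin_lors)
from .phantoms import VoxelPhantom
from .simulate import Acquisition


class EstimationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Siddon exact radiological path
# --------------------------------------------------------------------------

@njit(cache=True)
def _siddon_one(x0, y0, z0, x1, y1, z1, vol, ox, oy, oz, vx, vy, vz):
    nx, ny, nz = vol.shape
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < 1e-9:
        return 0.0
    t0 = 0.0
    t1 = 1.0
    # slab clipping
    for axis in range(3):
        if axis == 0:
            p, d, o, n, v = x0, dx, ox, nx, vx
        elif axis == 1:
            p, d, o, n, v = y0, dy, oy, ny, vy
        else:
            p, d, o, n, v = z0, dz, oz, nz, vz
        lo = o
        hi = o + n * v
        if abs(d) < 1e-12:
            if p < lo or p > hi:
                return 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return 0.0
    total = 0.0
    t = t0
    eps = 1e-9
    while t < t1 - eps:
        xm = x0 + (t + eps) * dx
        ym = y0 + (t + eps) * dy
        zm = z0 + (t + eps) * dz
        ix = int((xm - ox) / vx)
        iy = int((ym - oy) / vy)
        iz = int((zm - oz) / vz)
        if ix < 0:
            ix = 0
        elif ix >= nx:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy >= ny:
            iy = ny - 1
        if iz < 0:
            iz = 0
        elif iz >= nz:
            iz = nz - 1
        t_next = t1
        if abs(dx) > 1e-12:
            step = (ox + (ix + (1 if dx > 0 else 0)) * vx - x0) / dx
            if step > t + eps and step < t_next:
                t_next = step
        if abs(dy) > 1e-12:
            step = (oy + (iy + (1 if dy > 0 else 0)) * vy - y0) / dy
            if step > t + eps and step < t_next:
                t_next = step
        if abs(dz) > 1e-12:
            step = (oz + (iz + (1 if dz > 0 else 0)) * vz - z0) / dz
            if step > t + eps and step < t_next:
                t_next = step
        if t_next <= t + eps:
            t_next = t + eps * 10.0
        total += vol[ix, iy, iz] * (t_next - t) * length
        t = t_next
    return total * 0.1  # mm -> cm


@njit(cache=True)
def _siddon_batch(p0, p1, vol, ox, oy, oz, vx, vy, vz, out):
    for i in range(p0.shape[0]):
        out[i] = _siddon_one(p0[i, 0], p0[i, 1], p0[i, 2],
                             p1[i, 0], p1[i, 1], p1[i, 2],
                             vol, ox, oy, oz, vx, vy, vz)


def siddon_ray_sum(volume, origin, voxel_size, p0, p1):
    """Exact radiological path of segment p0->p1 (mm) through a voxel
    grid of values in cm^-1; returns cm^-1 * cm (dimensionless optical
    depth when the volume holds mu).  ``voxel_size`` may be a scalar or
    a per-axis triple."""
    p0 = np.atleast_2d(np.asarray(p0, dtype=np.float64))
    p1 = np.atleast_2d(np.asarray(p1, dtype=np.float64))
    out = np.empty(p0.shape[0])
    vol = np.ascontiguousarray(volume, dtype=np.float32)
    if np.isscalar(voxel_size):
        vx = vy = vz = float(voxel_size)
    else:
        vx, vy, vz = (float(v) for v in voxel_size)
    _siddon_batch(p0, p1, vol, float(origin[0]), float(origin[1]),
                  float(origin[2]), vx, vy, vz, out)
    return out if out.size > 1 else float(out[0])


# --------------------------------------------------------------------------
# attenuation correction
# --------------------------------------------------------------------------

@dataclass
class AttenuationSinogram:
    """Per-bin attenuation correction factors (>= 1) and the underlying
    mu line integrals used to derive the scatter-tail mask."""

    acf: np.ndarray
    mu_path: np.ndarray
    layout: SinogramLayout


def liner_attenuation_factor(s_mm, model: ScannerModel):
    """Analytic two-crossing attenuation of the plastic bore liner for an
    in-plane LOR at radial offset ``s_mm`` (1.0 when no liner)."""
    spec = model.spec
    r1 = spec.bore_liner_radius
    r2 = r1 + spec.bore_liner_thickness
    s = np.minimum(np.abs(np.asarray(s_mm, dtype=float)), r1 - 1e-6)
    chord = np.sqrt(r2 * r2 - s * s) - np.sqrt(r1 * r1 - s * s)
    mu = float(physics.PMMA.mu(511.0))
    return np.exp(mu * 2.0 * chord / 10.0)


def attenuation_correction_sinogram(phantom: VoxelPhantom, model: ScannerModel,
                                    layout: SinogramLayout,
                                    include_liner: bool = True) -> AttenuationSinogram:
    """acf = exp(+integral of mu) per sinogram bin, endpoints at the bin's
    representative crystal front-face positions."""
    e1, e2 = all_bin_endpoints(model, layout)
    mu_path = np.asarray(siddon_ray_sum(phantom.mu_511, phantom.origin,
                                        phantom.voxel_size, e1, e2))
    acf = np.exp(mu_path)
    if include_liner and model.spec.bore_liner_thickness > 0:
        r = np.arange(layout.n_radial) - layout.n_radial // 2
        s = r * layout.radial_bin_mm
        fac = liner_attenuation_factor(s, model)
        acf = acf.reshape(layout.shape) * fac[:, None, None]
        return AttenuationSinogram(acf.astype(np.float32),
                                   mu_path.reshape(layout.shape).astype(np.float32),
                                   layout)
    return AttenuationSinogram(acf.reshape(layout.shape).astype(np.float32),
                               mu_path.reshape(layout.shape).astype(np.float32),
                               layout)


# --------------------------------------------------------------------------
# pair accumulation kernel (randoms, normalisation bin models)
# --------------------------------------------------------------------------

@njit(cache=True)
def _accumulate_pairs(x, y, sector, n_sec, min_sd, radial_extent, radial_bin,
                      n_radial, n_azim, n_rings, ssrb, mrd, W, G, out, counts):
    n_tax = x.size
    half_r = n_radial // 2
    n_planes = 2 * n_rings - 1 if ssrb else n_rings * n_rings
    for t1 in range(n_tax):
        for t2 in range(t1 + 1, n_tax):
            d = (sector[t1] - sector[t2]) % n_sec
            dm = min(d, n_sec - d)
            if dm < min_sd:
                continue
            dx = x[t2] - x[t1]
            dy = y[t2] - y[t1]
            alpha = np.arctan2(dy, dx)
            if alpha < 0.0:
                alpha += np.pi
            if alpha >= np.pi:
                alpha -= np.pi
            ca = np.cos(alpha)
            sa = np.sin(alpha)
            s = x[t1] * sa - y[t1] * ca
            if abs(s) > radial_extent:
                continue
            r = int(np.round(s / radial_bin)) + half_r
            v = int(alpha / np.pi * n_azim)
            if v >= n_azim:
                v = n_azim - 1
            first1 = (x[t1] * ca + y[t1] * sa) <= (x[t2] * ca + y[t2] * sa)
            base = (r * n_azim + v) * n_planes
            for u in range(n_rings):
                w1 = W[u, t1]
                for vv in range(n_rings):
                    if ssrb:
                        if abs(u - vv) > mrd:
                            continue
                        plane = u + vv
                    else:
                        plane = u * n_rings + vv if first1 else vv * n_rings + u
                    idx = base + plane
                    out[idx] += w1 * W[vv, t2] * G[u, vv]
                    counts[idx] += 1
    return


def accumulate_pair_sinogram(model: ScannerModel, layout: SinogramLayout,
                             per_crystal: np.ndarray,
                             per_ring_pair: np.ndarray | float = 1.0):
    """Sum W[c1] * W[c2] * G[ring1, ring2] over every accepted crystal
    pair, binned; returns (sum sinogram, pair-count sinogram)."""
    spec = model.spec
    W = np.ascontiguousarray(per_crystal, dtype=np.float64)
    if np.isscalar(per_ring_pair):
        G = np.full((spec.n_rings, spec.n_rings), float(per_ring_pair))
    else:
        G = np.ascontiguousarray(per_ring_pair, dtype=np.float64)
    out = np.zeros(int(np.prod(layout.shape)), np.float64)
    counts = np.zeros(int(np.prod(layout.shape)), np.int64)
    mrd = layout.max_ring_diff if layout.max_ring_diff is not None else spec.n_rings
    _accumulate_pairs(model.x_tax, model.y_tax,
                      model.sector_of_tax.astype(np.int64), spec.n_rsector,
                      spec.min_sector_difference, layout.radial_extent,
                      layout.radial_bin_mm, layout.n_radial, layout.n_azimuthal,
                      spec.n_rings, layout.axial_mode == AXIAL_SSRB, mrd,
                      W, G, out, counts)
    return out.reshape(layout.shape), counts.reshape(layout.shape)


# --------------------------------------------------------------------------
# randoms from singles
# --------------------------------------------------------------------------

@dataclass
class RandomsSinogram:
    expected: np.ndarray
    duration_s: float
    window_2tau_s: float


def randoms_from_singles(singles_per_crystal: np.ndarray, duration_s: float,
                         window_2tau_s: float, model: ScannerModel,
                         layout: SinogramLayout) -> RandomsSinogram:
    """Expected random counts per bin: R = 2*tau * S1 * S2 / T summed over
    the crystal pairs addressing the bin."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    S = np.asarray(singles_per_crystal, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("singles counts must be nonnegative")
    fac = window_2tau_s / duration_s
    out, _ = accumulate_pair_sinogram(model, layout, S, fac)
    return RandomsSinogram(out.astype(np.float32), duration_s, window_2tau_s)


# --------------------------------------------------------------------------
# component-based normalisation
# --------------------------------------------------------------------------

@dataclass
class NormalisationComponents:
    """Correction-factor components (each mean-normalised to 1): per-LOR
    correction is the product eps1*eps2*b1*b2*g*r*f.  ``sens_sino`` is
    the bin-level relative sensitivity (pair sum of inverse corrections
    times the bin-level transaxial factors), ``eta_sino`` its inverse on
    valid bins, used multiplicatively on binned data."""

    eps: np.ndarray          # (n_rings, n_tax) crystal efficiency correction
    b_axial: np.ndarray      # (n_rings,)
    g_axial: np.ndarray      # (n_rings, n_rings)
    r_radial: np.ndarray     # (n_radial,)
    f_interference: np.ndarray  # (n_block_tax, n_radial)
    layout: SinogramLayout
    sens_sino: np.ndarray = None
    eta_sino: np.ndarray = None
    valid: np.ndarray = None

    def pair_eta(self, ring1, tax1, ring2, tax2, radial, azim):
        """Per-LOR normalisation correction factor (component product)."""
        blk = azim % self.f_interference.shape[0]
        return (self.eps[ring1, tax1] * self.eps[ring2, tax2]
                * self.b_axial[ring1] * self.b_axial[ring2]
                * self.g_axial[ring1, ring2]
                * self.r_radial[radial] * self.f_interference[blk, radial])


def _fan_sums(acq: Acquisition, model: ScannerModel):
    c = acq.coincidences
    if len(c) == 0:
        raise EstimationError("empty calibration acquisition")
    spec = model.spec
    F = np.zeros((spec.n_rings, spec.crystals_per_ring))
    np.add.at(F, (c.ring1.astype(np.int64), c.tax1.astype(np.int64)), 1.0)
    np.add.at(F, (c.ring2.astype(np.int64), c.tax2.astype(np.int64)), 1.0)
    M = np.zeros((spec.n_rings, spec.n_rings))
    np.add.at(M, (c.ring1.astype(np.int64), c.ring2.astype(np.int64)), 1.0)
    M = M + M.T
    return F, M


def estimate_normalisation(central: Acquisition, annulus: Acquisition,
                           model: ScannerModel, layout: SinogramLayout,
                           annulus_radius: float = 355.0,
                           central_radius: float = 100.0,
                           n_iter: int = 5) -> NormalisationComponents:
    """Estimate the normalisation components.

    Crystal efficiencies come from fan sums of the central-cylinder data
    (ratio to the ring mean); the axial block profile b and ring-pair
    geometric factor g (a function of ring difference) from alternating
    fits to the ring-pair count matrix; the radial profile r and crystal
    interference f from the annulus data after correcting for the axial
    model and the annulus chord geometry.
    """
    spec = model.spec
    F, M = _fan_sums(central, model)
    ring_mean = F.mean(axis=1, keepdims=True)
    if np.any(ring_mean <= 0):
        raise EstimationError("central acquisition leaves empty rings")
    eps_sens = np.clip(F / ring_mean, 1e-3, None)

    # alternating fit: M[u,v] ~ kappa * b_u * b_v * g(|u-v|); the b update
    # is the weighted-mean (fan) form so ring-pair multiplicity (edge
    # rings have fewer partners) stays out of the per-ring factor
    n = spec.n_rings
    dd = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    active = M.sum(axis=0) > 0
    b = np.ones(n)
    gg = np.ones(n)
    for _ in range(n_iter):
        gg = np.zeros(n)
        norm_d = np.zeros(n)
        np.add.at(gg, dd.ravel(), (M / np.outer(b, b)).ravel())
        np.add.at(norm_d, dd.ravel(), (np.outer(b, b) > 0).ravel() * 1.0)
        gg /= np.maximum(norm_d, 1)
        G = gg[dd]
        denom = (G * b[None, :]).sum(axis=1)
        b = np.where(denom > 0, M.sum(axis=1) / np.maximum(denom, 1e-12), 1.0)
        b /= b[active].mean() if active.any() else 1.0
    G = gg[dd]
    b_sens = np.clip(b, 1e-3, None)
    g_sens = np.clip(G / G.mean(), 1e-6, None)

    # bin-level axial/efficiency sensitivity model
    W = eps_sens * b_sens[:, None]
    s0, cnt = accumulate_pair_sinogram(model, layout, W, g_sens)
    valid = cnt > 0

    # transaxial factors.  The annulus covers the whole radial range but
    # its axial acceptance differs from the central source the axial
    # model was fitted to, which leaves a radial tilt if used alone; the
    # central cylinder has an analytic chord profile over the inner
    # radii.  Use the central acquisition inside its footprint, the
    # annulus outside, stitched over the overlap band.
    c = annulus.coincidences
    if len(c) == 0:
        raise EstimationError("empty annulus acquisition")
    from .geometry import histogram_events
    ann = histogram_events(model, layout, c.ring1, c.tax1, c.ring2, c.tax2)
    cc = central.coincidences
    cen = histogram_events(model, layout, cc.ring1, cc.tax1, cc.ring2, cc.tax2)
    r_idx = np.arange(layout.n_radial) - layout.n_radial // 2
    s_mm = r_idx * layout.radial_bin_mm
    chord_a = 1.0 / np.sqrt(np.maximum(1.0 - (s_mm / annulus_radius) ** 2, 1e-6))
    chord_c = 2.0 * np.sqrt(np.maximum(central_radius**2 - s_mm**2, 0.0))
    exp_a = s0 * chord_a[:, None, None]
    exp_c = s0 * chord_c[:, None, None]

    def _profile(obs, exp):
        o = np.where(valid, obs, 0.0).sum(axis=(1, 2))
        e = np.where(valid, exp, 0.0).sum(axis=(1, 2))
        return np.where(e > 0, o / np.maximum(e, 1e-12), 0.0)

    prof_c = _profile(cen, exp_c)
    prof_a = _profile(ann, exp_a)
    inner = np.abs(s_mm) <= central_radius - 10.0
    band = inner & (np.abs(s_mm) >= central_radius - 35.0)
    if prof_c[band].sum() <= 0 or prof_a[band].sum() <= 0:
        raise EstimationError("calibration acquisitions do not overlap radially")
    prof_a = prof_a * (prof_c[band].mean() / prof_a[band].mean())
    r_sens = np.where(inner, prof_c, prof_a)
    nz = r_sens > 0
    if not np.any(nz):
        raise EstimationError("no usable bins in calibration acquisitions")
    r_sens[~nz] = 1.0
    r_sens /= r_sens[nz].mean()
    r_sens = np.clip(r_sens, 1e-3, None)

    nblk = spec.n_crystal_transaxial
    f_sens = np.ones((nblk, layout.n_radial))
    exp_rf_a = exp_a * r_sens[:, None, None]
    exp_rf_c = exp_c * r_sens[:, None, None]
    # bring each acquisition's expectation to its own count scale before
    # pooling them for the interference fit
    sc_a = np.where(valid, ann, 0.0).sum() / np.where(valid, exp_rf_a, 0.0).sum()
    sc_c = np.where(valid, cen, 0.0).sum() / np.where(valid, exp_rf_c, 0.0).sum()
    for k in range(nblk):
        sel = (np.arange(layout.n_azimuthal) % nblk) == k
        o = (np.where(valid[:, sel, :], ann[:, sel, :], 0.0).sum(axis=(1, 2))
             + np.where(valid[:, sel, :], cen[:, sel, :], 0.0).sum(axis=(1, 2)))
        e = (np.where(valid[:, sel, :], exp_rf_a[:, sel, :], 0.0).sum(axis=(1, 2)) * sc_a
             + np.where(valid[:, sel, :], exp_rf_c[:, sel, :], 0.0).sum(axis=(1, 2)) * sc_c)
        f_sens[k] = np.where(e > 0, o / np.maximum(e, 1e-12), 1.0)
    f_sens /= f_sens[f_sens > 0].mean()
    f_sens = np.clip(f_sens, 1e-3, None)

    fmap = f_sens.T[:, np.arange(layout.n_azimuthal) % nblk]  # (n_radial, n_azim)
    sens = s0 * r_sens[:, None, None] * fmap[:, :, None]
    mean_sens = sens[valid].mean()
    eta = np.ones_like(sens)
    eta[valid] = mean_sens / np.clip(sens[valid], 1e-9 * mean_sens, None)

    return NormalisationComponents(
        eps=1.0 / eps_sens, b_axial=1.0 / b_sens, g_axial=1.0 / g_sens,
        r_radial=1.0 / r_sens, f_interference=1.0 / f_sens, layout=layout,
        sens_sino=sens.astype(np.float32), eta_sino=eta.astype(np.float32),
        valid=valid)


# --------------------------------------------------------------------------
# well-counter calibration
# --------------------------------------------------------------------------

@dataclass
class WellCounterCalibration:
    wcc: float
    c_abs: float
    c_arb: float


def well_counter_calibrate(image: np.ndarray, voxel_xy_mm: float,
                           slice_z_mm: np.ndarray, known_concentration: float,
                           roi_radius_mm: float = 70.0,
                           z_range_mm: float = 80.0) -> WellCounterCalibration:
    """WCC = C_abs / C_arb with C_arb the mean of centred circular ROIs
    over the transverse slices within ``z_range_mm`` of the centre."""
    nx, ny, nz = image.shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * voxel_xy_mm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * voxel_xy_mm
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    roi = X**2 + Y**2 <= roi_radius_mm**2
    sel = np.abs(np.asarray(slice_z_mm)) <= z_range_mm
    if not np.any(sel) or not np.any(roi):
        raise ValueError("ROI does not intersect the image")
    c_arb = float(image[:, :, sel][roi].mean())
    if c_arb <= 0:
        raise ValueError("zero mean in calibration ROI")
    return WellCounterCalibration(known_concentration / c_arb,
                                  known_concentration, c_arb)
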