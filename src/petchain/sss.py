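"""Single Scatter Simulation (SSS) with tail fitting and iteration.

The scatter rate on a LOR between detectors A and B is modelled as the
sum over sampled scatter points S of two contributions: annihilations on
the segment S-A whose unscattered photon reaches A while the partner
Compton-scatters at S into B, and the mirrored term with emitters on
S-B.  Each term is the emitter line integral times the attenuation of
both legs (the scattered leg at the Compton-shifted energy), the
detector efficiencies at the respective energies, the solid-angle factor
sigma_A*sigma_B/(4*pi*l_A^2*l_B^2), and the Klein-Nishina angular
probability mu * (dsigma/dOmega)/sigma_c at the scatter point.

Emission and attenuation images are down-sampled to a 32x32x4 grid;
scatter points are the coarse cells with mu >= 0.04 cm^-1, each jittered
uniformly within its cell to avoid sampling artefacts; the detector
system is down-sampled to 68 transaxial x 4 axial elements.  The coarse
scatter sinogram is up-sampled with cubic splines radially and axially
and linear (periodic) interpolation azimuthally, and scaled to the
measured prompts by a least-squares fit over the object-free sinogram
tails.  The procedure is iterated with FBP re-estimates of the emission
image, averaging the first two iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.interpolate import CubicSpline

from . import physics
from .corrections import AttenuationSinogram, EstimationError, NormalisationComponents
from .geometry import ScannerModel, SinogramLayout
from .phantoms import VoxelPhantom
from .recon import ImageGrid, ReconImage, fbp_initial

MU_SCATTER_POINT_MIN = 0.04  # cm^-1
TAIL_MU_PATH_MAX = 1e-3      # optical depth below which a bin is object-free


@dataclass
class ScatterEstimate:
    """Result of one SSS pass (optionally the average of two)."""

    coarse: np.ndarray           # (n_rad_c, n_azim_c, n_plane_c)
    upsampled: np.ndarray        # fine sinogram, shape = layout.shape
    scaled: np.ndarray           # beta * upsampled / eta + q, counts domain
    beta: float
    intercept: float
    tail_mask: np.ndarray
    n_scatter_points: int
    history: list = field(default_factory=list)


# --------------------------------------------------------------------------
# down-sampling helpers
# --------------------------------------------------------------------------

def downsample_to_coarse(values: np.ndarray, origin, voxel_size,
                         coarse_shape=(32, 32, 4),
                         extent=(700.0, 700.0, 190.8)):
    """Block-average a fine grid into the coarse SSS grid centred on the
    isocenter (fine voxels outside the coarse extent are ignored; coarse
    cells with no fine voxel are zero)."""
    nx, ny, nz = values.shape
    cs = np.asarray(coarse_shape)
    ext = np.asarray(extent, dtype=float)
    cell = ext / cs
    out = np.zeros(tuple(cs))
    cnt = np.zeros(tuple(cs))
    idx = []
    ok = np.ones(values.shape, dtype=bool)
    for a, n in enumerate((nx, ny, nz)):
        centers = origin[a] + (np.arange(n) + 0.5) * (
            voxel_size if np.isscalar(voxel_size) else voxel_size[a])
        ci = np.floor((centers + ext[a] / 2.0) / cell[a]).astype(int)
        good = (ci >= 0) & (ci < cs[a])
        sh = [1, 1, 1]
        sh[a] = n
        ok &= good.reshape(sh)
        idx.append(ci)
    I, J, K = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    np.add.at(out, (I[ok], J[ok], K[ok]), values[ok])
    np.add.at(cnt, (I[ok], J[ok], K[ok]), 1.0)
    return np.where(cnt > 0, out / np.maximum(cnt, 1), 0.0), cell


def coarse_detectors(model: ScannerModel, n_tax: int = 68, n_ax: int = 4):
    """Down-sampled detector ring: positions (n, 3), inward normals
    (n, 3), effective face area (mm^2), and (tax, ax) indices."""
    spec = model.spec
    R = spec.front_face_radius
    ang = np.pi / 2.0 - (np.arange(n_tax) + 0.5) * (2.0 * np.pi / n_tax)
    zax = (np.arange(n_ax) - (n_ax - 1) / 2.0) * (model.axial_extent / n_ax)
    A, Z = np.meshgrid(ang, zax, indexing="ij")
    pos = np.stack([R * np.cos(A), R * np.sin(A), Z], axis=-1).reshape(-1, 3)
    nrm = np.stack([-np.cos(A), -np.sin(A), np.zeros_like(A)], axis=-1).reshape(-1, 3)
    width = 2.0 * np.pi * R / n_tax
    height = model.axial_extent / n_ax
    ti, ai = np.meshgrid(np.arange(n_tax), np.arange(n_ax), indexing="ij")
    return pos, nrm, width * height, ti.ravel(), ai.ravel()


def _efficiency_table(cfg_window=(425.0, 650.0), fwhm=0.0963, det_eff=0.98,
                      depth_cm=2.5):
    """Detector efficiency vs photon energy: blurred-window acceptance
    times the LYSO interaction probability times the set efficiency."""
    e = physics.ENERGY_GRID
    acc = physics.window_acceptance(e, cfg_window[0], cfg_window[1], fwhm)
    p = physics.detector_interaction_probability(e, depth_cm)
    return (acc * p * det_eff).astype(np.float64)


# --------------------------------------------------------------------------
# core double loop
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _ray_march_coarse(lam, mu, x0, y0, z0, x1, y1, z1, ex, ey, ez, cx, cy, cz,
                      n_steps):
    """Trapezoid-free fixed-step march of integral(lam) and integral(mu)
    from (x0,y0,z0) to (x1,y1,z1) over the coarse grids (cm units out)."""
    nx, ny, nz = lam.shape
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    ln = np.sqrt(dx * dx + dy * dy + dz * dz)
    sl = 0.0
    sm = 0.0
    if ln < 1e-9:
        return 0.0, 0.0
    step = ln / n_steps
    for k in range(n_steps):
        t = (k + 0.5) / n_steps
        x = x0 + t * dx
        y = y0 + t * dy
        z = z0 + t * dz
        i = int((x + ex) / cx)
        j = int((y + ey) / cy)
        l = int((z + ez) / cz)
        if i < 0 or i >= nx or j < 0 or j >= ny or l < 0 or l >= nz:
            continue
        sl += lam[i, j, l]
        sm += mu[i, j, l]
    return sl * step * 0.1, sm * step * 0.1


@njit(cache=True, fastmath=True)
def _sss_core(points, mu_at_point, lam_c, mu_c, ext_half, cell,
              det_pos, det_nrm, det_area, det_tax, det_ax,
              n_tax, min_dtax, radial_extent, eff_tab, ratio_tab,
              n_rad_c, n_azim_c, radial_bin_c, out, cnt, n_march):
    """Accumulate the SSS estimate on the coarse sinogram."""
    n_pts = points.shape[0]
    n_det = det_pos.shape[0]
    kn_tot = 2.865403638016735e-25  # sigma_KN(511 keV), cm^2/electron
    re2 = 7.94080e-26
    half_r = n_rad_c // 2
    # per (point, detector) leg cache
    Ll = np.empty((n_pts, n_det))
    Lm = np.empty((n_pts, n_det))
    dist = np.empty((n_pts, n_det))
    cosw = np.empty((n_pts, n_det))
    for p in range(n_pts):
        for d in range(n_det):
            dx = det_pos[d, 0] - points[p, 0]
            dy = det_pos[d, 1] - points[p, 1]
            dz = det_pos[d, 2] - points[p, 2]
            ln = np.sqrt(dx * dx + dy * dy + dz * dz)
            dist[p, d] = ln
            cw = -(dx * det_nrm[d, 0] + dy * det_nrm[d, 1] + dz * det_nrm[d, 2]) / ln
            cosw[p, d] = abs(cw)
            sl, sm = _ray_march_coarse(lam_c, mu_c,
                                       points[p, 0], points[p, 1], points[p, 2],
                                       det_pos[d, 0], det_pos[d, 1], det_pos[d, 2],
                                       ext_half[0], ext_half[1], ext_half[2],
                                       cell[0], cell[1], cell[2], n_march)
            Ll[p, d] = sl
            Lm[p, d] = sm
    eff511 = eff_tab[511 - 50]
    for d1 in range(n_det):
        for d2 in range(d1 + 1, n_det):
            dt = (det_tax[d1] - det_tax[d2]) % n_tax
            dtm = min(dt, n_tax - dt)
            if dtm < min_dtax:
                continue
            x1 = det_pos[d1, 0]
            y1 = det_pos[d1, 1]
            x2 = det_pos[d2, 0]
            y2 = det_pos[d2, 1]
            alpha = np.arctan2(y2 - y1, x2 - x1)
            if alpha < 0.0:
                alpha += np.pi
            if alpha >= np.pi:
                alpha -= np.pi
            ca = np.cos(alpha)
            sa = np.sin(alpha)
            s = x1 * sa - y1 * ca
            if abs(s) > radial_extent:
                continue
            rb = int(np.round(s / radial_bin_c)) + half_r
            if rb < 0 or rb >= n_rad_c:
                continue
            vb = int(alpha / np.pi * n_azim_c)
            if vb >= n_azim_c:
                vb = n_azim_c - 1
            pb = det_ax[d1] + det_ax[d2]
            acc = 0.0
            for p in range(n_pts):
                l1 = dist[p, d1]
                l2 = dist[p, d2]
                u1x = (det_pos[d1, 0] - points[p, 0]) / l1
                u1y = (det_pos[d1, 1] - points[p, 1]) / l1
                u1z = (det_pos[d1, 2] - points[p, 2]) / l1
                u2x = (det_pos[d2, 0] - points[p, 0]) / l2
                u2y = (det_pos[d2, 1] - points[p, 1]) / l2
                u2z = (det_pos[d2, 2] - points[p, 2]) / l2
                cos_t = -(u1x * u2x + u1y * u2y + u1z * u2z)
                ratio = 1.0 / (2.0 - cos_t)  # E'/E at 511 keV (alpha=1)
                e_sc = 511.0 * ratio
                ie = int(e_sc) - 50
                if ie < 0:
                    ie = 0
                elif ie > 650:
                    ie = 650
                kn = 0.5 * re2 * ratio * ratio * (ratio + 1.0 / ratio
                                                  - (1.0 - cos_t * cos_t))
                # solid angles, capped in the near field (liner points can
                # sit close to a detector face)
                om1 = det_area * cosw[p, d1] / (l1 * l1)
                om2 = det_area * cosw[p, d2] / (l2 * l2)
                if om1 > 2.0:
                    om1 = 2.0
                if om2 > 2.0:
                    om2 = 2.0
                geom = om1 * om2 / (4.0 * np.pi)
                phys = mu_at_point[p] * kn / kn_tot * geom
                att_sc_1 = np.exp(-Lm[p, d1] * ratio_tab[ie])
                att_sc_2 = np.exp(-Lm[p, d2] * ratio_tab[ie])
                term_a = Ll[p, d1] * np.exp(-Lm[p, d1]) * att_sc_2 \
                    * eff511 * eff_tab[ie]
                term_b = Ll[p, d2] * np.exp(-Lm[p, d2]) * att_sc_1 \
                    * eff511 * eff_tab[ie]
                acc += phys * (term_a + term_b)
            out[rb, vb, pb] += acc
            cnt[rb, vb, pb] += 1.0
    return


def sss_scatter_estimate(emission: ReconImage | np.ndarray,
                         phantom: VoxelPhantom, model: ScannerModel,
                         rng: np.random.Generator,
                         emission_grid: ImageGrid | None = None,
                         coarse_shape=(32, 32, 4), n_det_tax=68, n_det_ax=4,
                         jitter=True, digitizer=None, n_march=48,
                         include_liner=True, n_liner=96):
    """Coarse SSS estimate.

    Returns ``(coarse sinogram, meta)`` where meta carries the coarse
    axis coordinates needed for up-sampling and the scatter-point count.
    """
    if isinstance(emission, ReconImage):
        emis, egrid = emission.values, emission.grid
    else:
        emis, egrid = emission, emission_grid
    extent = (700.0, 700.0, model.axial_extent)
    lam_c, cell = downsample_to_coarse(emis, egrid.origin, (egrid.dx, egrid.dx, egrid.dz),
                                       coarse_shape, extent)
    mu_c, _ = downsample_to_coarse(phantom.mu_511, phantom.origin,
                                   phantom.voxel_size, coarse_shape, extent)
    # activity lives inside the attenuating compartments; masking the
    # emission estimate by the mu support suppresses reconstruction noise
    # outside the object, which would otherwise broaden the scatter shape
    lam_c = lam_c * (mu_c >= MU_SCATTER_POINT_MIN)
    pts_idx = np.argwhere(mu_c >= MU_SCATTER_POINT_MIN)
    ext_half = np.asarray(extent) / 2.0
    centers = (pts_idx + 0.5) * cell - ext_half
    if jitter and pts_idx.size:
        centers = centers + (rng.random(centers.shape) - 0.5) * cell
    mu_at = mu_c[pts_idx[:, 0], pts_idx[:, 1], pts_idx[:, 2]] if pts_idx.size \
        else np.empty(0)

    spec = model.spec
    if include_liner and spec.bore_liner_thickness > 0 and pts_idx.size:
        # the plastic bore liner lies outside the coarse-grid extent; add a
        # ring of scatter points carrying its volume-weighted mu
        thick = spec.bore_liner_thickness
        r_l = spec.bore_liner_radius + thick / 2.0
        ncz = coarse_shape[2]
        slab_h = extent[2] / ncz
        ang = ((np.arange(n_liner)[:, None]
                + (rng.random((n_liner, ncz)) if jitter else 0.5))
               * 2.0 * np.pi / n_liner)
        zc = ((np.arange(ncz) - (ncz - 1) / 2.0) * slab_h)[None, :] \
            + ((rng.random((n_liner, ncz)) - 0.5) * slab_h if jitter else 0.0)
        liner_pts = np.stack([r_l * np.cos(ang), r_l * np.sin(ang),
                              np.broadcast_to(zc, ang.shape)], axis=-1).reshape(-1, 3)
        v_point = 2.0 * np.pi * r_l * thick * slab_h / n_liner
        v_cell = float(np.prod(cell))
        mu_liner = float(physics.PMMA.mu(511.0)) * v_point / v_cell
        centers = np.vstack([centers, liner_pts])
        mu_at = np.concatenate([mu_at, np.full(liner_pts.shape[0], mu_liner)])

    det_pos, det_nrm, det_area, det_tax, det_ax = coarse_detectors(
        model, n_det_tax, n_det_ax)
    spec = model.spec
    min_dtax = int(round(spec.min_sector_difference * n_det_tax / spec.n_rsector))
    radial_bin_c = 700.0 / (n_det_tax // 2)
    n_rad_c = 2 * int(np.ceil(350.0 / radial_bin_c)) + 1
    n_azim_c = n_det_tax // 2
    n_plane_c = 2 * n_det_ax - 1
    out = np.zeros((n_rad_c, n_azim_c, n_plane_c))
    cnt = np.zeros((n_rad_c, n_azim_c, n_plane_c))
    if digitizer is None:
        eff = _efficiency_table()
    else:
        eff = _efficiency_table(digitizer.energy_window,
                                digitizer.energy_resolution_fwhm,
                                digitizer.detection_efficiency,
                                spec.crystal_size[2] / 10.0)
    if pts_idx.size:
        _sss_core(np.ascontiguousarray(centers, np.float64),
                  np.ascontiguousarray(mu_at, np.float64),
                  np.ascontiguousarray(lam_c, np.float64),
                  np.ascontiguousarray(mu_c, np.float64),
                  ext_half, cell, det_pos, det_nrm, float(det_area),
                  det_tax.astype(np.int64), det_ax.astype(np.int64),
                  n_det_tax, min_dtax, 350.0, eff,
                  physics.water_mu_ratio_table(),
                  n_rad_c, n_azim_c, radial_bin_c, out, cnt, n_march)
        # mean over the detector pairs sampling each coarse bin: the coarse
        # sinogram is a smooth sample of the scatter rate, not a histogram.
        # Bins no detector pair addresses are padded from their radial
        # neighbours afterwards so the up-sampling spline stays smooth.
        out = np.where(cnt > 0, out / np.maximum(cnt, 1.0), 0.0)
        sampled = out.copy()
        _fill_empty_radial(out, cnt)
    meta = dict(
        s_centers=(np.arange(n_rad_c) - n_rad_c // 2) * radial_bin_c,
        phi_centers=(np.arange(n_azim_c) + 0.5) * np.pi / n_azim_c,
        z_planes=(np.arange(n_plane_c) - (n_plane_c - 1) / 2.0)
        * (model.axial_extent / n_det_ax / 2.0),
        n_points=int(pts_idx.shape[0]),
        pair_count=cnt,
        sampled=sampled if pts_idx.size else out,
    )
    return out, meta


# --------------------------------------------------------------------------
# up-sampling & tail fit
# --------------------------------------------------------------------------

def _fill_empty_radial(out, cnt):
    """Coarse bins sampled by no detector pair inherit the nearest sampled
    value along the radial axis (keeps the spline from dipping to zero
    inside the object)."""
    n_rad, n_azim, n_pl = out.shape
    for v in range(n_azim):
        for p in range(n_pl):
            col = out[:, v, p]
            has = cnt[:, v, p] > 0
            if not has.any():
                continue
            idx = np.flatnonzero(has)
            col[:idx[0]] = 0.0
            for a, b in zip(idx[:-1], idx[1:]):
                if b - a > 1:
                    mid = (a + b) // 2
                    col[a + 1:mid + 1] = col[a]
                    col[mid + 1:b] = col[b]
            col[idx[-1] + 1:] = 0.0


def upsample_scatter(coarse: np.ndarray, meta: dict, model: ScannerModel,
                     layout: SinogramLayout) -> np.ndarray:
    """Separable interpolation to the full sinogram: cubic splines in the
    radial and axial directions, periodic linear interpolation in the
    azimuthal direction; clamped at zero."""
    s_c = meta["s_centers"]
    phi_c = meta["phi_centers"]
    z_c = meta["z_planes"]
    s_f = (np.arange(layout.n_radial) - layout.n_radial // 2) * layout.radial_bin_mm
    phi_f = (np.arange(layout.n_azimuthal) + 0.5) * np.pi / layout.n_azimuthal
    z_f = layout.plane_z(model)

    cs = CubicSpline(s_c, coarse, axis=0, bc_type="natural")
    a = cs(np.clip(s_f, s_c[0], s_c[-1]))
    # periodic linear in azimuth (period pi)
    period = np.pi
    phi_ext = np.concatenate([phi_c, [phi_c[0] + period]])
    a_ext = np.concatenate([a, a[:, :1, :]], axis=1)
    b = np.empty((a.shape[0], phi_f.size, a.shape[2]))
    for i, ph in enumerate(phi_f):
        ph_m = (ph - phi_c[0]) % period + phi_c[0]
        k = np.searchsorted(phi_ext, ph_m) - 1
        k = np.clip(k, 0, phi_ext.size - 2)
        w = (ph_m - phi_ext[k]) / (phi_ext[k + 1] - phi_ext[k])
        b[:, i, :] = (1 - w) * a_ext[:, k, :] + w * a_ext[:, k + 1, :]
    cz = CubicSpline(z_c, b, axis=2, bc_type="natural")
    out = cz(np.clip(z_f, z_c[0], z_c[-1]))
    return np.maximum(out, 0.0)


def fit_scatter_tails(scatter_shape: np.ndarray, prompts: np.ndarray,
                      acf: AttenuationSinogram, randoms=None, valid=None,
                      prompt_gamma: bool = False):
    """Least-squares scale of the scatter shape to the prompts over the
    object-free tail bins (w_b = 1 where the forward-projected mu support
    is empty).  The intercept q is forced to zero for isotopes without
    prompt gamma emission.  Returns (beta, q, tail_mask)."""
    tails = acf.mu_path < TAIL_MU_PATH_MAX
    if valid is not None:
        tails = tails & valid
    if not np.any(tails):
        raise EstimationError("no object-free tail bins to fit")
    y = np.asarray(prompts, dtype=np.float64)[tails]
    if randoms is not None:
        y = y - np.asarray(randoms, dtype=np.float64)[tails]
    s = np.asarray(scatter_shape, dtype=np.float64)[tails]
    if prompt_gamma:
        A = np.stack([s, np.ones_like(s)], axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        beta, q = float(coef[0]), float(coef[1])
    else:
        denom = float(np.dot(s, s))
        if denom <= 0:
            raise EstimationError("scatter shape vanishes on the tails")
        beta, q = float(np.dot(s, y) / denom), 0.0
    return beta, q, tails


# --------------------------------------------------------------------------
# iterative SSS
# --------------------------------------------------------------------------

def iterate_sss(prompts: np.ndarray, randoms: np.ndarray,
                acf: AttenuationSinogram, norm: NormalisationComponents,
                phantom: VoxelPhantom, model: ScannerModel,
                layout: SinogramLayout, rng: np.random.Generator,
                n_iter: int = 2, digitizer=None, fbp_nx: int = 128,
                coarse_shape=(32, 32, 4)) -> ScatterEstimate:
    """Iterative SSS: the emission image is an FBP reconstruction of the
    corrected prompts (no scatter term in iteration 0), the scatter
    estimate is refreshed each iteration, and from the second iteration
    on the running estimate is the average of the first two."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    eta = norm.eta_sino
    valid = norm.valid
    scaled = np.zeros(layout.shape)
    history = []
    upsampled = None
    coarse = None
    meta = None
    tails = None
    for it in range(n_iter):
        corrected = (np.asarray(prompts, dtype=np.float64)
                     - np.asarray(randoms, dtype=np.float64) - scaled)
        corrected = np.maximum(corrected, 0.0) * acf.acf * eta * valid
        # heavy rebinning: the scatter model only needs a coarse emission
        # image, and the decimated prompts are sparse per fine bin
        emis = fbp_initial(corrected, model, layout, nx=fbp_nx,
                           rebin=(4, 4, 6))
        coarse, meta = sss_scatter_estimate(emis, phantom, model, rng,
                                            coarse_shape=coarse_shape,
                                            digitizer=digitizer)
        upsampled = upsample_scatter(coarse, meta, model, layout)
        shape = upsampled / eta * valid
        beta, q, tails = fit_scatter_tails(shape, prompts, acf, randoms,
                                           valid=valid)
        this = np.maximum(beta * shape + q, 0.0)
        history.append((beta, q, this))
        if it == 0:
            scaled = this
        else:
            scaled = 0.5 * (history[-2][2] + history[-1][2])
    beta, q, _ = history[-1]
    return ScatterEstimate(coarse=coarse, upsampled=upsampled, scaled=scaled,
                           beta=beta, intercept=q, tail_mask=tails,
                           n_scatter_points=meta["n_points"],
                           history=[(b, qq) for b, qq, _ in history])
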