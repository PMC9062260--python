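"""Tomographic engines: Joseph forward/back projection, OS-EM with
attenuation/normalisation in the system matrix and additive
randoms+scatter terms, an FBP initialiser for the scatter model, and the
Gaussian post-filter.

The forward model for bin b is  yhat_b = c_b (P x)_b + r_b + s_b  with
c_b = 1/(acf_b * eta_b); the sensitivity image backprojects c_b so that
it matches the back-projected image, and the multiplicative EM update
preserves nonnegativity.  Subsets partition azimuthal views by index
modulo the subset count, processed in fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .geometry import ScannerModel, SinogramLayout, all_bin_endpoints

EPS_DENOM = 1e-10


@dataclass(frozen=True)
class ImageGrid:
    """Reconstruction grid: (nx, ny, nz) voxels, transaxial pixel dx=dy,
    slice pitch dz; centred on the isocenter."""

    nx: int
    ny: int
    nz: int
    dx: float
    dz: float

    @property
    def shape(self):
        return (self.nx, self.ny, self.nz)

    @property
    def origin(self):
        return np.array([-self.nx * self.dx / 2.0, -self.ny * self.dx / 2.0,
                         -self.nz * self.dz / 2.0])

    @property
    def slice_z(self):
        return (np.arange(self.nz) - (self.nz - 1) / 2.0) * self.dz

    @classmethod
    def from_layout(cls, model: ScannerModel, layout: SinogramLayout,
                    nx: int = 256, fov_mm: float = 700.0):
        dz = (model.spec.axial_pitch / 2.0 if layout.axial_mode == "ssrb"
              else model.spec.axial_pitch)
        nz = layout.n_planes if layout.axial_mode == "ssrb" else model.spec.n_rings
        return cls(nx, nx, nz, fov_mm / nx, dz)


@dataclass(frozen=True)
class ReconConfig:
    n_iterations: int = 4
    n_subsets: int = 16
    projector: str = "joseph"
    nx: int = 256
    fov_mm: float = 700.0
    postfilter_fwhm_mm: tuple = (4.0, 4.0)  # transaxial, axial
    corrections: tuple = ("acf", "norm", "randoms", "scatter")
    tof: bool = False  # TOF-weighted EM (the clinical reconstructions are TOF)


@dataclass
class ReconImage:
    values: np.ndarray  # (nx, ny, nz), nonnegative
    grid: ImageGrid
    provenance: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Joseph projector
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _joseph_one(img, ox, oy, oz, dxy, dzv, x0, y0, z0, x1, y1, z1, back, val):
    """Forward-project one ray (back=False, returns the line integral in
    value*cm) or backproject ``val`` along it with the transposed weights
    (back=True, returns 0)."""
    nx, ny, nz = img.shape
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    ln = np.sqrt(dx * dx + dy * dy + dz * dz)
    if ln < 1e-9:
        return 0.0
    ax = abs(dx)
    ay = abs(dy)
    az = abs(dz)
    total = 0.0
    if ax >= ay and ax >= az:
        # march along x at pixel pitch, restricted to the ray's span
        step = dxy * ln / ax * 0.1
        lo = (min(x0, x1) - ox) / dxy - 0.5
        hi = (max(x0, x1) - ox) / dxy - 0.5
        k0 = max(int(np.ceil(lo)), 0)
        k1 = min(int(np.floor(hi)) + 1, nx)
        for k in range(k0, k1):
            xs = ox + (k + 0.5) * dxy
            t = (xs - x0) / dx
            if t < 0.0 or t > 1.0:
                continue
            ys = (y0 + t * dy - oy) / dxy - 0.5
            zs = (z0 + t * dz - oz) / dzv - 0.5
            iy = int(np.floor(ys))
            iz = int(np.floor(zs))
            fy = ys - iy
            fz = zs - iz
            for oy_ in range(2):
                jy = iy + oy_
                if jy < 0 or jy >= ny:
                    continue
                wy = fy if oy_ == 1 else 1.0 - fy
                for oz_ in range(2):
                    jz = iz + oz_
                    if jz < 0 or jz >= nz:
                        continue
                    w = wy * (fz if oz_ == 1 else 1.0 - fz)
                    if back:
                        img[k, jy, jz] += w * val * step
                    else:
                        total += w * img[k, jy, jz]
        return total * step
    elif ay >= az:
        step = dxy * ln / ay * 0.1
        lo = (min(y0, y1) - oy) / dxy - 0.5
        hi = (max(y0, y1) - oy) / dxy - 0.5
        k0 = max(int(np.ceil(lo)), 0)
        k1 = min(int(np.floor(hi)) + 1, ny)
        for k in range(k0, k1):
            ys = oy + (k + 0.5) * dxy
            t = (ys - y0) / dy
            if t < 0.0 or t > 1.0:
                continue
            xs = (x0 + t * dx - ox) / dxy - 0.5
            zs = (z0 + t * dz - oz) / dzv - 0.5
            ix = int(np.floor(xs))
            iz = int(np.floor(zs))
            fx = xs - ix
            fz = zs - iz
            for ox_ in range(2):
                jx = ix + ox_
                if jx < 0 or jx >= nx:
                    continue
                wx = fx if ox_ == 1 else 1.0 - fx
                for oz_ in range(2):
                    jz = iz + oz_
                    if jz < 0 or jz >= nz:
                        continue
                    w = wx * (fz if oz_ == 1 else 1.0 - fz)
                    if back:
                        img[jx, k, jz] += w * val * step
                    else:
                        total += w * img[jx, k, jz]
        return total * step
    else:
        step = dzv * ln / az * 0.1
        for k in range(nz):
            zs = oz + (k + 0.5) * dzv
            t = (zs - z0) / dz
            if t < 0.0 or t > 1.0:
                continue
            xs = (x0 + t * dx - ox) / dxy - 0.5
            ys = (y0 + t * dy - oy) / dxy - 0.5
            ix = int(np.floor(xs))
            iy = int(np.floor(ys))
            fx = xs - ix
            fy = ys - iy
            for ox_ in range(2):
                jx = ix + ox_
                if jx < 0 or jx >= nx:
                    continue
                wx = fx if ox_ == 1 else 1.0 - fx
                for oy_ in range(2):
                    jy = iy + oy_
                    if jy < 0 or jy >= ny:
                        continue
                    w = wx * (fy if oy_ == 1 else 1.0 - fy)
                    if back:
                        img[jx, jy, k] += w * val * step
                    else:
                        total += w * img[jx, jy, k]
        return total * step


@njit(cache=True, fastmath=True)
def _joseph_fwd_batch(img, ox, oy, oz, dxy, dzv, e1, e2, out):
    for i in range(e1.shape[0]):
        out[i] = _joseph_one(img, ox, oy, oz, dxy, dzv,
                             e1[i, 0], e1[i, 1], e1[i, 2],
                             e2[i, 0], e2[i, 1], e2[i, 2], False, 0.0)


@njit(cache=True, fastmath=True)
def _joseph_back_batch(img, ox, oy, oz, dxy, dzv, e1, e2, vals):
    for i in range(e1.shape[0]):
        _joseph_one(img, ox, oy, oz, dxy, dzv,
                    e1[i, 0], e1[i, 1], e1[i, 2],
                    e2[i, 0], e2[i, 1], e2[i, 2], True, vals[i])


def joseph_project(image: np.ndarray, grid: ImageGrid, e1, e2) -> np.ndarray:
    """Line integrals (value*cm) of ``image`` along rays e1->e2 (mm)."""
    e1 = np.atleast_2d(np.asarray(e1, dtype=np.float64))
    e2 = np.atleast_2d(np.asarray(e2, dtype=np.float64))
    out = np.empty(e1.shape[0])
    o = grid.origin
    _joseph_fwd_batch(np.ascontiguousarray(image, dtype=np.float64),
                      o[0], o[1], o[2], grid.dx, grid.dz, e1, e2, out)
    return out


def joseph_backproject(values, grid: ImageGrid, e1, e2) -> np.ndarray:
    """Adjoint of :func:`joseph_project`."""
    e1 = np.atleast_2d(np.asarray(e1, dtype=np.float64))
    e2 = np.atleast_2d(np.asarray(e2, dtype=np.float64))
    img = np.zeros(grid.shape, dtype=np.float64)
    o = grid.origin
    _joseph_back_batch(img, o[0], o[1], o[2], grid.dx, grid.dz, e1, e2,
                       np.ascontiguousarray(values, dtype=np.float64))
    return img


# --------------------------------------------------------------------------
# OS-EM
# --------------------------------------------------------------------------

class _BinSet:
    """Valid sinogram bins flattened to arrays, with endpoints and subset
    assignment by azimuthal view."""

    def __init__(self, model, layout, valid=None):
        shape = layout.shape
        if valid is None:
            valid = np.ones(shape, dtype=bool)
        self.valid = valid
        r, v, p = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                              np.arange(shape[2]), indexing="ij")
        self.r = r[valid]
        self.v = v[valid]
        self.p = p[valid]
        from .geometry import bin_endpoints
        e1, e2 = bin_endpoints(model, layout, self.r, self.v, self.p)
        self.e1 = np.ascontiguousarray(e1, dtype=np.float64)
        self.e2 = np.ascontiguousarray(e2, dtype=np.float64)

    def subset(self, k, n_subsets):
        return np.flatnonzero(self.v % n_subsets == k)


def sensitivity_image(weights, grid: ImageGrid, bins: _BinSet, idx) -> np.ndarray:
    """Backprojection of the per-bin model weights c_b = 1/(acf*eta) over
    one subset's LORs; doubling every acf halves it inside the shadow."""
    return joseph_backproject(weights[idx], grid, bins.e1[idx], bins.e2[idx])


def osem_reconstruct(prompts: np.ndarray, model: ScannerModel,
                     layout: SinogramLayout, cfg: ReconConfig = ReconConfig(),
                     acf=None, eta=None, randoms=None, scatter=None,
                     valid=None, n_iterations=None) -> ReconImage:
    """Ordered-subsets EM reconstruction of a (non-TOF) prompt sinogram."""
    if np.any(np.asarray(prompts) < 0):
        raise ValueError("prompt sinogram must be nonnegative")
    grid = ImageGrid.from_layout(model, layout, cfg.nx, cfg.fov_mm)
    bins = _BinSet(model, layout, valid)
    y = np.asarray(prompts, dtype=np.float64)[bins.valid]
    c = np.ones_like(y)
    if acf is not None and "acf" in cfg.corrections:
        c /= np.asarray(acf, dtype=np.float64)[bins.valid]
    if eta is not None and "norm" in cfg.corrections:
        c /= np.asarray(eta, dtype=np.float64)[bins.valid]
    add = np.zeros_like(y)
    if randoms is not None and "randoms" in cfg.corrections:
        add += np.asarray(randoms, dtype=np.float64)[bins.valid]
    if scatter is not None and "scatter" in cfg.corrections:
        add += np.asarray(scatter, dtype=np.float64)[bins.valid]

    n_iter = cfg.n_iterations if n_iterations is None else n_iterations
    nsub = cfg.n_subsets
    sens = [sensitivity_image(c, grid, bins, bins.subset(k, nsub))
            for k in range(nsub)]
    x = np.ones(grid.shape, dtype=np.float64)
    fov_mask = _fov_mask(grid, cfg.fov_mm)
    x *= fov_mask
    for _ in range(n_iter):
        for k in range(nsub):
            idx = bins.subset(k, nsub)
            proj = np.empty(idx.size)
            o = grid.origin
            _joseph_fwd_batch(x, o[0], o[1], o[2], grid.dx, grid.dz,
                              bins.e1[idx], bins.e2[idx], proj)
            yhat = c[idx] * proj + add[idx]
            ratio = y[idx] / np.maximum(yhat, EPS_DENOM)
            back = joseph_backproject(c[idx] * ratio, grid,
                                      bins.e1[idx], bins.e2[idx])
            x = x * back / np.maximum(sens[k], EPS_DENOM)
            x *= fov_mask
    return ReconImage(x, grid, provenance=dict(
        n_iterations=n_iter, n_subsets=nsub, nx=cfg.nx,
        corrections=list(cfg.corrections)))


def _fov_mask(grid: ImageGrid, fov_mm):
    xs = (np.arange(grid.nx) - (grid.nx - 1) / 2.0) * grid.dx
    ys = (np.arange(grid.ny) - (grid.ny - 1) / 2.0) * grid.dx
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    return ((X**2 + Y**2) <= (fov_mm / 2.0) ** 2)[:, :, None].astype(float)


# --------------------------------------------------------------------------
# TOF OS-EM (sparse TOF histogram)
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _joseph_tof_one(img, ox, oy, oz, dxy, dzv, x0, y0, z0, x1, y1, z1,
                    s0, sigma, back, val):
    """Joseph ray march weighted by a Gaussian TOF kernel centred ``s0``
    mm from the ray midpoint (positive towards the second endpoint).
    The kernel is a probability along the ray (sums to ~1), so the
    non-TOF sensitivity image remains valid."""
    nx, ny, nz = img.shape
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    ln = np.sqrt(dx * dx + dy * dy + dz * dz)
    if ln < 1e-9:
        return 0.0
    # parametric window around the TOF centre (t in [0,1])
    tc = 0.5 + s0 / ln
    half = 4.0 * sigma / ln
    t_lo = tc - half
    t_hi = tc + half
    if t_hi < 0.0 or t_lo > 1.0:
        return 0.0
    ax = abs(dx)
    ay = abs(dy)
    az = abs(dz)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    total = 0.0
    if ax >= ay and ax >= az:
        step = dxy * ln / ax
        lo = (min(x0, x1) - ox) / dxy - 0.5
        hi = (max(x0, x1) - ox) / dxy - 0.5
        k0 = max(int(np.ceil(lo)), 0)
        k1 = min(int(np.floor(hi)) + 1, nx)
        for k in range(k0, k1):
            xs = ox + (k + 0.5) * dxy
            t = (xs - x0) / dx
            if t < t_lo or t > t_hi or t < 0.0 or t > 1.0:
                continue
            u = (t - tc) * ln / sigma
            w0 = np.exp(-0.5 * u * u) * norm * step
            ys = (y0 + t * dy - oy) / dxy - 0.5
            zs = (z0 + t * dz - oz) / dzv - 0.5
            iy = int(np.floor(ys))
            iz = int(np.floor(zs))
            fy = ys - iy
            fz = zs - iz
            for oy_ in range(2):
                jy = iy + oy_
                if jy < 0 or jy >= ny:
                    continue
                wy = (fy if oy_ == 1 else 1.0 - fy) * w0
                for oz_ in range(2):
                    jz = iz + oz_
                    if jz < 0 or jz >= nz:
                        continue
                    w = wy * (fz if oz_ == 1 else 1.0 - fz)
                    if back:
                        img[k, jy, jz] += w * val
                    else:
                        total += w * img[k, jy, jz]
        return total
    elif ay >= az:
        step = dxy * ln / ay
        lo = (min(y0, y1) - oy) / dxy - 0.5
        hi = (max(y0, y1) - oy) / dxy - 0.5
        k0 = max(int(np.ceil(lo)), 0)
        k1 = min(int(np.floor(hi)) + 1, ny)
        for k in range(k0, k1):
            ys = oy + (k + 0.5) * dxy
            t = (ys - y0) / dy
            if t < t_lo or t > t_hi or t < 0.0 or t > 1.0:
                continue
            u = (t - tc) * ln / sigma
            w0 = np.exp(-0.5 * u * u) * norm * step
            xs = (x0 + t * dx - ox) / dxy - 0.5
            zs = (z0 + t * dz - oz) / dzv - 0.5
            ix = int(np.floor(xs))
            iz = int(np.floor(zs))
            fx = xs - ix
            fz = zs - iz
            for ox_ in range(2):
                jx = ix + ox_
                if jx < 0 or jx >= nx:
                    continue
                wx = (fx if ox_ == 1 else 1.0 - fx) * w0
                for oz_ in range(2):
                    jz = iz + oz_
                    if jz < 0 or jz >= nz:
                        continue
                    w = wx * (fz if oz_ == 1 else 1.0 - fz)
                    if back:
                        img[jx, k, jz] += w * val
                    else:
                        total += w * img[jx, k, jz]
        return total
    else:
        return 0.0  # near-axial rays do not occur for transaxial LORs


@njit(cache=True, fastmath=True)
def _tof_fwd_batch(img, ox, oy, oz, dxy, dzv, e1, e2, s0, sigma, out):
    for i in range(e1.shape[0]):
        out[i] = _joseph_tof_one(img, ox, oy, oz, dxy, dzv,
                                 e1[i, 0], e1[i, 1], e1[i, 2],
                                 e2[i, 0], e2[i, 1], e2[i, 2],
                                 s0[i], sigma, False, 0.0)


@njit(cache=True, fastmath=True)
def _tof_back_batch(img, ox, oy, oz, dxy, dzv, e1, e2, s0, sigma, vals):
    for i in range(e1.shape[0]):
        _joseph_tof_one(img, ox, oy, oz, dxy, dzv,
                        e1[i, 0], e1[i, 1], e1[i, 2],
                        e2[i, 0], e2[i, 1], e2[i, 2],
                        s0[i], sigma, True, vals[i])


def osem_tof_reconstruct(coincidences, model: ScannerModel,
                         layout: SinogramLayout, cfg: ReconConfig = None,
                         acf=None, eta=None, randoms=None, scatter=None,
                         valid=None, timing_fwhm_ps: float = 380.0,
                         tof_bin_ps: float = 169.0, n_iterations=None,
                         scatter_tof_sigma_mm: float = 90.0) -> ReconImage:
    """TOF OS-EM on the sparse TOF histogram of a coincidence list.

    Events are binned on the non-TOF sinogram grid plus a TOF axis; only
    occupied (bin, TOF) cells enter the multiplicative update (cells
    with zero counts contribute nothing to the EM numerator), while the
    sensitivity image is the ordinary non-TOF backprojection of the
    model weights, because the TOF kernel is a probability along the
    LOR.  Additive expectations carry simple TOF profiles: randoms are
    uniform over the TOF axis (uncorrelated arrival times), scattered
    coincidences follow an object-centred Gaussian of width
    ``scatter_tof_sigma_mm``.
    """
    from .geometry import bin_lors, bin_endpoints
    import petchain.physics as physics

    cfg = cfg or ReconConfig()
    c = coincidences
    # canonical TOF sign comes from the binning path
    ok, r, v, p, tofb = bin_lors(
        model, _tof_layout(layout, tof_bin_ps), c.ring1, c.tax1, c.ring2,
        c.tax2, c.tof_delta)
    r, v, p, tofb = r[ok], v[ok], p[ok], tofb[ok]
    shape = layout.shape
    flat = ((r * shape[1] + v) * shape[2] + p)
    n_tof = _tof_layout(layout, tof_bin_ps).tof_bins
    key = flat * n_tof + tofb
    uniq, counts = np.unique(key, return_counts=True)
    ub = uniq // n_tof
    ut = uniq % n_tof
    ur = ub // (shape[1] * shape[2])
    uv = (ub // shape[2]) % shape[1]
    up = ub % shape[2]

    grid = ImageGrid.from_layout(model, layout, cfg.nx, cfg.fov_mm)
    e1, e2 = bin_endpoints(model, layout, ur, uv, up)
    e1 = np.ascontiguousarray(e1, np.float64)
    e2 = np.ascontiguousarray(e2, np.float64)
    s0 = (ut - n_tof // 2) * tof_bin_ps * physics.C_MM_PER_PS / 2.0

    sigma_t = timing_fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_x = np.sqrt((sigma_t * physics.C_MM_PER_PS / 2.0) ** 2
                      + (tof_bin_ps * physics.C_MM_PER_PS / 2.0) ** 2 / 12.0)

    def bin_arr(a):
        return np.asarray(a, np.float64)[ur, uv, up]

    ds_tof = tof_bin_ps * physics.C_MM_PER_PS / 2.0  # mm per TOF bin
    cvals = np.ones(uniq.size)
    if acf is not None and "acf" in cfg.corrections:
        cvals /= bin_arr(acf)
    if eta is not None and "norm" in cfg.corrections:
        cvals /= bin_arr(eta)
    add = np.zeros(uniq.size)
    tof_pos = (np.arange(n_tof) - n_tof // 2) * ds_tof
    if randoms is not None and "randoms" in cfg.corrections:
        add += bin_arr(randoms) / n_tof
    if scatter is not None and "scatter" in cfg.corrections:
        q_sc = np.exp(-0.5 * (tof_pos / scatter_tof_sigma_mm) ** 2)
        q_sc /= q_sc.sum()
        add += bin_arr(scatter) * q_sc[ut]
    # the TOF kernel is a probability density along the ray; fold the
    # value*cm projector scale and the TOF bin width into the per-cell
    # model weight so that summing over TOF bins reproduces the non-TOF
    # forward model (and hence the non-TOF sensitivity image)
    cvals = cvals * 0.1 * ds_tof

    # sensitivity: non-TOF backprojection of the model weights over every
    # valid bin (identical to the non-TOF engine)
    bins = _BinSet(model, layout, valid)
    call = np.ones(bins.r.size)
    if acf is not None and "acf" in cfg.corrections:
        call /= np.asarray(acf, np.float64)[bins.valid]
    if eta is not None and "norm" in cfg.corrections:
        call /= np.asarray(eta, np.float64)[bins.valid]
    nsub = cfg.n_subsets
    # joseph ray weights are in value*cm; the TOF kernel is a pure
    # probability, so convert the sensitivity to the same (probability *
    # value) scale by the 0.1 cm/mm factor
    sens = [sensitivity_image(call, grid, bins,
                              bins.subset(k, nsub)) for k in range(nsub)]

    y = counts.astype(np.float64)
    o = grid.origin
    n_iter = cfg.n_iterations if n_iterations is None else n_iterations
    x = np.ones(grid.shape) * _fov_mask(grid, cfg.fov_mm)
    subsets = [np.flatnonzero(uv % nsub == k) for k in range(nsub)]
    for _ in range(n_iter):
        for k in range(nsub):
            idx = subsets[k]
            if idx.size == 0:
                continue
            proj = np.empty(idx.size)
            _tof_fwd_batch(x, o[0], o[1], o[2], grid.dx, grid.dz,
                           e1[idx], e2[idx], s0[idx], sigma_x, proj)
            yhat = cvals[idx] * proj + add[idx]
            ratio = y[idx] / np.maximum(yhat, EPS_DENOM)
            back = np.zeros(grid.shape)
            _tof_back_batch(back, o[0], o[1], o[2], grid.dx, grid.dz,
                            e1[idx], e2[idx], s0[idx], sigma_x,
                            cvals[idx] * ratio)
            x = x * back / np.maximum(sens[k], EPS_DENOM)
            x *= _fov_mask(grid, cfg.fov_mm)
    return ReconImage(x, grid, provenance=dict(
        n_iterations=n_iter, n_subsets=nsub, nx=cfg.nx, tof=True,
        corrections=list(cfg.corrections)))


def _tof_layout(layout: SinogramLayout, tof_bin_ps: float) -> SinogramLayout:
    from dataclasses import replace
    n = 2 * int(np.ceil(2450.0 / tof_bin_ps)) + 1
    return replace(layout, tof_bins=n, tof_bin_ps=tof_bin_ps)


# --------------------------------------------------------------------------
# FBP initialiser (SSRB + 2-D ramp filter)
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fbp_backproject(filtered, cos_a, sin_a, xs, ys, radial_bin, half_r, out):
    n_azim = filtered.shape[1]
    nx = xs.size
    ny = ys.size
    for v in range(n_azim):
        ca = cos_a[v]
        sa = sin_a[v]
        for i in range(nx):
            for j in range(ny):
                s = xs[i] * sa - ys[j] * ca
                rb = s / radial_bin + half_r
                k = int(np.floor(rb))
                f = rb - k
                if k < 0 or k + 1 >= filtered.shape[0]:
                    continue
                out[i, j] += (1.0 - f) * filtered[k, v] + f * filtered[k + 1, v]


def fbp_initial(corrected: np.ndarray, model: ScannerModel,
                layout: SinogramLayout, nx: int = 128, fov_mm: float = 700.0,
                rebin=(1, 1, 1)) -> ReconImage:
    """Ramp-filtered backprojection of a randoms/attenuation/normalisation
    corrected non-TOF sinogram; inverts line integrals in value*cm.

    Span-1 input is first collapsed to SSRB planes; each plane is then
    reconstructed in 2-D.  ``rebin`` = (radial, azimuthal, plane) merge
    factors: binwise averaging before filtering, used when the image only
    seeds the scatter model and the data are sparse.  Output is clamped
    at zero (the scatter model needs a nonnegative emission estimate).
    """
    if layout.axial_mode == "span1":
        ssrb = np.zeros((layout.n_radial, layout.n_azimuthal,
                         2 * layout.n_rings - 1), dtype=np.float64)
        ra, rb = np.divmod(np.arange(layout.n_planes), layout.n_rings)
        for p in range(layout.n_planes):
            ssrb[:, :, ra[p] + rb[p]] += corrected[:, :, p]
        sino = ssrb
    else:
        sino = np.asarray(corrected, dtype=np.float64)
    kr, kv, kz = rebin
    n_rad = sino.shape[0] // kr
    n_azim = sino.shape[1] // kv
    nz = -(-sino.shape[2] // kz)
    pad_z = nz * kz - sino.shape[2]
    if pad_z:
        sino = np.concatenate([sino, np.zeros(sino.shape[:2] + (pad_z,))], axis=2)
    sino = sino[:n_rad * kr, :n_azim * kv, :]
    sino = sino.reshape(n_rad, kr, n_azim, kv, nz, kz).mean(axis=(1, 3, 5))
    bin_mm = layout.radial_bin_mm * kr
    dz = model.spec.axial_pitch / 2.0 * kz
    grid = ImageGrid(nx, nx, nz, fov_mm / nx, dz)

    nfft = int(2 ** np.ceil(np.log2(2 * n_rad)))
    ramp = np.abs(np.fft.rfftfreq(nfft))  # cycles per sample
    xs = (np.arange(grid.nx) - (grid.nx - 1) / 2.0) * grid.dx
    ys = (np.arange(grid.ny) - (grid.ny - 1) / 2.0) * grid.dx
    ang = (np.arange(n_azim) + 0.5) * np.pi / n_azim
    cos_a = np.cos(ang)
    sin_a = np.sin(ang)
    out = np.zeros(grid.shape)
    scale = np.pi / n_azim / (bin_mm * 0.1)  # line integrals are value*cm
    for p in range(nz):
        f = np.fft.irfft(np.fft.rfft(sino[:, :, p], nfft, axis=0)
                         * ramp[:, None], nfft, axis=0)[:n_rad]
        slab = np.zeros((grid.nx, grid.ny))
        _fbp_backproject(np.ascontiguousarray(f), cos_a, sin_a, xs, ys,
                         bin_mm, n_rad // 2, slab)
        out[:, :, p] = slab * scale
    np.maximum(out, 0.0, out)
    return ReconImage(out, grid, provenance=dict(method="fbp", rebin=tuple(rebin)))


# --------------------------------------------------------------------------
# post-filter
# --------------------------------------------------------------------------

def gaussian_postfilter(image: ReconImage | np.ndarray,
                        fwhm_mm=(4.0, 4.0), grid: ImageGrid | None = None):
    """Separable Gaussian smoothing, sigma = FWHM/2.3548 converted to
    voxels; sum-preserving away from the volume edge."""
    if isinstance(image, ReconImage):
        arr, grid = image.values, image.grid
    else:
        arr = image
    ft, fa = fwhm_mm
    if ft <= 0 and fa <= 0:
        out = arr.copy()
    else:
        s = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sig = (ft * s / grid.dx, ft * s / grid.dx, fa * s / grid.dz)
        out = ndimage.gaussian_filter(arr, sigma=sig, mode="constant")
    if isinstance(image, ReconImage):
        prov = dict(image.provenance)
        prov["postfilter_fwhm_mm"] = tuple(fwhm_mm)
        return ReconImage(out, grid, prov)
    return out
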