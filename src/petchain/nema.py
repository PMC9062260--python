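"""NEMA NU 2-style image-quality evaluation.

Sixty background ROIs (12 transaxial positions replicated on the central
slice and slices at +-1 cm and +-2 cm) are placed automatically in the
background compartment, at least 15 mm from the phantom edge and clear
of the spheres and lung insert; one concentric set per evaluated sphere
diameter.  Sphere ROIs are circles of the sphere's inner diameter on the
sphere's central slice.  The metrics are the scatter fraction
SF = S/(T+S), contrast recovery CRC_i = (S_i/B_i - 1)/(a_H/a_B - 1),
SNR_i = (S_i - B_i)/sigma_i with sigma_i pooled over all voxels of the
60 ROIs, background variability BV_i = SD(ROI means)/B_i, and the
residual lung error dC = C_lung / B_37 averaged over 60 slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ConfigurationError
from .phantoms import PhantomSpec
from .recon import ImageGrid, ReconImage

EDGE_MARGIN_MM = 15.0
SPHERE_PAD_MM = 2.0


class MetricError(ValueError):
    pass


# --------------------------------------------------------------------------
# scalar metric formulas
# --------------------------------------------------------------------------

def scatter_fraction(prompts: float, scatter_est: float, randoms_est: float) -> float:
    """SF = S/(T+S) in percent, with T = P - R - S."""
    trues = prompts - randoms_est - scatter_est
    denom = trues + scatter_est
    if denom <= 0:
        raise MetricError("no true-plus-scatter counts; SF undefined")
    return 100.0 * scatter_est / denom


def crc(sphere_mean: float, background_mean: float, sbr: float) -> float:
    """Contrast recovery coefficient in percent."""
    if background_mean <= 0:
        raise MetricError("background mean must be positive")
    if sbr <= 1:
        raise MetricError("sphere-to-background ratio must exceed 1")
    return 100.0 * (sphere_mean / background_mean - 1.0) / (sbr - 1.0)


def snr(sphere_mean: float, background_mean: float, sigma: float) -> float:
    if sigma <= 0:
        raise MetricError("sigma must be positive")
    return (sphere_mean - background_mean) / sigma


def background_variability(roi_means) -> float:
    """BV = SD(ROI means)/mean in percent (sample SD, N-1)."""
    m = np.asarray(roi_means, dtype=float)
    if m.size < 2:
        raise MetricError("background variability needs at least 2 ROIs")
    return 100.0 * m.std(ddof=1) / m.mean()


# --------------------------------------------------------------------------
# ROI placement
# --------------------------------------------------------------------------

@dataclass
class RoiSet:
    """Background ROI centres (12 positions x 5 slices), per-diameter
    circular masks are derived on demand."""

    centers_xy: np.ndarray      # (12, 2) mm
    slice_indices: np.ndarray   # (5,) into the image z axis
    sphere_centers: np.ndarray  # (n_spheres, 3) mm
    sphere_diameters: np.ndarray
    lung_center_xy: tuple = (0.0, 0.0)
    lung_roi_diameter: float = 30.0


def _edge_radius(theta, a, b):
    return 1.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)


def place_background_rois(spec: PhantomSpec, grid: ImageGrid,
                          n_positions: int = 12) -> RoiSet:
    """Deterministic ROI placement honouring the edge/sphere/insert
    clearances for the largest evaluated sphere diameter."""
    a, b = spec.body_half_axes
    spheres = spec.spheres()
    roi_r = max(spec.sphere_diameters) / 2.0
    if spec.kind == "nema_iq":
        base = np.array([-50.0, -30.0, -10.0, 10.0, 30.0, 50.0])
        angles = np.deg2rad(np.concatenate([base, base + 180.0]))
    else:
        angles = np.deg2rad(15.0 + 30.0 * np.arange(n_positions))
    # exact edge clearance against a densely sampled body boundary
    tb = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)
    bx = a * np.cos(tb)
    by = b * np.sin(tb)
    centers = []
    for th in angles:
        r_hi = _edge_radius(th, a, b) - EDGE_MARGIN_MM - roi_r
        placed = False
        for r in np.arange(r_hi, 0.0, -1.0):
            x = r * np.cos(th)
            y = r * np.sin(th)
            if np.min(np.hypot(bx - x, by - y)) < EDGE_MARGIN_MM + roi_r:
                continue
            ok = True
            for s in spheres:
                d = np.hypot(x - s.center[0], y - s.center[1])
                if d < s.radius + roi_r + SPHERE_PAD_MM:
                    ok = False
                    break
            if ok and spec.lung_insert:
                if np.hypot(x, y) < spec.lung_insert_radius + roi_r + SPHERE_PAD_MM:
                    ok = False
            if ok:
                centers.append((x, y))
                placed = True
                break
        if not placed:
            raise ConfigurationError("no feasible background ROI position "
                                     f"at angle {np.rad2deg(th):.0f} deg")
    if len(centers) != n_positions:
        raise ConfigurationError("background ROI placement failed")
    z = grid.slice_z
    slice_idx = [int(np.argmin(np.abs(z - off))) for off in
                 (0.0, 10.0, -10.0, 20.0, -20.0)]
    return RoiSet(np.asarray(centers), np.asarray(slice_idx),
                  np.asarray([s.center for s in spheres]),
                  np.asarray(spec.sphere_diameters))


def circle_mask(grid: ImageGrid, cx: float, cy: float, diameter: float):
    """Boolean transaxial mask of pixels whose centres fall inside the
    circle; guaranteed nonempty (falls back to the nearest pixel)."""
    xs = (np.arange(grid.nx) - (grid.nx - 1) / 2.0) * grid.dx
    ys = (np.arange(grid.ny) - (grid.ny - 1) / 2.0) * grid.dx
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    m = (X - cx) ** 2 + (Y - cy) ** 2 <= (diameter / 2.0) ** 2
    if not m.any():
        i = int(np.argmin(np.abs(xs - cx)))
        j = int(np.argmin(np.abs(ys - cy)))
        m[i, j] = True
    return m


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

@dataclass
class IqReport:
    crc_pct: dict
    snr: dict
    bv_pct: dict
    lung_error_pct: float | None
    sf_pct: float | None = None
    details: dict = field(default_factory=dict)


def evaluate_image(image: ReconImage, spec: PhantomSpec, sbr: float,
                   sf_pct: float | None = None,
                   lung_slices: int = 60) -> IqReport:
    """Compute CRC, SNR and BV for every sphere, plus the residual lung
    error when the phantom has a lung insert."""
    vol = image.values
    grid = image.grid
    rois = place_background_rois(spec, grid)
    crc_d, snr_d, bv_d = {}, {}, {}
    b37 = None
    for s, dia in zip(spec.spheres(), rois.sphere_diameters):
        iz = int(np.argmin(np.abs(grid.slice_z - s.center[2])))
        smask = circle_mask(grid, s.center[0], s.center[1], dia)
        s_mean = float(vol[:, :, iz][smask].mean())
        voxels = []
        means = []
        for (cx, cy) in rois.centers_xy:
            bmask = circle_mask(grid, cx, cy, dia)
            for jz in rois.slice_indices:
                vals = vol[:, :, jz][bmask]
                voxels.append(vals)
                means.append(float(vals.mean()))
        voxels = np.concatenate(voxels)
        b_mean = float(voxels.mean())
        sigma = float(voxels.std(ddof=1))
        key = f"{dia:g}"
        crc_d[key] = crc(s_mean, b_mean, sbr)
        snr_d[key] = snr(s_mean, b_mean, sigma)
        bv_d[key] = background_variability(means)
        if dia == max(rois.sphere_diameters):
            b37 = b_mean
    lung = None
    if spec.lung_insert:
        lung = residual_lung_error(image, spec, b37, n_slices=lung_slices)
    return IqReport(crc_pct=crc_d, snr=snr_d, bv_pct=bv_d,
                    lung_error_pct=lung, sf_pct=sf_pct,
                    details=dict(sbr=sbr, b37=b37))


def residual_lung_error(image: ReconImage, spec: PhantomSpec,
                        b_largest: float, roi_diameter: float = 30.0,
                        n_slices: int = 60) -> float:
    """dC = C_lung / B_37 in percent, averaged over the central slices."""
    if b_largest is None or b_largest <= 0:
        raise MetricError("background reference must be positive")
    grid = image.grid
    mask = circle_mask(grid, 0.0, 0.0, roi_diameter)
    order = np.argsort(np.abs(grid.slice_z))
    sel = np.sort(order[:min(n_slices, grid.nz)])
    vals = [float(image.values[:, :, iz][mask].mean()) for iz in sel]
    return 100.0 * float(np.mean(vals)) / b_largest


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------

def line_profile(image: ReconImage | np.ndarray, p0, p1, spacing: float = 1.0,
                 grid: ImageGrid | None = None):
    """Trilinear samples along the segment p0->p1 (mm).

    Returns (positions mm from p0, values, inside_mask); samples outside
    the volume are clipped to the boundary and flagged False.
    """
    if isinstance(image, ReconImage):
        vol, grid = image.values, image.grid
    else:
        vol = image
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.linalg.norm(p1 - p0)
    n = max(int(np.floor(length / spacing)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    vsz = np.array([grid.dx, grid.dx, grid.dz])
    coords = (pts - grid.origin[None, :]) / vsz[None, :] - 0.5
    upper = np.array(vol.shape) - 1.0
    inside = np.all((coords >= 0.0) & (coords <= upper[None, :]), axis=1)
    clipped = np.clip(coords, 0.0, upper[None, :])
    vals = ndimage.map_coordinates(vol, clipped.T, order=1, mode="nearest")
    return ts * length, vals, inside
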