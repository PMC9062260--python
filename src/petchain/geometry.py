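"""Scanner geometry: crystal indexing, LOR geometry and sinogram addressing.

The scanner is a 34-sector cylindrical ring of LYSO blocks modelled on the
GE Discovery MI (four axial units of 4 transaxial blocks, each block a
4 x 9 transaxial-by-axial crystal array; 19584 crystals in 36 rings of
544).  Crystal volume IDs follow the Gate ``cylindricalPET`` hierarchy
(rsector / module / submodule / crystal) and are flattened to a ring
("axial") index and an in-ring ("transaxial") index with integer
arithmetic; sinogram bins are addressed geometrically from the crystal
front-face centres.

Coordinates are right-handed with z along the bore, origin at the
isocenter and rsector 0 centred at +y (12 o'clock); the rsector number
increases clockwise when the gantry is viewed from the front (+x to the
right).  Lengths are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Inconsistent scanner or phantom configuration."""


@dataclass(frozen=True)
class ScannerSpec:
    """Multiplicities and dimensions of the cylindrical scanner.

    ``crystal_size`` is (transaxial, axial, depth) in mm.  Note the
    crystal cross-section: 3.95 mm transaxial by 5.3 mm axial is the only
    assignment compatible with 16 crystals per 34-gon face of apothem
    372.1 mm and with the 20 cm axial field of view (36 rings).
    """

    n_rsector: int = 34
    n_module_axial: int = 4
    n_module_transaxial: int = 1
    n_submodule_transaxial: int = 4
    n_submodule_axial: int = 1
    n_crystal_transaxial: int = 4
    n_crystal_axial: int = 9
    crystal_size: tuple = (3.95, 5.3, 25.0)
    face_to_face_diameter: float = 744.2
    transaxial_fov: float = 700.0
    min_sector_difference: int = 4
    bore_liner_radius: float = 350.0
    bore_liner_thickness: float = 2.0

    def __post_init__(self):
        for name in ("n_rsector", "n_module_axial", "n_module_transaxial",
                     "n_submodule_transaxial", "n_submodule_axial",
                     "n_crystal_transaxial", "n_crystal_axial"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.face_to_face_diameter <= 0 or self.transaxial_fov <= 0:
            raise ConfigurationError("scanner diameters must be positive")

    # ---- derived counts -------------------------------------------------
    @property
    def n_crystals(self) -> int:
        return (self.n_rsector * self.n_module_axial * self.n_module_transaxial
                * self.n_submodule_axial * self.n_submodule_transaxial
                * self.n_crystal_transaxial * self.n_crystal_axial)

    @property
    def n_rings(self) -> int:
        return self.n_module_axial * self.n_submodule_axial * self.n_crystal_axial

    @property
    def crystals_per_ring(self) -> int:
        return (self.n_rsector * self.n_module_transaxial
                * self.n_submodule_transaxial * self.n_crystal_transaxial)

    @property
    def crystals_per_rsector_transaxial(self) -> int:
        return (self.n_module_transaxial * self.n_submodule_transaxial
                * self.n_crystal_transaxial)

    @property
    def front_face_radius(self) -> float:
        return self.face_to_face_diameter / 2.0

    @property
    def axial_pitch(self) -> float:
        return self.crystal_size[1]

    @property
    def transaxial_pitch(self) -> float:
        return self.crystal_size[0]

    def to_yaml(self) -> str:
        d = asdict(self)
        d["crystal_size"] = list(self.crystal_size)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScannerSpec":
        d = yaml.safe_load(text)
        if "crystal_size" in d:
            d["crystal_size"] = tuple(d["crystal_size"])
        spec = cls(**d)
        face_width = spec.face_to_face_diameter * np.tan(np.pi / spec.n_rsector)
        if spec.crystals_per_rsector_transaxial * spec.transaxial_pitch > face_width + 1e-9:
            raise ConfigurationError("crystals do not fit on the rsector face")
        return spec


class CrystalAddress(NamedTuple):
    """Gate-style volume-ID tuple identifying one crystal."""

    id_rsector: int
    id_module: int
    id_submodule: int
    id_crystal: int


class CrystalIndex(NamedTuple):
    axial: int        # ring index
    transaxial: int   # in-ring index


def _check_address(addr: CrystalAddress, spec: ScannerSpec) -> None:
    n_cry = spec.n_crystal_transaxial * spec.n_crystal_axial
    if not (0 <= addr.id_rsector < spec.n_rsector):
        raise IndexError(f"rsector id {addr.id_rsector} out of range")
    if not (0 <= addr.id_module < spec.n_module_axial * spec.n_module_transaxial):
        raise IndexError(f"module id {addr.id_module} out of range")
    if not (0 <= addr.id_submodule < spec.n_submodule_transaxial * spec.n_submodule_axial):
        raise IndexError(f"submodule id {addr.id_submodule} out of range")
    if not (0 <= addr.id_crystal < n_cry):
        raise IndexError(f"crystal id {addr.id_crystal} out of range")


def axial_crystal_index(addr: CrystalAddress, spec: ScannerSpec = ScannerSpec()) -> int:
    """Ring index of a crystal from its volume-ID tuple (integer division
    throughout; the leading rsector term is identically zero for valid IDs
    but kept for fidelity with the published indexing rule)."""
    addr = CrystalAddress(*addr)
    _check_address(addr, spec)
    s = spec
    return (addr.id_rsector // s.n_rsector
            * (s.n_module_axial * s.n_submodule_axial * s.n_crystal_axial)
            + addr.id_module // s.n_module_transaxial
            * (s.n_submodule_axial * s.n_crystal_axial)
            + addr.id_submodule // s.n_submodule_transaxial * s.n_crystal_axial
            + addr.id_crystal // s.n_crystal_transaxial)


def transaxial_crystal_index(addr: CrystalAddress, spec: ScannerSpec = ScannerSpec()) -> int:
    """In-ring index of a crystal from its volume-ID tuple."""
    addr = CrystalAddress(*addr)
    _check_address(addr, spec)
    s = spec
    n_cry_smod_tax = s.n_crystal_transaxial
    n_cry_mod_tax = n_cry_smod_tax * s.n_submodule_transaxial
    n_cry_rsec_tax = n_cry_mod_tax * s.n_module_transaxial
    return (addr.id_crystal % s.n_crystal_transaxial
            + n_cry_smod_tax * (addr.id_submodule % s.n_submodule_transaxial)
            + n_cry_mod_tax * (addr.id_module % s.n_module_transaxial)
            + n_cry_rsec_tax * addr.id_rsector)


def crystal_index(addr: CrystalAddress, spec: ScannerSpec = ScannerSpec()) -> CrystalIndex:
    return CrystalIndex(axial_crystal_index(addr, spec), transaxial_crystal_index(addr, spec))


def address_from_index(index: CrystalIndex, spec: ScannerSpec = ScannerSpec()) -> CrystalAddress:
    """Inverse of :func:`crystal_index` (bijective over all crystals)."""
    ax, tax = index
    if not (0 <= ax < spec.n_rings and 0 <= tax < spec.crystals_per_ring):
        raise IndexError("crystal index out of range")
    per_rsec = spec.crystals_per_rsector_transaxial
    rsec, tax_in_rsec = divmod(tax, per_rsec)
    smod_tax, tax_in_smod = divmod(tax_in_rsec % (spec.n_submodule_transaxial
                                                  * spec.n_crystal_transaxial),
                                   spec.n_crystal_transaxial)
    mod_tax = tax_in_rsec // (spec.n_submodule_transaxial * spec.n_crystal_transaxial)
    n_ax_per_mod = spec.n_submodule_axial * spec.n_crystal_axial
    mod_ax, ax_in_mod = divmod(ax, n_ax_per_mod)
    smod_ax, ax_in_smod = divmod(ax_in_mod, spec.n_crystal_axial)
    module = mod_ax * spec.n_module_transaxial + mod_tax
    submodule = smod_ax * spec.n_submodule_transaxial + smod_tax
    crystal = ax_in_smod * spec.n_crystal_transaxial + tax_in_smod
    return CrystalAddress(rsec, module, submodule, crystal)


# --------------------------------------------------------------------------
# scanner model
# --------------------------------------------------------------------------

class ScannerModel:
    """Crystal front-face centre coordinates, panel normals and index
    tables for one :class:`ScannerSpec`."""

    def __init__(self, spec: ScannerSpec):
        self.spec = spec
        n_tax = spec.crystals_per_ring
        per_rsec = spec.crystals_per_rsector_transaxial
        tax = np.arange(n_tax)
        sector = tax // per_rsec
        in_panel = tax % per_rsec
        # rsector 0 at +y, increasing clockwise viewed from the front
        theta = np.pi / 2.0 - sector * (2.0 * np.pi / spec.n_rsector)
        ur = np.stack([np.cos(theta), np.sin(theta)], axis=1)     # outward radial
        tan = np.stack([np.sin(theta), -np.cos(theta)], axis=1)   # clockwise tangential
        offset = (in_panel - (per_rsec - 1) / 2.0) * spec.transaxial_pitch
        xy = ur * spec.front_face_radius + tan * offset[:, None]
        self.sector_of_tax = sector
        self.x_tax = xy[:, 0].copy()
        self.y_tax = xy[:, 1].copy()
        self.panel_theta = np.pi / 2.0 - np.arange(spec.n_rsector) * (2.0 * np.pi / spec.n_rsector)
        rings = np.arange(spec.n_rings)
        self.z_ring = (rings - (spec.n_rings - 1) / 2.0) * spec.axial_pitch

    @property
    def n_crystals(self) -> int:
        return self.spec.n_crystals

    @property
    def axial_extent(self) -> float:
        """Axial field of view (mm), crystal pitch times number of rings."""
        return self.spec.n_rings * self.spec.axial_pitch

    def crystal_centers(self) -> np.ndarray:
        """(n_crystals, 3) front-face centres, flat index = ring*544 + tax."""
        spec = self.spec
        n_tax = spec.crystals_per_ring
        out = np.empty((spec.n_rings * n_tax, 3))
        out[:, 0] = np.tile(self.x_tax, spec.n_rings)
        out[:, 1] = np.tile(self.y_tax, spec.n_rings)
        out[:, 2] = np.repeat(self.z_ring, n_tax)
        return out

    def panel_normals(self) -> np.ndarray:
        """(n_rsector, 2) inward unit normals of the detector panels."""
        return -np.stack([np.cos(self.panel_theta), np.sin(self.panel_theta)], axis=1)


def build_scanner(spec: ScannerSpec = ScannerSpec()) -> ScannerModel:
    return ScannerModel(spec)


# --------------------------------------------------------------------------
# sinogram layout & binning
# --------------------------------------------------------------------------

AXIAL_SPAN1 = "span1"
AXIAL_SSRB = "ssrb"


@dataclass(frozen=True)
class SinogramLayout:
    """Addressing of the (radial, azimuthal, plane[, TOF]) histogram.

    ``span1`` keeps the full Michelogram (one plane per ordered ring
    pair); ``ssrb`` performs single-slice rebinning, assigning each LOR
    to the plane at its mean ring coordinate (2*n_rings - 1 planes).
    The radial coordinate is the LOR's signed closest-approach distance
    to the axis, binned at half the crystal pitch (interleaved sampling);
    the azimuthal coordinate is the LOR direction modulo pi in
    ``crystals_per_ring / 2`` views.
    """

    n_radial: int = 355
    n_azimuthal: int = 272
    radial_bin_mm: float = 3.95 / 2.0
    radial_extent: float = 350.0
    axial_mode: str = AXIAL_SPAN1
    n_rings: int = 36
    max_ring_diff: int | None = None
    tof_bins: int = 1
    tof_bin_ps: float = 169.0
    version: str = "petchain-sino-1"

    def __post_init__(self):
        if self.axial_mode not in (AXIAL_SPAN1, AXIAL_SSRB):
            raise ConfigurationError(f"unknown axial mode {self.axial_mode!r}")
        if self.n_radial % 2 == 0:
            raise ConfigurationError("n_radial must be odd (centred bin)")
        if self.tof_bins % 2 == 0:
            raise ConfigurationError("tof_bins must be odd (centred bin)")

    @property
    def n_planes(self) -> int:
        if self.axial_mode == AXIAL_SPAN1:
            return self.n_rings * self.n_rings
        return 2 * self.n_rings - 1

    @property
    def shape(self) -> tuple:
        if self.tof_bins > 1:
            return (self.n_radial, self.n_azimuthal, self.n_planes, self.tof_bins)
        return (self.n_radial, self.n_azimuthal, self.n_planes)

    def plane_z(self, model: ScannerModel) -> np.ndarray:
        """Axial coordinate (mm) of each plane's representative LOR."""
        if self.axial_mode == AXIAL_SSRB:
            p = np.arange(self.n_planes)
            return (p - (self.n_planes - 1) / 2.0) * self.axial_mode_pitch(model)
        ra, rb = np.divmod(np.arange(self.n_planes), self.n_rings)
        return 0.5 * (model.z_ring[ra] + model.z_ring[rb])

    def axial_mode_pitch(self, model: ScannerModel) -> float:
        return model.spec.axial_pitch / 2.0


def default_layout(**kw) -> SinogramLayout:
    return SinogramLayout(**kw)


def desk_layout(mash: int = 2, max_ring_diff: int = 9, **kw) -> SinogramLayout:
    """SSRB layout with azimuthally mashed views, used by the end-to-end
    pipelines to keep reconstruction at desk scale."""
    return SinogramLayout(n_azimuthal=272 // mash, axial_mode=AXIAL_SSRB,
                          max_ring_diff=max_ring_diff, **kw)


def bin_lors(model: ScannerModel, layout: SinogramLayout,
             ax1, tax1, ax2, tax2, dt_ps=None):
    """Map crystal-index pairs to sinogram bins.

    Returns ``(accepted_mask, radial, azimuthal, plane, tof)`` where the
    bin arrays are only meaningful where ``accepted_mask`` is True.  A
    pair is rejected when the transaxial rsector separation is below the
    scanner minimum, when the LOR's closest approach to the axis exceeds
    the radial extent, or (ssrb) when the ring difference exceeds the
    layout's maximum.  Swapping the two crystals yields the same bin and
    negates the TOF offset.
    """
    spec = model.spec
    ax1 = np.asarray(ax1, dtype=np.int64)
    tax1 = np.asarray(tax1, dtype=np.int64)
    ax2 = np.asarray(ax2, dtype=np.int64)
    tax2 = np.asarray(tax2, dtype=np.int64)
    # canonical pair order makes the binning exactly swap-symmetric even
    # for LORs that fall on a bin boundary
    swap = (tax2 < tax1) | ((tax2 == tax1) & (ax2 < ax1))
    ax1, ax2 = np.where(swap, ax2, ax1), np.where(swap, ax1, ax2)
    tax1, tax2 = np.where(swap, tax2, tax1), np.where(swap, tax1, tax2)
    if dt_ps is not None:
        dt_ps = np.where(swap, -np.asarray(dt_ps), dt_ps)
    s1 = model.sector_of_tax[tax1]
    s2 = model.sector_of_tax[tax2]
    d = (s1 - s2) % spec.n_rsector
    sector_ok = np.minimum(d, spec.n_rsector - d) >= spec.min_sector_difference

    x1 = model.x_tax[tax1]
    y1 = model.y_tax[tax1]
    x2 = model.x_tax[tax2]
    y2 = model.y_tax[tax2]
    alpha = np.mod(np.arctan2(y2 - y1, x2 - x1), np.pi)
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    s = x1 * sa - y1 * ca
    radial_ok = np.abs(s) <= layout.radial_extent

    radial = np.rint(s / layout.radial_bin_mm).astype(np.int64) + layout.n_radial // 2
    azim = np.minimum((alpha / np.pi * layout.n_azimuthal).astype(np.int64),
                      layout.n_azimuthal - 1)

    t1 = x1 * ca + y1 * sa
    t2 = x2 * ca + y2 * sa
    first_is_1 = t1 <= t2
    ring_a = np.where(first_is_1, ax1, ax2)
    ring_b = np.where(first_is_1, ax2, ax1)
    ok = sector_ok & radial_ok
    if layout.axial_mode == AXIAL_SPAN1:
        plane = ring_a * layout.n_rings + ring_b
    else:
        plane = ring_a + ring_b
    if layout.max_ring_diff is not None:
        ok &= np.abs(ring_a - ring_b) <= layout.max_ring_diff

    if layout.tof_bins > 1 and dt_ps is not None:
        dtc = np.where(first_is_1, dt_ps, -np.asarray(dt_ps))
        tof = np.rint(dtc / layout.tof_bin_ps).astype(np.int64) + layout.tof_bins // 2
        tof = np.clip(tof, 0, layout.tof_bins - 1)
    else:
        tof = np.zeros_like(plane)
    return ok, radial, azim, plane, tof


def histogram_events(model: ScannerModel, layout: SinogramLayout,
                     ax1, tax1, ax2, tax2, dt_ps=None,
                     chunk: int = 5_000_000) -> np.ndarray:
    """Histogram an event list into a prompt sinogram (float32).

    The sum over the result equals the number of accepted events; long
    lists are processed in bounded-memory chunks.
    """
    sino = np.zeros(layout.shape, dtype=np.float32)
    n = len(np.asarray(ax1))
    flat_view = sino.reshape(-1)
    for lo in range(0, max(n, 1), chunk):
        hi = min(lo + chunk, n)
        if hi <= lo:
            break
        dt = None if dt_ps is None else np.asarray(dt_ps)[lo:hi]
        ok, r, v, p, t = bin_lors(model, layout, np.asarray(ax1)[lo:hi],
                                  np.asarray(tax1)[lo:hi],
                                  np.asarray(ax2)[lo:hi],
                                  np.asarray(tax2)[lo:hi], dt)
        if layout.tof_bins > 1:
            flat = (((r[ok] * layout.n_azimuthal + v[ok]) * layout.n_planes
                     + p[ok]) * layout.tof_bins + t[ok])
        else:
            flat = (r[ok] * layout.n_azimuthal + v[ok]) * layout.n_planes + p[ok]
        np.add.at(flat_view, flat, 1.0)
    return sino


def bin_endpoints(model: ScannerModel, layout: SinogramLayout,
                  radial, azim, plane):
    """Representative LOR endpoints (mm) for sinogram bins.

    Endpoints lie on the front-face cylinder at the bin-centre radial
    offset and azimuth; for ssrb layouts the LOR is placed in-plane at
    the plane's axial coordinate.
    """
    radial = np.asarray(radial)
    azim = np.asarray(azim)
    plane = np.asarray(plane)
    alpha = (azim + 0.5) * np.pi / layout.n_azimuthal
    s = (radial - layout.n_radial // 2) * layout.radial_bin_mm
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    R = model.spec.front_face_radius
    half = np.sqrt(np.maximum(R * R - s * s, 0.0))
    x0 = s * sa
    y0 = -s * ca
    p1 = np.stack([x0 - half * ca, y0 - half * sa], axis=-1)
    p2 = np.stack([x0 + half * ca, y0 + half * sa], axis=-1)
    if layout.axial_mode == AXIAL_SSRB:
        z = (plane - (layout.n_planes - 1) / 2.0) * (model.spec.axial_pitch / 2.0)
        z1 = z2 = z
    else:
        ra, rb = np.divmod(plane, layout.n_rings)
        z1 = model.z_ring[ra]
        z2 = model.z_ring[rb]
    e1 = np.concatenate([p1, np.asarray(z1)[..., None]], axis=-1)
    e2 = np.concatenate([p2, np.asarray(z2)[..., None]], axis=-1)
    return e1, e2


def all_bin_endpoints(model: ScannerModel, layout: SinogramLayout):
    """Endpoints for every bin of a (non-TOF) layout, flattened in C order
    of (radial, azimuthal, plane)."""
    r, v, p = np.meshgrid(np.arange(layout.n_radial), np.arange(layout.n_azimuthal),
                          np.arange(layout.n_planes), indexing="ij")
    return bin_endpoints(model, layout, r.ravel(), v.ravel(), p.ravel())
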