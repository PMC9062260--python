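"""Phantom construction: analytic solids, voxelised activity/attenuation maps.

Three families are provided: a uniform water cylinder (calibration and
digitizer tuning), the NEMA IQ body phantom (six hot spheres of 37-10 mm
inner diameter on a 114.4 mm circle around a low-density cylindrical lung
insert, in a ~9.7 L elliptical body), and the Data Spectrum cylinder with
six small spheres (15.43-3.95 mm).  Activity concentrations are kBq/mL,
attenuation is cm^-1 at 511 keV.  Normalisation sources (a central
cylinder and an annulus just outside the transaxial FOV) are built as
non-attenuating emitters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physics
from .geometry import ConfigurationError

NEMA_SPHERE_DIAMETERS = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)
DS_SPHERE_DIAMETERS = (15.43, 12.43, 9.89, 6.23, 4.95, 3.95)

MATERIALS = {
    "air": 0.0,
    "water": float(physics.WATER.mu(511.0)),
    "lung_insert": 0.004,
    "pmma": float(physics.PMMA.mu(511.0)),
    "couch": 0.05,  # effective carbon-fibre sandwich at 511 keV
}
MATERIAL_NAMES = ("air", "water", "lung_insert", "pmma", "couch")


@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float
    concentration: float  # kBq/mL

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2

    @property
    def volume_ml(self):
        return 4.0 / 3.0 * np.pi * self.radius**3 / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of one phantom set-up.

    ``kind`` selects the family; ``body_half_axes`` are the transaxial
    semi-axes in mm (equal for circular bodies), ``sphere_radius_mm`` is
    the radius of the circle the sphere centres sit on.
    """

    kind: str = "uniform_cylinder"
    body_half_axes: tuple = (95.0, 95.0)
    body_length: float = 200.0
    background_concentration: float = 0.0  # kBq/mL
    sphere_diameters: tuple = ()
    sphere_concentration: float = 0.0
    sphere_ring_radius: float = 57.2
    lung_insert: bool = False
    lung_insert_radius: float = 25.0
    lung_insert_mu: float = 0.004
    wall_thickness: float = 3.0  # acrylic shell of the physical phantom, mm
    sphere_wall_mm: float = 1.0  # cold glass/acrylic shell of each sphere
    couch: bool = True           # carbon-fibre couch slab under the phantom
    couch_thickness: float = 8.0
    couch_width: float = 360.0
    attenuating: bool = True

    # ---- constructors ---------------------------------------------------
    @classmethod
    def uniform_cylinder(cls, radius=95.0, length=200.0, concentration=4.4):
        return cls(kind="uniform_cylinder", body_half_axes=(radius, radius),
                   body_length=length, background_concentration=concentration)

    @classmethod
    def nema_iq(cls, sphere_concentration=32.6, background_concentration=3.7,
                lung_insert_mu=0.004):
        return cls(kind="nema_iq", body_half_axes=(150.0, 115.0), body_length=194.0,
                   background_concentration=background_concentration,
                   sphere_diameters=NEMA_SPHERE_DIAMETERS,
                   sphere_concentration=sphere_concentration,
                   sphere_ring_radius=57.2, lung_insert=True,
                   lung_insert_mu=lung_insert_mu)

    @classmethod
    def ds_cylinder(cls, sphere_concentration=20.7, background_concentration=2.6):
        return cls(kind="ds_cylinder", body_half_axes=(110.0, 110.0), body_length=176.0,
                   background_concentration=background_concentration,
                   sphere_diameters=DS_SPHERE_DIAMETERS,
                   sphere_concentration=sphere_concentration,
                   sphere_ring_radius=50.0)

    @classmethod
    def norm_cylinder(cls, radius=100.0, length=190.8, concentration=1.0):
        return cls(kind="norm_cylinder", body_half_axes=(radius, radius),
                   body_length=length, background_concentration=concentration,
                   couch=False, attenuating=False)

    @classmethod
    def norm_annulus(cls, radius=355.0, thickness=1.0, length=190.8, concentration=1.0):
        return cls(kind="norm_annulus", body_half_axes=(radius, radius),
                   body_length=length, background_concentration=concentration,
                   lung_insert_radius=radius - thickness, couch=False,
                   attenuating=False)

    # ---- derived geometry ----------------------------------------------
    def spheres(self):
        out = []
        for k, d in enumerate(self.sphere_diameters):
            ang = np.deg2rad(90.0 - 60.0 * k)
            c = (self.sphere_ring_radius * np.cos(ang),
                 self.sphere_ring_radius * np.sin(ang), 0.0)
            out.append(Sphere(c, d / 2.0, self.sphere_concentration))
        return out

    def validate(self):
        a, b = self.body_half_axes
        sph = self.spheres()
        for s in sph:
            cx, cy, _ = s.center
            rho = np.hypot(cx / a, cy / b)
            if rho + s.radius / min(a, b) > 1.0:
                raise ConfigurationError(f"sphere at {s.center} extends outside the body")
            if self.lung_insert and np.hypot(cx, cy) < self.lung_insert_radius + s.radius:
                raise ConfigurationError("sphere overlaps the lung insert")
        for i in range(len(sph)):
            for j in range(i + 1, len(sph)):
                d = np.linalg.norm(np.subtract(sph[i].center, sph[j].center))
                if d < sph[i].radius + sph[j].radius:
                    raise ConfigurationError("spheres overlap")

    def in_body(self, x, y, z):
        a, b = self.body_half_axes
        inside = ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (np.abs(z) <= self.body_length / 2.0)
        if self.kind == "norm_annulus":
            inner = self.lung_insert_radius
            inside &= (x**2 + y**2) >= inner**2
        return inside

    def in_insert(self, x, y, z):
        if not self.lung_insert:
            return np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        return (x**2 + y**2 <= self.lung_insert_radius**2) & (np.abs(z) <= self.body_length / 2.0)

    @property
    def body_volume_ml(self):
        a, b = self.body_half_axes
        v = np.pi * a * b * self.body_length
        if self.kind == "norm_annulus":
            v -= np.pi * self.lung_insert_radius**2 * self.body_length
        return v / 1000.0

    @property
    def background_volume_ml(self):
        w = self.sphere_wall_mm
        outer = sum(4.0 / 3.0 * np.pi * (s.radius + w) ** 3 / 1000.0
                    for s in self.spheres())
        v = self.body_volume_ml - outer
        if self.lung_insert:
            v -= np.pi * self.lung_insert_radius**2 * self.body_length / 1000.0
        return v

    @property
    def total_activity_kbq(self):
        act = self.background_concentration * self.background_volume_ml
        act += sum(s.concentration * s.volume_ml for s in self.spheres())
        return act


@dataclass
class VoxelPhantom:
    """Congruent voxel grids of activity (kBq/mL), material label and
    linear attenuation at 511 keV (cm^-1).  ``origin`` is the corner of
    voxel (0,0,0) in mm; voxels are cubes of ``voxel_size`` mm."""

    activity: np.ndarray
    material: np.ndarray
    mu_511: np.ndarray
    voxel_size: float
    origin: np.ndarray
    material_names: tuple = MATERIAL_NAMES

    def __post_init__(self):
        if not (self.activity.shape == self.material.shape == self.mu_511.shape):
            raise ConfigurationError("phantom grids must be congruent")
        if np.any(self.activity < 0) or np.any(self.mu_511 < 0):
            raise ConfigurationError("activity and attenuation must be nonnegative")

    @property
    def shape(self):
        return self.activity.shape

    def voxel_centers(self):
        xs = self.origin[0] + (np.arange(self.shape[0]) + 0.5) * self.voxel_size
        ys = self.origin[1] + (np.arange(self.shape[1]) + 0.5) * self.voxel_size
        zs = self.origin[2] + (np.arange(self.shape[2]) + 0.5) * self.voxel_size
        return xs, ys, zs

    @property
    def total_activity_kbq(self):
        return float(self.activity.sum() * self.voxel_size**3 / 1000.0)

    def mu_at_energy(self, e_kev):
        """mu(E) grid via the water energy-scaling of Compton-dominated
        materials (all phantom materials are light; LYSO is elsewhere)."""
        ratio = float(physics.WATER.mu(e_kev) / physics.WATER.mu(511.0))
        return self.mu_511 * ratio


def build_phantom(spec: PhantomSpec, voxel_size: float = 2.0,
                  margin: float = 8.0) -> VoxelPhantom:
    """Rasterise a phantom spec on a cubic-voxel grid by centre sampling."""
    spec.validate()
    a, b = spec.body_half_axes
    use_couch = spec.couch and spec.attenuating
    xhalf = max(a + margin, spec.couch_width / 2.0 + 2.0 if use_couch else 0.0)
    yextra = spec.couch_thickness + 4.0 if use_couch else 0.0
    half = np.array([xhalf, b + margin + yextra, spec.body_length / 2.0 + margin])
    n = np.ceil(2.0 * half / voxel_size).astype(int)
    origin = -n * voxel_size / 2.0
    xs = origin[0] + (np.arange(n[0]) + 0.5) * voxel_size
    ys = origin[1] + (np.arange(n[1]) + 0.5) * voxel_size
    zs = origin[2] + (np.arange(n[2]) + 0.5) * voxel_size
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    body = spec.in_body(X, Y, Z)
    activity = np.zeros(tuple(n), dtype=np.float32)
    material = np.zeros(tuple(n), dtype=np.uint8)  # air
    activity[body] = spec.background_concentration
    if spec.attenuating:
        if spec.wall_thickness > 0:
            tw = spec.wall_thickness
            shell = (((X / (a + tw)) ** 2 + (Y / (b + tw)) ** 2 <= 1.0)
                     & (np.abs(Z) <= spec.body_length / 2.0 + tw) & ~body)
            material[shell] = MATERIAL_NAMES.index("pmma")
        material[body] = MATERIAL_NAMES.index("water")
        if use_couch:
            top = -(b + spec.wall_thickness)
            slab = ((np.abs(X) <= spec.couch_width / 2.0)
                    & (Y <= top) & (Y >= top - spec.couch_thickness)
                    & (material == 0))
            material[slab] = MATERIAL_NAMES.index("couch")

    if spec.lung_insert:
        ins = spec.in_insert(X, Y, Z)
        activity[ins] = 0.0
        material[ins] = MATERIAL_NAMES.index("lung_insert")

    for s in spec.spheres():
        if spec.sphere_wall_mm > 0:
            shell = Sphere(s.center, s.radius + spec.sphere_wall_mm, 0.0)
            m = shell.contains(X, Y, Z)
            activity[m] = 0.0
            if spec.attenuating:
                material[m] = MATERIAL_NAMES.index("pmma")
        m = s.contains(X, Y, Z)
        activity[m] = s.concentration
        if spec.attenuating:
            material[m] = MATERIAL_NAMES.index("water")

    mu_lookup = np.array([MATERIALS[name] for name in MATERIAL_NAMES], dtype=np.float32)
    mu_lookup[MATERIAL_NAMES.index("lung_insert")] = spec.lung_insert_mu
    mu = mu_lookup[material]
    return VoxelPhantom(activity, material, mu, voxel_size, origin.astype(float))


class AnalyticSource:
    """Exact decay-position sampler for a :class:`PhantomSpec`.

    Components (spheres / background) are chosen with probability
    proportional to their total activity; positions are uniform within
    the chosen solid, with rejection of sphere/insert interiors for the
    background compartment.
    """

    def __init__(self, spec: PhantomSpec):
        spec.validate()
        self.spec = spec
        self.spheres = spec.spheres()
        acts = [s.concentration * s.volume_ml for s in self.spheres]
        acts.append(spec.background_concentration * spec.background_volume_ml)
        acts = np.asarray(acts, dtype=float)
        if acts.sum() <= 0:
            self._cdf = None
        else:
            self._cdf = np.cumsum(acts) / acts.sum()
        self.total_activity_kbq = float(acts.sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, 3) decay positions in mm."""
        if n == 0 or self._cdf is None:
            return np.empty((0, 3))
        comp = np.searchsorted(self._cdf, rng.random(n))
        out = np.empty((n, 3))
        for k, s in enumerate(self.spheres):
            m = comp == k
            cnt = int(m.sum())
            if cnt:
                out[m] = _sample_sphere(rng, s, cnt)
        m = comp == len(self.spheres)
        cnt = int(m.sum())
        if cnt:
            out[m] = self._sample_background(rng, cnt)
        return out

    def _sample_background(self, rng, n):
        spec = self.spec
        a, b = spec.body_half_axes
        if spec.kind == "norm_annulus":
            # thin shell: draw the radius directly instead of rejecting
            r_in = spec.lung_insert_radius
            r = np.sqrt(rng.uniform(r_in**2, a**2, n))
            phi = rng.uniform(0.0, 2.0 * np.pi, n)
            z = rng.uniform(-spec.body_length / 2.0, spec.body_length / 2.0, n)
            return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        out = np.empty((n, 3))
        got = 0
        while got < n:
            m = int((n - got) * 1.6) + 16
            u = rng.random((m, 2))
            r = np.sqrt(u[:, 0])
            phi = 2.0 * np.pi * u[:, 1]
            x = a * r * np.cos(phi)
            y = b * r * np.sin(phi)
            z = rng.uniform(-spec.body_length / 2.0, spec.body_length / 2.0, m)
            keep = np.ones(m, dtype=bool)
            if spec.kind == "norm_annulus":
                keep &= x**2 + y**2 >= spec.lung_insert_radius**2
            if spec.lung_insert:
                keep &= x**2 + y**2 > spec.lung_insert_radius**2
            if self.spheres:
                # spheres sit in the z=0 plane; only test the slab they
                # occupy (including the cold wall shells)
                w = spec.sphere_wall_mm
                zmax = max(s.radius for s in self.spheres) + w
                band = np.abs(z) <= zmax
                for s in self.spheres:
                    shell = Sphere(s.center, s.radius + w, 0.0)
                    inside = np.zeros(m, dtype=bool)
                    inside[band] = shell.contains(x[band], y[band], z[band])
                    keep &= ~inside
            x, y, z = x[keep], y[keep], z[keep]
            take = min(x.size, n - got)
            out[got:got + take, 0] = x[:take]
            out[got:got + take, 1] = y[:take]
            out[got:got + take, 2] = z[:take]
            got += take
        return out


def _sample_sphere(rng, sphere: Sphere, n):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = sphere.radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(sphere.center) + v * r[:, None]


class VoxelSource:
    """Decay-position sampler drawing from a voxelised activity grid
    (positions uniform within the selected voxel)."""

    def __init__(self, phantom: VoxelPhantom):
        w = phantom.activity.reshape(-1).astype(np.float64)
        tot = w.sum()
        self.phantom = phantom
        self._cdf = np.cumsum(w) / tot if tot > 0 else None
        self.total_activity_kbq = phantom.total_activity_kbq

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0 or self._cdf is None:
            return np.empty((0, 3))
        flat = np.searchsorted(self._cdf, rng.random(n))
        idx = np.stack(np.unravel_index(flat, self.phantom.shape), axis=1)
        jitter = rng.random((n, 3))
        return self.phantom.origin + (idx + jitter) * self.phantom.voxel_size
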