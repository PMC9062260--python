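"""Monte Carlo acquisition simulator.

Stand-in for a full Geant4-based simulation: annihilation-photon pairs are
transported through the voxelised phantom with Woodcock delta-tracking
(Compton scattering sampled from Klein-Nishina, a small photoelectric
branch), detected on the 34-panel crystal ring, and pushed through a
digitizer chain replicating the front-end electronics: per-event adder and
rsector-level energy-winner readout, Gaussian energy blur (9.63% FWHM at
511 keV, scaling with 1/sqrt(E)), detection efficiency, Gaussian temporal
blur, energy discriminator, and a multi-window coincidence sorter with a
takeAllGoods multiples policy and a minimum sector difference.  A Poisson
noise source emulates the intrinsic 176Lu activity of the LYSO crystals.

Energy deposits are the full photon energy at the first crystal
interaction; deadtime and pile-up are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from . import physics
from .geometry import ScannerModel, ScannerSpec, build_scanner
from .phantoms import AnalyticSource, PhantomSpec, VoxelPhantom, VoxelSource

TAU_PS = 2450.0          # single-photon window tau (2.45 ns) in ps
E_KILL_KEV = 250.0       # photons below this can never reach the 425 keV window

LABEL_TRUE = 0
LABEL_SCATTER = 1
LABEL_RANDOM = 2


@dataclass(frozen=True)
class DigitizerConfig:
    energy_resolution_fwhm: float = 0.0963   # fractional FWHM at 511 keV
    energy_window: tuple = (425.0, 650.0)    # keV
    temporal_fwhm_ps: float = 268.7
    detection_efficiency: float = 0.98
    lu176_rate_khz: float = 1142.0
    coincidence_window_2tau_ns: float = 4.9
    min_sector_difference: int = 4
    acollinearity_fwhm_deg: float = 0.0      # optional; off by default

    def __post_init__(self):
        lo, hi = self.energy_window
        if lo >= hi:
            raise ValueError("energy window lower bound must be below upper")
        if min(self.energy_resolution_fwhm, self.temporal_fwhm_ps,
               self.detection_efficiency, self.lu176_rate_khz) < 0:
            raise ValueError("rates and resolutions must be nonnegative")

    @property
    def tau_ps(self) -> float:
        return self.coincidence_window_2tau_ns * 1000.0 / 2.0


# --------------------------------------------------------------------------
# decay sampling
# --------------------------------------------------------------------------

def expected_decays(total_activity_kbq, duration_s, decimation=1.0,
                    frame_offset_min=0.0):
    """Poisson mean of positron decays in a frame, including the beta+
    yield and optional physical-decay correction to the frame start."""
    rate = total_activity_kbq * 1e3 * physics.F18_POSITRON_YIELD * decimation
    rate *= 2.0 ** (-frame_offset_min / physics.F18_HALF_LIFE_MIN)
    return rate * duration_s


def sample_annihilations(source, duration_s, rng, decimation=1.0,
                         frame_offset_min=0.0, max_batch=None):
    """Sample decay positions and times for one frame.

    ``source`` is an :class:`AnalyticSource` or :class:`VoxelSource` (a
    :class:`VoxelPhantom` is wrapped automatically).  Returns
    ``(positions mm, times ps)``; an inactive source yields empty arrays.
    """
    if isinstance(source, VoxelPhantom):
        source = VoxelSource(source)
    mean = expected_decays(source.total_activity_kbq, duration_s, decimation,
                           frame_offset_min)
    n = int(rng.poisson(mean))
    if max_batch is not None:
        n = min(n, max_batch)
    pos = source.sample(rng, n)
    times = rng.uniform(0.0, duration_s * 1e12, n)
    return pos, times


# --------------------------------------------------------------------------
# photon transport (Woodcock delta-tracking + Klein-Nishina)
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _transport_batch(pos, t_emit, mu, ox, oy, oz, vox, mumax511,
                     ratio_tab, pe_tab, lyso_tab, r_det, axial_half,
                     ring_pitch, n_rings, n_sec, panel_cos, panel_sin,
                     pitch_t, per_rsec,
                     depth_cm, acol_sigma, liner_r, liner_thick, liner_mu511,
                     seed,
                     out_decay, out_ring, out_tax, out_e, out_t, out_scat):
    np.random.seed(seed)
    n = pos.shape[0]
    nx, ny, nz = mu.shape
    cnt = 0
    step = 2.0 * np.pi / n_sec
    c_inv = 1.0 / physics.C_MM_PER_PS
    for i in range(n):
        # isotropic first photon
        czen = 1.0 - 2.0 * np.random.random()
        szen = np.sqrt(max(0.0, 1.0 - czen * czen))
        phi = 2.0 * np.pi * np.random.random()
        ux0 = szen * np.cos(phi)
        uy0 = szen * np.sin(phi)
        uz0 = czen
        for ph in range(2):
            ux, uy, uz = ux0, uy0, uz0
            if ph == 1:
                ux, uy, uz = -ux, -uy, -uz
                if acol_sigma > 0.0:
                    dth = np.random.normal() * acol_sigma
                    dph = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, np.cos(dth), dph)
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            e = 511.0
            nscat = 0
            path = 0.0
            absorbed = False
            if mumax511 > 0.0:
                it = 0
                while it < 10000:
                    it += 1
                    idx_e = int(e) - 50
                    if idx_e < 0:
                        idx_e = 0
                    elif idx_e > 650:
                        idx_e = 650
                    mumaj = mumax511 * ratio_tab[idx_e]
                    l_mm = -np.log(np.random.random()) / mumaj * 10.0
                    x += ux * l_mm
                    y += uy * l_mm
                    z += uz * l_mm
                    path += l_mm
                    ix = int(np.floor((x - ox) / vox))
                    iy = int(np.floor((y - oy) / vox))
                    iz = int(np.floor((z - oz) / vox))
                    if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                        # left the phantom volume: rewind the overshoot so the
                        # ballistic flight to the detector starts on the ray
                        # inside the bore
                        x -= ux * l_mm
                        y -= uy * l_mm
                        z -= uz * l_mm
                        path -= l_mm
                        break
                    mloc = mu[ix, iy, iz] * ratio_tab[idx_e]
                    if np.random.random() * mumaj < mloc:
                        if np.random.random() < pe_tab[idx_e]:
                            absorbed = True
                            break
                        # Compton: Klein-Nishina rejection sampling
                        alpha = e / 511.0
                        c = 1.0
                        while True:
                            c = 1.0 - 2.0 * np.random.random()
                            r = 1.0 / (1.0 + alpha * (1.0 - c))
                            val = 0.5 * r * r * (r + 1.0 / r - (1.0 - c * c))
                            if np.random.random() <= val:
                                break
                        e = e * (1.0 / (1.0 + alpha * (1.0 - c)))
                        nscat += 1
                        dph = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, c, dph)
                        if e < E_KILL_KEV:
                            absorbed = True
                            break
            if absorbed:
                continue
            # single-Compton interaction in the plastic bore liner,
            # treated as an analytic thin shell outside the phantom grid
            if liner_mu511 > 0.0:
                a2 = ux * ux + uy * uy
                if a2 > 1e-12:
                    b2 = x * ux + y * uy
                    c_in = x * x + y * y - liner_r * liner_r
                    disc_in = b2 * b2 - a2 * c_in
                    if disc_in > 0.0 and c_in < 0.0:
                        t_in = (-b2 + np.sqrt(disc_in)) / a2
                        r_out = liner_r + liner_thick
                        c_out = x * x + y * y - r_out * r_out
                        t_out = (-b2 + np.sqrt(b2 * b2 - a2 * c_out)) / a2
                        idx_e = min(max(int(e) - 50, 0), 650)
                        chord_cm = (t_out - t_in) / 10.0
                        p_sc = 1.0 - np.exp(-liner_mu511 * ratio_tab[idx_e] * chord_cm)
                        if np.random.random() < p_sc:
                            frac = np.random.random()
                            t_s = t_in + frac * (t_out - t_in)
                            x += ux * t_s
                            y += uy * t_s
                            z += uz * t_s
                            path += t_s
                            alpha = e / 511.0
                            c = 1.0
                            while True:
                                c = 1.0 - 2.0 * np.random.random()
                                r = 1.0 / (1.0 + alpha * (1.0 - c))
                                val = 0.5 * r * r * (r + 1.0 / r - (1.0 - c * c))
                                if np.random.random() <= val:
                                    break
                            e = e / (1.0 + alpha * (1.0 - c))
                            nscat += 1
                            dph = 2.0 * np.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, c, dph)
                            if e < E_KILL_KEV:
                                continue
            # fly to the detector ring: approximate hit angle on the
            # front-face cylinder, then exact intersection with up to
            # three candidate flat panels
            a = ux * ux + uy * uy
            if a < 1e-12:
                continue
            b = x * ux + y * uy
            cq = x * x + y * y - r_det * r_det
            disc = b * b - a * cq
            if disc <= 0.0:
                continue
            t_cyl = (-b + np.sqrt(disc)) / a
            if t_cyl <= 0.0:
                continue
            hx = x + ux * t_cyl
            hy = y + uy * t_cyl
            th = np.arctan2(hy, hx)
            k0 = int(np.round((np.pi / 2.0 - th) / step))
            best_t = 1e30
            best_p = -1
            best_ring = -1
            best_sec = -1
            best_cos = 1.0
            for dk in range(-1, 2):
                k = (k0 + dk) % n_sec
                ukx = panel_cos[k]
                uky = panel_sin[k]
                denom = ux * ukx + uy * uky
                if denom <= 1e-9:
                    continue
                t_p = (r_det - (x * ukx + y * uky)) / denom
                if t_p <= 0.0 or t_p >= best_t:
                    continue
                px = x + ux * t_p
                py = y + uy * t_p
                # tangential offset on the panel (clockwise positive)
                off = px * uky - py * ukx
                pidx = int(np.floor(off / pitch_t + per_rsec / 2.0))
                if pidx < 0 or pidx >= per_rsec:
                    continue
                pz = z + uz * t_p
                ridx = int(np.floor((pz + axial_half) / ring_pitch))
                if ridx < 0 or ridx >= n_rings:
                    continue
                best_t = t_p
                best_p = pidx
                best_ring = ridx
                best_sec = k
                best_cos = denom
            if best_p < 0:
                continue
            idx_e = int(e) - 50
            if idx_e < 0:
                idx_e = 0
            elif idx_e > 650:
                idx_e = 650
            path_c = depth_cm / max(best_cos, 1.0 / 3.0)
            mu_d = lyso_tab[idx_e]
            p_int = 1.0 - np.exp(-mu_d * path_c)
            if np.random.random() >= p_int:
                continue
            # mean interaction depth refines the timestamp only; the
            # crystal stays the one whose face the ray crossed
            # (depth-of-interaction encoding is out of scope)
            d_mm = -np.log(1.0 - np.random.random() * p_int) / mu_d * 10.0
            out_decay[cnt] = i
            out_ring[cnt] = best_ring
            out_tax[cnt] = best_sec * per_rsec + best_p
            out_e[cnt] = e
            out_t[cnt] = t_emit[i] + (path + best_t + d_mm) * c_inv
            out_scat[cnt] = nscat
            cnt += 1
    return cnt


@njit(cache=True, fastmath=True, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    """Rotate a unit vector away from itself by acos(cos_t) with azimuth
    phi (standard scattering-frame rotation)."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    sp = np.sin(phi)
    cp = np.cos(phi)
    if abs(uz) < 0.999999:
        nrm = np.sqrt(ux * ux + uy * uy)
        # e1 = u x ez / |..| ; e2 = u x e1
        e1x = uy / nrm
        e1y = -ux / nrm
        e2x = uz * ux / nrm
        e2y = uz * uy / nrm
        e2z = -nrm
        vx = ux * cos_t + sin_t * (cp * e1x + sp * e2x)
        vy = uy * cos_t + sin_t * (cp * e1y + sp * e2y)
        vz = uz * cos_t + sin_t * (sp * e2z)
    else:
        sgn = 1.0 if uz > 0 else -1.0
        vx = sin_t * cp
        vy = sin_t * sp * sgn
        vz = sgn * cos_t
    nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / nrm, vy / nrm, vz / nrm


def transport_photons(positions, times_ps, phantom: VoxelPhantom | None,
                      model: ScannerModel, cfg: DigitizerConfig, seed: int):
    """Transport annihilation pairs and return raw crystal hits.

    Returns a dict of arrays: decay (index into the batch), ring, tax,
    energy (true deposit, keV), time (ps), n_scatters.
    """
    n = positions.shape[0]
    cap = 2 * n + 16
    out_decay = np.empty(cap, np.int64)
    out_ring = np.empty(cap, np.int16)
    out_tax = np.empty(cap, np.int16)
    out_e = np.empty(cap, np.float32)
    out_t = np.empty(cap, np.float64)
    out_scat = np.empty(cap, np.uint8)
    if phantom is not None:
        mu = np.ascontiguousarray(phantom.mu_511, dtype=np.float32)
        ox, oy, oz = (float(v) for v in phantom.origin)
        vox = float(phantom.voxel_size)
        mumax = float(mu.max())
    else:
        mu = np.zeros((1, 1, 1), np.float32)
        ox = oy = oz = 0.0
        vox = 1.0
        mumax = 0.0
    spec = model.spec
    acol = np.deg2rad(cfg.acollinearity_fwhm_deg) * physics.FWHM_TO_SIGMA
    cnt = _transport_batch(
        np.ascontiguousarray(positions, dtype=np.float64),
        np.ascontiguousarray(times_ps, dtype=np.float64),
        mu, ox, oy, oz, vox, mumax,
        physics.water_mu_ratio_table(), physics.water_photoelectric_fraction_table(),
        physics.lyso_mu_table(),
        spec.front_face_radius, model.axial_extent / 2.0, spec.axial_pitch,
        spec.n_rings, spec.n_rsector,
        np.cos(model.panel_theta), np.sin(model.panel_theta),
        spec.transaxial_pitch,
        spec.crystals_per_rsector_transaxial, spec.crystal_size[2] / 10.0,
        acol, spec.bore_liner_radius, spec.bore_liner_thickness,
        float(physics.PMMA.mu(511.0)) if phantom is not None else 0.0,
        seed & 0x7FFFFFFF,
        out_decay, out_ring, out_tax, out_e, out_t, out_scat)
    return dict(decay=out_decay[:cnt], ring=out_ring[:cnt], tax=out_tax[:cnt],
                energy=out_e[:cnt], time=out_t[:cnt], scat=out_scat[:cnt])


# --------------------------------------------------------------------------
# digitizer: adder + rsector energy-winner readout, blur, efficiency, window
# --------------------------------------------------------------------------

def digitize(hits: dict, cfg: DigitizerConfig, model: ScannerModel,
             rng: np.random.Generator) -> dict:
    """Convert raw hits into singles.

    Per decay and per rsector, deposits are summed (adder) and positioned
    at the crystal with the largest individual deposit (energy-winner
    readout at the rsector level, imitating Compton-scatter recovery);
    then Gaussian energy blur, the detection efficiency, Gaussian time
    blur, and finally the energy window are applied.
    """
    per_rsec = model.spec.crystals_per_rsector_transaxial
    decay = np.asarray(hits["decay"], np.int64)
    ring = np.asarray(hits["ring"], np.int16)
    tax = np.asarray(hits["tax"], np.int16)
    energy = np.asarray(hits["energy"], np.float64)
    time = np.asarray(hits["time"], np.float64)
    scat = np.asarray(hits["scat"], np.uint16)
    sector = tax // per_rsec
    order = np.lexsort((sector, decay))
    decay, ring, tax, energy, time, scat, sector = (
        a[order] for a in (decay, ring, tax, energy, time, scat, sector))
    if decay.size:
        same = (decay[1:] == decay[:-1]) & (sector[1:] == sector[:-1])
    else:
        same = np.zeros(0, bool)
    # at most two hits per decay, so merges are adjacent pairs
    merge = np.flatnonzero(same)
    keep = np.ones(decay.size, bool)
    if merge.size:
        a, b = merge, merge + 1
        win_b = energy[b] >= energy[a]
        tot = energy[a] + energy[b]
        winner = np.where(win_b, b, a)
        energy = energy.copy()
        energy[winner] = tot
        scat = scat.copy()
        scat[winner] = scat[a] + scat[b]
        time = time.copy()
        time[winner] = np.minimum(time[a], time[b])
        keep[np.where(win_b, a, b)] = False
    decay, ring, tax, energy, time, scat = (
        a[keep] for a in (decay, ring, tax, energy, time, scat))
    return _finalize_singles(decay, ring, tax, energy, time, scat, cfg, rng)


def _finalize_singles(src, ring, tax, energy, time, scat, cfg, rng):
    """Shared tail of the digitizer chain: energy blur, efficiency,
    temporal blur, energy window."""
    if cfg.energy_resolution_fwhm > 0:
        energy = energy + rng.normal(size=energy.size) * physics.energy_sigma(
            energy, cfg.energy_resolution_fwhm)
    if cfg.detection_efficiency < 1.0:
        m = rng.random(energy.size) < cfg.detection_efficiency
        src, ring, tax, energy, time, scat = (
            a[m] for a in (src, ring, tax, energy, time, scat))
    if cfg.temporal_fwhm_ps > 0:
        time = time + rng.normal(size=time.size) * (cfg.temporal_fwhm_ps
                                                    * physics.FWHM_TO_SIGMA)
    lo, hi = cfg.energy_window
    m = (energy >= lo) & (energy <= hi)
    return dict(src=src[m], ring=ring[m].astype(np.int16),
                tax=tax[m].astype(np.int16), energy=energy[m].astype(np.float32),
                time=time[m], scat=scat[m].astype(np.uint16))


# --------------------------------------------------------------------------
# 176Lu intrinsic background
# --------------------------------------------------------------------------

def _lu176_deposit_sampler():
    """Inverse-CDF sampler for the single-crystal 176Lu deposit spectrum:
    a beta continuum (endpoint 596 keV) plus the 307/202/88 keV cascade
    gammas, each absorbed in the origin crystal with its LYSO capture
    probability.  A documented approximation; only the rate is calibrated."""
    t = np.linspace(0.5, 595.5, 1191)
    w = (t + 511.0) / 511.0
    p = np.sqrt(np.maximum(w * w - 1.0, 0.0))
    shape = p * w * (596.0 - t) ** 2
    cdf = np.cumsum(shape)
    cdf /= cdf[-1]
    gammas = np.array([306.8, 201.8, 88.3])
    p_abs = 1.0 - np.exp(-physics.LYSO.mu(gammas) * 1.25)

    def sample(rng, n):
        e = np.interp(rng.random(n), cdf, t)
        for g, pa in zip(gammas, p_abs):
            e = e + g * (rng.random(n) < pa)
        return e

    return sample


_LU_SAMPLER = _lu176_deposit_sampler()


def lu176_background(cfg: DigitizerConfig, model: ScannerModel, duration_s,
                     rng: np.random.Generator, decimation=1.0) -> dict:
    """Singles from intrinsic crystal radioactivity: a Poisson stream at
    the configured rate, uniform over crystals and time."""
    mean = cfg.lu176_rate_khz * 1e3 * duration_s * decimation
    n = int(rng.poisson(mean)) if mean > 0 else 0
    spec = model.spec
    flat = rng.integers(0, spec.n_crystals, n)
    ring = (flat // spec.crystals_per_ring).astype(np.int16)
    tax = (flat % spec.crystals_per_ring).astype(np.int16)
    time = rng.uniform(0.0, duration_s * 1e12, n)
    energy = _LU_SAMPLER(rng, n)
    src = -1 - np.arange(n, dtype=np.int64)  # unique non-annihilation origins
    scat = np.zeros(n, np.uint16)
    return _finalize_singles(src, ring, tax, energy, time, scat, cfg, rng)


# --------------------------------------------------------------------------
# coincidence sorting
# --------------------------------------------------------------------------

@dataclass
class CoincidenceList:
    """Prompt coincidences with ground-truth labels."""

    ring1: np.ndarray
    tax1: np.ndarray
    ring2: np.ndarray
    tax2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    tof_delta: np.ndarray  # time1 - time2, ps
    label: np.ndarray      # LABEL_TRUE / LABEL_SCATTER / LABEL_RANDOM
    lu: np.ndarray         # True when a 176Lu single is involved
    time1: np.ndarray = None  # absolute timestamp of the first single, ps
    scat1: np.ndarray = None  # object-scatter count of each single
    scat2: np.ndarray = None

    def __len__(self):
        return self.ring1.size

    def counts(self):
        return dict(
            prompts=int(len(self)),
            trues=int(np.sum(self.label == LABEL_TRUE)),
            scatters=int(np.sum(self.label == LABEL_SCATTER)),
            randoms=int(np.sum(self.label == LABEL_RANDOM)),
            lu_involved=int(np.sum(self.lu)),
        )

    @classmethod
    def concatenate(cls, parts):
        parts = [p for p in parts if len(p)]
        if not parts:
            return _empty_coincidences()
        return cls(*[np.concatenate([getattr(p, f) for p in parts])
                     for f in ("ring1", "tax1", "ring2", "tax2", "e1", "e2",
                               "tof_delta", "label", "lu", "time1",
                               "scat1", "scat2")])


def _empty_coincidences():
    return CoincidenceList(*(np.empty(0, d) for d in
                             (np.int16, np.int16, np.int16, np.int16,
                              np.float32, np.float32, np.float64,
                              np.uint8, bool, np.float64, np.uint16,
                              np.uint16)))


def sort_coincidences(singles: dict, cfg: DigitizerConfig,
                      model: ScannerModel) -> CoincidenceList:
    """Multi-window coincidence sorting with a takeAllGoods policy.

    Every pair of singles separated by at most tau (half the full
    coincidence window) forms a prompt, except pairs failing the minimum
    transaxial sector difference.  Input singles must be time-ordered.
    """
    t = singles["time"]
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("singles must be sorted by time")
    if t.size < 2:
        return _empty_coincidences()
    right = np.searchsorted(t, t + TAU_PS, side="right")
    counts = right - np.arange(t.size) - 1
    i = np.repeat(np.arange(t.size), counts)
    if i.size == 0:
        return _empty_coincidences()
    # within-group offsets 1..counts[i], fully vectorised
    start = np.cumsum(counts) - counts
    j = i + (np.arange(i.size) - np.repeat(start, counts)) + 1
    per = model.spec.crystals_per_rsector_transaxial
    s1 = singles["tax"][i] // per
    s2 = singles["tax"][j] // per
    d = (s1 - s2) % model.spec.n_rsector
    ok = np.minimum(d, model.spec.n_rsector - d) >= cfg.min_sector_difference
    i, j = i[ok], j[ok]
    src_i = singles["src"][i]
    src_j = singles["src"][j]
    same = (src_i == src_j) & (src_i >= 0)
    nsc = singles["scat"][i].astype(np.int32) + singles["scat"][j]
    label = np.full(i.size, LABEL_RANDOM, np.uint8)
    label[same & (nsc == 0)] = LABEL_TRUE
    label[same & (nsc > 0)] = LABEL_SCATTER
    lu = (src_i < 0) | (src_j < 0)
    return CoincidenceList(
        ring1=singles["ring"][i], tax1=singles["tax"][i],
        ring2=singles["ring"][j], tax2=singles["tax"][j],
        e1=singles["energy"][i], e2=singles["energy"][j],
        tof_delta=(t[i] - t[j]), label=label, lu=lu, time1=t[i],
        scat1=singles["scat"][i], scat2=singles["scat"][j])


# --------------------------------------------------------------------------
# acquisition driver
# --------------------------------------------------------------------------

@dataclass
class Acquisition:
    """One simulated frame: prompts, per-crystal singles counts and the
    ground-truth summary."""

    coincidences: CoincidenceList
    singles_per_crystal: np.ndarray  # (n_rings, crystals_per_ring) int64
    duration_s: float
    decimation: float
    seed: int
    summary: dict = field(default_factory=dict)


def simulate_acquisition(spec: PhantomSpec, cfg: DigitizerConfig,
                         model: ScannerModel, duration_s: float,
                         decimation: float, seed: int,
                         phantom: VoxelPhantom | None = None,
                         voxel_size: float = 2.0,
                         batch: int = 2_000_000,
                         include_lu: bool = True) -> Acquisition:
    """End-to-end simulation of one acquisition frame at a decimated
    activity (the 176Lu rate is decimated by the same factor so that the
    trues-to-background balance scales consistently)."""
    if not (0.0 < decimation <= 1.0):
        raise ValueError("decimation must be in (0, 1]")
    from .phantoms import build_phantom
    rng = np.random.default_rng(seed)
    if phantom is None and spec.attenuating:
        phantom = build_phantom(spec, voxel_size=voxel_size)
    source = AnalyticSource(spec)
    mean = expected_decays(source.total_activity_kbq, duration_s, decimation)
    n_total = int(rng.poisson(mean)) if mean > 0 else 0

    singles_parts = []
    done = 0
    kbatch = 0
    while done < n_total:
        m = min(batch, n_total - done)
        pos = source.sample(rng, m)
        times = rng.uniform(0.0, duration_s * 1e12, m)
        hits = transport_photons(pos, times, phantom if spec.attenuating else None,
                                 model, cfg, seed=int(rng.integers(1 << 31)))
        s = digitize(hits, cfg, model, rng)
        s["src"] = s["src"] + done  # decay ids unique across batches
        singles_parts.append(s)
        done += m
        kbatch += 1
    if include_lu and cfg.lu176_rate_khz > 0:
        singles_parts.append(lu176_background(cfg, model, duration_s, rng,
                                              decimation))
    keys = ("src", "ring", "tax", "energy", "time", "scat")
    if singles_parts:
        singles = {k: np.concatenate([p[k] for p in singles_parts]) for k in keys}
    else:
        singles = dict(src=np.empty(0, np.int64), ring=np.empty(0, np.int16),
                       tax=np.empty(0, np.int16), energy=np.empty(0, np.float32),
                       time=np.empty(0, np.float64), scat=np.empty(0, np.uint16))
    order = np.argsort(singles["time"], kind="stable")
    singles = {k: v[order] for k, v in singles.items()}

    per_crystal = np.zeros(model.spec.n_crystals, np.int64)
    flat = singles["ring"].astype(np.int64) * model.spec.crystals_per_ring + singles["tax"]
    np.add.at(per_crystal, flat, 1)
    per_crystal = per_crystal.reshape(model.spec.n_rings,
                                      model.spec.crystals_per_ring)

    coin = sort_coincidences(singles, cfg, model)
    summary = dict(decays=n_total, singles=int(singles["time"].size),
                   duration_s=duration_s, decimation=decimation,
                   **coin.counts())
    return Acquisition(coin, per_crystal, duration_s, decimation, seed, summary)
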