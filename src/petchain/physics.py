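"""Photon-interaction physics shared by the simulator and the scatter model.

Everything here is expressed in keV, cm and cm^-1.  The phantom materials
(water, polystyrene foam, PMMA) are Compton dominated between 100 and
650 keV, so their attenuation is modelled as electron density times the
Klein-Nishina cross-section plus a small 1/E^3 photoelectric term; LYSO
needs a substantial photoelectric component and gets its own table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ELECTRON_REST_KEV = 511.0
#: classical electron radius squared, cm^2
R_E_SQ = 7.94080e-26
AVOGADRO = 6.02214076e23
#: speed of light in mm/ps
C_MM_PER_PS = 0.299792458
#: 18F positron yield per decay
F18_POSITRON_YIELD = 0.967
#: 18F half-life in minutes
F18_HALF_LIFE_MIN = 109.77

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def compton_energy(e_kev, cos_theta):
    """Energy of a photon of energy ``e_kev`` after Compton scattering by
    an angle with cosine ``cos_theta``."""
    alpha = np.asarray(e_kev, dtype=float) / ELECTRON_REST_KEV
    return np.asarray(e_kev) / (1.0 + alpha * (1.0 - np.asarray(cos_theta)))


def klein_nishina_dsigma(e_kev, cos_theta):
    """Klein-Nishina differential cross-section dsigma/dOmega (cm^2/sr per
    electron) for incident energy ``e_kev`` and scattering-angle cosine."""
    cos_theta = np.asarray(cos_theta, dtype=float)
    alpha = np.asarray(e_kev, dtype=float) / ELECTRON_REST_KEV
    ratio = 1.0 / (1.0 + alpha * (1.0 - cos_theta))  # E'/E
    sin2 = 1.0 - cos_theta**2
    return 0.5 * R_E_SQ * ratio**2 * (ratio + 1.0 / ratio - sin2)


def klein_nishina_total(e_kev):
    """Total Klein-Nishina cross-section (cm^2 per electron)."""
    a = np.asarray(e_kev, dtype=float) / ELECTRON_REST_KEV
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log(1.0 + 2.0 * a) / a)
    t2 = np.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    return 2.0 * np.pi * R_E_SQ * (t1 + t2 - t3)


def energy_sigma(e_kev, fwhm_frac_511=0.0963):
    """Gaussian energy-blur sigma (keV) at energy ``e_kev``.

    The fractional FWHM is anchored at 511 keV and scales with 1/sqrt(E)
    (scintillator photon statistics), so the absolute sigma scales with
    sqrt(E):  sigma(E) = f511 * sqrt(511 * E) * FWHM_TO_SIGMA.
    """
    return fwhm_frac_511 * np.sqrt(ELECTRON_REST_KEV * np.asarray(e_kev, dtype=float)) * FWHM_TO_SIGMA


def window_acceptance(e_kev, lower=425.0, upper=650.0, fwhm_frac_511=0.0963):
    """Probability that a deposit of true energy ``e_kev`` falls inside the
    energy window after Gaussian blurring."""
    from scipy.special import ndtr

    sigma = energy_sigma(e_kev, fwhm_frac_511)
    e = np.asarray(e_kev, dtype=float)
    return ndtr((upper - e) / sigma) - ndtr((lower - e) / sigma)


@dataclass(frozen=True)
class Material:
    """Attenuating material: electron density plus a photoelectric
    coefficient ``mu_pe = pe_coeff / E^3`` (E in keV, mu in cm^-1)."""

    name: str
    electron_density: float  # electrons / cm^3
    pe_coeff: float = 0.0

    def mu(self, e_kev):
        e = np.asarray(e_kev, dtype=float)
        return self.electron_density * klein_nishina_total(e) + self.pe_coeff / e**3

    def mu_compton(self, e_kev):
        return self.electron_density * klein_nishina_total(e_kev)


def _water():
    n_e = 1.0 * 0.5551 * AVOGADRO  # rho * Z/A * N_A
    # photoelectric anchored at mu_pe(100 keV) ~ 0.0026 cm^-1
    return Material("water", n_e, 0.0026 * 100.0**3)


def _lung_insert(mu_511=0.004):
    # low-density polystyrene foam; defined by its 511 keV attenuation
    n_e = mu_511 / klein_nishina_total(511.0)
    return Material("lung_insert", float(n_e))


def _pmma():
    n_e = 1.19 * 0.5394 * AVOGADRO
    return Material("pmma", n_e, 0.003 * 100.0**3)


def _lyso():
    n_e = 7.25 * 0.427 * AVOGADRO
    mu_c_511 = n_e * klein_nishina_total(511.0)
    # pin total mu at 511 keV to 0.87 cm^-1 (published LYSO value)
    pe = (0.87 - mu_c_511) * 511.0**3
    return Material("lyso", n_e, float(pe))


WATER = _water()
PMMA = _pmma()
LYSO = _lyso()
AIR = Material("air", 0.0)


def lung_insert_material(mu_511=0.004):
    return _lung_insert(mu_511)


#: energy grid used by all tabulated lookups (keV)
ENERGY_GRID = np.arange(50.0, 701.0, 1.0)


def water_mu_ratio_table():
    """mu_water(E)/mu_water(511) on ENERGY_GRID -- used to scale any
    Compton-dominated material's 511 keV map to other energies."""
    return (WATER.mu(ENERGY_GRID) / WATER.mu(511.0)).astype(np.float64)


def water_photoelectric_fraction_table():
    """Photoelectric share of water interactions on ENERGY_GRID."""
    mu = WATER.mu(ENERGY_GRID)
    pe = WATER.pe_coeff / ENERGY_GRID**3
    return (pe / mu).astype(np.float64)


def lyso_mu_table():
    return LYSO.mu(ENERGY_GRID).astype(np.float64)


def detector_interaction_probability(e_kev, path_cm=2.5):
    """Probability that a photon of energy ``e_kev`` interacts within a
    LYSO crystal of the given depth (normal incidence by default)."""
    return 1.0 - np.exp(-LYSO.mu(e_kev) * path_cm)


def sample_klein_nishina(rng, e_kev, size):
    """Sample Compton scattering-angle cosines from the Klein-Nishina
    distribution by rejection (vectorised reference implementation; the
    transport kernel carries its own scalar copy)."""
    out = np.empty(size)
    peak = klein_nishina_dsigma(e_kev, 1.0)
    n = 0
    while n < size:
        m = max(int((size - n) * 4.5), 64)
        c = rng.uniform(-1.0, 1.0, m)
        u = rng.uniform(0.0, peak, m)
        acc = c[u < klein_nishina_dsigma(e_kev, c)]
        take = min(acc.size, size - n)
        out[n : n + take] = acc[:take]
        n += take
    return out
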