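"""Four-stage pipeline: simulate -> bin -> correct -> reconstruct ->
evaluate, runnable end to end or stage by stage.

Normalisation is a scanner property, not a phantom property, so the two
calibration acquisitions (central cylinder and annulus) are simulated
once per scanner/layout configuration and cached in-process; the
randoms, attenuation and scatter corrections are recomputed per
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as pio
from .corrections import (AttenuationSinogram, NormalisationComponents,
                          RandomsSinogram, attenuation_correction_sinogram,
                          estimate_normalisation, randoms_from_singles,
                          well_counter_calibrate)
from .geometry import (ScannerModel, ScannerSpec, SinogramLayout, build_scanner,
                       desk_layout, histogram_events)
from .nema import IqReport, evaluate_image, scatter_fraction
from .phantoms import PhantomSpec, VoxelPhantom, build_phantom
from .recon import ReconConfig, ReconImage, gaussian_postfilter, osem_reconstruct
from .simulate import Acquisition, DigitizerConfig, simulate_acquisition
from .sss import ScatterEstimate, iterate_sss


class StageError(RuntimeError):
    """A pipeline stage is missing its upstream artifact."""


@dataclass
class PipelineConfig:
    phantom: PhantomSpec
    # annihilation-photon acollinearity is part of the emulated physics;
    # the bare simulator default leaves it off
    digitizer: DigitizerConfig = DigitizerConfig(acollinearity_fwhm_deg=0.5)
    recon: ReconConfig = ReconConfig(tof=True)
    duration_s: float = 600.0
    decimation: float = 0.01
    seed: int = 1
    voxel_size_mm: float = 2.0
    layout: SinogramLayout = None
    norm_decays: float = 6.0e7
    sss_iterations: int = 2
    outdir: Path | None = None

    def __post_init__(self):
        if self.layout is None:
            self.layout = desk_layout()

    @property
    def sbr(self) -> float | None:
        p = self.phantom
        if p.sphere_concentration > 0 and p.background_concentration > 0:
            return p.sphere_concentration / p.background_concentration
        return None


@dataclass
class PipelineResult:
    config: PipelineConfig
    acquisition: Acquisition
    prompts: np.ndarray
    acf: AttenuationSinogram
    norm: NormalisationComponents
    randoms: RandomsSinogram
    scatter: ScatterEstimate
    image: ReconImage
    report: IqReport | None
    phantom_grid: VoxelPhantom
    sf_pct: float | None = None
    paths: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# normalisation calibration (cached per scanner/layout)
# --------------------------------------------------------------------------

_NORM_CACHE: dict = {}


def simulate_norm_acquisitions(model: ScannerModel, digitizer: DigitizerConfig,
                               seed: int = 900, n_decays: float = 6.0e7):
    """The two calibration acquisitions: a non-attenuating central
    cylinder and an annulus just outside the transaxial FOV, both 5 MBq
    for 2 h with the 176Lu noise source off, decimated to ``n_decays``
    positron decays each."""
    cal_cfg = replace(digitizer, lu176_rate_khz=0.0)
    length = model.axial_extent
    dec = float(np.clip(n_decays / (5e3 * 1e3 * 7200.0 * 0.967), 0.0, 1.0))
    central = simulate_acquisition(
        PhantomSpec.norm_cylinder(length=length, concentration=5e3 / (np.pi * 100**2 * length / 1000.0)),
        cal_cfg, model, 7200.0, dec, seed)
    annulus = simulate_acquisition(
        PhantomSpec.norm_annulus(length=length, concentration=5e3 / (np.pi * (355**2 - 354**2) * length / 1000.0)),
        cal_cfg, model, 7200.0, dec, seed + 1)
    return central, annulus


def get_normalisation(model: ScannerModel, layout: SinogramLayout,
                      digitizer: DigitizerConfig, seed: int = 900,
                      n_decays: float = 6.0e7) -> NormalisationComponents:
    """Cached component estimate from the calibration acquisitions."""
    key = (pio.scanner_hash(model.spec), layout, digitizer, seed, n_decays)
    if key in _NORM_CACHE:
        return _NORM_CACHE[key]
    central, annulus = simulate_norm_acquisitions(model, digitizer, seed, n_decays)
    comp = estimate_normalisation(central, annulus, model, layout)
    _NORM_CACHE[key] = comp
    return comp


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, model: ScannerModel) -> Acquisition:
    return simulate_acquisition(cfg.phantom, cfg.digitizer, model,
                                cfg.duration_s, cfg.decimation, cfg.seed,
                                voxel_size=cfg.voxel_size_mm)


def stage_bin(acq: Acquisition, model: ScannerModel,
              layout: SinogramLayout) -> np.ndarray:
    c = acq.coincidences
    return histogram_events(model, layout, c.ring1, c.tax1, c.ring2, c.tax2,
                            c.tof_delta)


def stage_correct(cfg: PipelineConfig, acq: Acquisition, prompts: np.ndarray,
                  model: ScannerModel, phantom: VoxelPhantom):
    layout = cfg.layout
    acf = attenuation_correction_sinogram(phantom, model, layout)
    norm = get_normalisation(model, layout, cfg.digitizer,
                             n_decays=cfg.norm_decays)
    randoms = randoms_from_singles(
        acq.singles_per_crystal, acq.duration_s,
        cfg.digitizer.coincidence_window_2tau_ns * 1e-9, model, layout)
    rng = np.random.default_rng(cfg.seed + 7)
    scatter = iterate_sss(prompts, randoms.expected, acf, norm, phantom,
                          model, layout, rng, n_iter=cfg.sss_iterations,
                          digitizer=cfg.digitizer)
    return acf, norm, randoms, scatter


def stage_reconstruct(cfg: PipelineConfig, prompts, acf, norm, randoms,
                      scatter, model: ScannerModel,
                      acquisition: Acquisition | None = None) -> ReconImage:
    if cfg.recon.tof and acquisition is not None:
        from .recon import osem_tof_reconstruct
        img = osem_tof_reconstruct(acquisition.coincidences, model, cfg.layout,
                                   cfg.recon, acf=acf.acf, eta=norm.eta_sino,
                                   randoms=randoms.expected,
                                   scatter=scatter.scaled, valid=norm.valid)
    else:
        img = osem_reconstruct(prompts, model, cfg.layout, cfg.recon,
                               acf=acf.acf, eta=norm.eta_sino,
                               randoms=randoms.expected, scatter=scatter.scaled,
                               valid=norm.valid)
    img = gaussian_postfilter(img, cfg.recon.postfilter_fwhm_mm)
    # normalise to unit acquisition time and unit decimation (rate-like
    # units) so the well-counter calibration transfers across runs
    img.values = img.values / (cfg.duration_s * cfg.decimation)
    img.provenance["per_second_per_decimation"] = True
    return img


def stage_evaluate(cfg: PipelineConfig, image: ReconImage, prompts, randoms,
                   scatter, norm) -> tuple:
    valid = norm.valid
    p_tot = float(np.asarray(prompts)[valid].sum())
    r_tot = float(np.asarray(randoms.expected)[valid].sum())
    s_tot = float(np.asarray(scatter.scaled)[valid].sum())
    sf = scatter_fraction(p_tot, s_tot, r_tot)
    report = None
    if cfg.sbr is not None and cfg.phantom.sphere_diameters:
        report = evaluate_image(image, cfg.phantom, cfg.sbr, sf_pct=sf)
    return sf, report


def run_pipeline(cfg: PipelineConfig, scanner: ScannerSpec = ScannerSpec(),
                 write_artifacts: bool | None = None) -> PipelineResult:
    """Run every stage; artifacts are written when ``cfg.outdir`` is set."""
    model = build_scanner(scanner)
    write = (cfg.outdir is not None) if write_artifacts is None else write_artifacts
    paths = {}
    acq = stage_simulate(cfg, model)
    phantom = build_phantom(cfg.phantom, voxel_size=cfg.voxel_size_mm) \
        if cfg.phantom.attenuating else None
    prompts = stage_bin(acq, model, cfg.layout)
    if phantom is None:
        raise StageError("correction stage needs an attenuating phantom")
    acf, norm, randoms, scatter = stage_correct(cfg, acq, prompts, model,
                                                phantom)
    image = stage_reconstruct(cfg, prompts, acf, norm, randoms, scatter, model,
                              acquisition=acq)
    sf, report = stage_evaluate(cfg, image, prompts, randoms, scatter, norm)
    if write:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths["events"] = out / "events.h5"
        pio.write_event_list(paths["events"], acq, scanner, cfg.digitizer)
        paths["sinograms"] = out / "sinograms.h5"
        pio.write_sinogram_set(paths["sinograms"], dict(
            prompts=prompts.astype(np.float32),
            randoms=randoms.expected.astype(np.float32),
            scatter=scatter.scaled.astype(np.float32),
            acf=acf.acf.astype(np.float32),
            eta=norm.eta_sino.astype(np.float32),
            tail_mask=scatter.tail_mask.astype(np.uint8),
            valid=norm.valid.astype(np.uint8)), cfg.layout,
            meta=dict(seed=cfg.seed, decimation=cfg.decimation,
                      duration_s=cfg.duration_s,
                      scanner_hash=pio.scanner_hash(scanner),
                      summary=acq.summary))
        paths["image"] = out / "image.nii.gz"
        pio.write_volume(paths["image"], image,
                         sidecar=dict(seed=cfg.seed, sf_pct=sf))
        if report is not None:
            paths["report"] = out / "report.json"
            pio.write_report(out / "report", report)
    return PipelineResult(cfg, acq, prompts, acf, norm, randoms, scatter,
                          image, report, phantom, sf_pct=sf, paths=paths)


def calibrate_wcc(model: ScannerModel, digitizer: DigitizerConfig,
                  seed: int = 77, decimation: float = 2e-3,
                  duration_s: float = 1200.0, recon: ReconConfig = None):
    """Well-counter calibration run: uniform 9.5 cm x 20 cm cylinder at
    4.4 kBq/mL through the full chain; returns the calibration and image."""
    spec = PhantomSpec.uniform_cylinder(radius=95.0, length=200.0,
                                        concentration=4.4)
    cfg = PipelineConfig(phantom=spec, digitizer=digitizer,
                         recon=recon or ReconConfig(), duration_s=duration_s,
                         decimation=decimation, seed=seed)
    res = run_pipeline(cfg, model.spec, write_artifacts=False)
    wcc = well_counter_calibrate(res.image.values, res.image.grid.dx,
                                 res.image.grid.slice_z, 4.4)
    return wcc, res
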