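# petchain

A desk-scale, fully tested pipeline from Monte Carlo PET simulation to
quantitative reconstructed images, modelled on a GE Discovery-MI-like
four-ring scanner (34 rsectors, 19584 LYSO crystals in 36 rings of 544,
744.2 mm face-to-face).  It is written for medical-physics work that
needs the *whole* chain under one roof — simulate an acquisition, form
sinograms, compute every correction the way a clinical workflow does,
reconstruct, and score the image with NEMA NU 2-style metrics — so that
the effect of any single parameter can be followed from photon physics
to image quality.

The chain:

- **Simulator** — annihilation pairs transported by Woodcock
  delta-tracking with Klein–Nishina Compton sampling through voxelised
  phantoms (NEMA IQ, Data Spectrum micro-sphere cylinder, uniform
  cylinders, incl. acrylic walls, cold sphere shells, a carbon-fibre
  couch and the plastic bore liner); a digitizer chain with adder,
  rsector-level energy-winner readout, Gaussian energy blur (9.63% FWHM
  at 511 keV), 425–650 keV window, 268.7 ps timing blur, a 1142 kHz
  ¹⁷⁶Lu intrinsic-background stream, and a multi-window takeAllGoods
  coincidence sorter (2τ = 4.9 ns, minimum sector difference 4).
  Events carry ground-truth labels (true / scattered / random).
- **Sinograms** — crystal-index arithmetic over the
  rsector/module/submodule/crystal hierarchy,

  ID_ax = ⌊ID_rsec/N_rsec⌋·N_mod,ax·N_smod,ax·N_cry,ax +
  ⌊ID_mod/N_mod,tax⌋·N_smod,ax·N_cry,ax + ⌊ID_smod/N_smod,tax⌋·N_cry,ax +
  ⌊ID_cry/N_cry,tax⌋,

  and geometric (radial, azimuthal, ring-pair/SSRB, TOF) binning.
- **Corrections** — attenuation factors acf = exp(∫μ dl) by exact Siddon
  ray tracing; component-based normalisation
  η = ε_ui ε_vj b_u b_v g_uv r f estimated from two simulated
  calibration acquisitions; randoms R = 2τ·S₁·S₂/T from singles;
  iterative TOF-capable single-scatter simulation with least-squares
  tail scaling ∑_b w_b (y_b − s_b β − q)²; well-counter calibration
  WCC = C_abs/C_arb.
- **Reconstruction** — OS-EM (4 iterations × 16 subsets) with the Joseph
  projector, corrections in the system matrix and sensitivity image,
  4 mm Gaussian post-filter; both a binned non-TOF engine and a sparse
  TOF-histogram engine (380 ps kernel); ramp-filter FBP seeds the
  scatter iteration.
- **Evaluation** — NEMA NU 2-style scatter fraction SF = S/(T+S),
  contrast recovery CRC_i = (S_i/B_i − 1)/(a_H/a_B − 1), SNR, background
  variability, residual lung error ΔC = C_lung/B_Ø37, and line profiles.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import petchain as pc
from petchain.pipeline import PipelineConfig, run_pipeline
from petchain.recon import ReconConfig

cfg = PipelineConfig(
    phantom=pc.PhantomSpec.nema_iq(),   # spheres 32.6, background 3.7 kBq/mL
    decimation=8e-3,                    # desk-scale activity decimation
    seed=42,
    recon=ReconConfig(nx=256, tof=True),
    norm_decays=2e7,
)
res = run_pipeline(cfg)
s = res.acquisition.summary
print(f"prompts {s['prompts']}  trues {s['trues']}  "
      f"scatters {s['scatters']}  randoms {s['randoms']}")
print(f"scatter fraction (chain estimate): {res.sf_pct:.1f}%")
print("CRC%:", {k: round(v, 1) for k, v in res.report.crc_pct.items()})
print(f"residual lung error: {res.report.lung_error_pct:.1f}%")
```

Output of this exact configuration (10-minute NEMA IQ hot-background
acquisition decimated to ~1% of the clinical activity, ≈ 2.8 × 10⁶
prompt coincidences, about 12 minutes on one CPU):

```
prompts 2770017  trues 1789798  scatters 975563  randoms 4656
scatter fraction (chain estimate): 32.2%
CRC%: {'37': 78.7, '28': 77.2, '22': 76.3, '17': 67.7, '13': 35.8, '10': 29.6}
residual lung error: 15.1%
```

The contrast recovery of the largest sphere (~80%) and its fall-off
with sphere size match full-statistics validation values for this
scanner class; the residual lung error is dominated at desk scale by
unmodelled multiple scatter and the low-count bias of EM in a cold
region (see `docs/methods.md`).  The ground-truth labels of the same
run give a scatter fraction of 35.3%, against which the single-scatter
chain estimate is expected to sit a few points low.

A command-line interface wraps the same pipeline:

```bash
petchain all --config examples/nemab.yaml --seed 42 --decimation 0.008
```

with stages `simulate | bin | correct | reconstruct | evaluate`
runnable individually from each other's artifacts (HDF5 event lists and
sinogram sets, NIfTI volumes, JSON/CSV reports).

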