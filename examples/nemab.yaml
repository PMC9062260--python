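# NEMA IQ phantom with hot background (spheres 32.6, background 3.7 kBq/mL),
# 10-minute frame, desk-scale decimation
phantom:
  kind: nema_iq
duration_s: 600.0
decimation: 0.008
seed: 42
recon:
  nx: 256
  tof: true
norm_decays: 2.0e7
outdir: petchain_out
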