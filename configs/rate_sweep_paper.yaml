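# Loading-rate sweep, full reference design: 2 impulses x 5 slab
# thicknesses at a fixed 5 A gap, 3 replicate membranes.
experiment: rate_sweep
impulses_mPa_s: [1.0, 10.0]
slab_thicknesses_A: [5.0, 10.0, 15.0, 20.0, 30.0]
gaps_A: [5.0]
seeds: [0, 1, 2]
sample_interval_ps: 0.05
water_density_kg_m3: 1000.0
outdir: results/rate_sweep_paper
system:
  n_lipids: 240
  cholesterol_fraction: 0.10
  solvent_pad_plus_z_A: 200.0
  solvent_pad_minus_z_A: 30.0
  temperature_K: 310.0
  equilibration_steps: 20000
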