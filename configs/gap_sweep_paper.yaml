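# Gap sweep, full reference design: 10 mPa s impulse, one slab
# thickness, gaps 5-20 A between the slab face and the proximal
# head-group density peak.
experiment: gap_sweep
impulses_mPa_s: [10.0]
slab_thicknesses_A: [5.0]
gaps_A: [5.0, 10.0, 15.0, 20.0]
seeds: [0, 1, 2]
sample_interval_ps: 0.05
water_density_kg_m3: 1000.0
outdir: results/gap_sweep_paper
system:
  n_lipids: 240
  cholesterol_fraction: 0.10
  solvent_pad_plus_z_A: 200.0
  solvent_pad_minus_z_A: 30.0
  temperature_K: 310.0
  equilibration_steps: 20000
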