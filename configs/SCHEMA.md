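# Experiment config schema

A config is a YAML mapping resolved by `memshock.pipeline.plan_from_config`.
Validation errors list every offending key.

| key | type | constraint |
|---|---|---|
| `experiment` | str | `rate_sweep` or `gap_sweep` |
| `impulses_mPa_s` | list[float] | non-empty, positive; exactly one entry for `gap_sweep` |
| `slab_thicknesses_A` | list[float] | non-empty, positive; exactly one entry for `gap_sweep` |
| `gaps_A` | list[float] | non-empty, ≥ 0; exactly one entry for `rate_sweep` |
| `seeds` | list[int] | non-empty; one membrane replicate per seed |
| `sample_interval_ps` | float | trajectory sampling interval (default 0.05) |
| `water_density_kg_m3` | float | density in the nominal pulse relations (default 1000) |
| `outdir` | str | output directory |
| `system.n_lipids` | int | even, ≥ 2 (default 240) |
| `system.cholesterol_fraction` | float | [0, 1) (default 0.10) |
| `system.solvent_pad_plus_z_A` | float | +z solvent column (default 200) |
| `system.solvent_pad_minus_z_A` | float | −z solvent column; must host the shock slab (default 30) |
| `system.temperature_K` | float | equilibration temperature (default 310) |
| `system.equilibration_steps` | int | Langevin NVT steps before the shock (default 20000) |

A `rate_sweep` holds the gap fixed and crosses every impulse with every
slab thickness; a `gap_sweep` holds (impulse, slab thickness) fixed and
varies the gap.  Derived per-condition quantities (Δv_z, t_p, P_n, γ) are
echoed to `<outdir>/conditions.csv` for audit.

Presets: `memshock.pipeline.preset_config(name, experiment, outdir)` with
`name` ∈ {`paper`, `ci`, `micro`} returns ready-made configs; the YAML
files in this directory reproduce the two full reference designs.
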