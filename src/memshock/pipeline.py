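"""Experiment orchestration: gap sweep and loading-rate sweep.

A plan resolves a config (YAML or dict) into a list of shock conditions
(impulse, slab thickness, gap) x replicate seeds; ``run_plan`` builds and
equilibrates one membrane per seed (cached), injects each shock, analyses
the trajectory and writes tidy per-run metric CSVs plus a JSON summary.
Everything is deterministic for a fixed master seed; replicate seeds are
derived with numpy SeedSequence.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .units import KB
from .system import LEAFLET_PROXIMAL, LEAFLET_DISTAL
from .shock import ShockSpec
from .build import build_system, assign_leaflets
from .integrate import equilibrate, run_nve_shock
from . import metrics as mx
from .system import default_forcefield


class PlanValidationError(ValueError):
    """Config does not satisfy the plan schema; lists offending keys."""


_SYSTEM_DEFAULTS = {
    "n_lipids": 240,
    "cholesterol_fraction": 0.10,
    "solvent_pad_plus_z_A": 200.0,
    "solvent_pad_minus_z_A": 30.0,
    "temperature_K": 310.0,
    "equilibration_steps": 20000,
}


@dataclass
class ExperimentPlan:
    experiment: str                       # 'gap_sweep' or 'rate_sweep'
    impulses_mPa_s: List[float]
    slab_thicknesses_A: List[float]
    gaps_A: List[float]
    seeds: List[int]
    sample_interval_ps: float = 0.05
    water_density_kg_m3: float = 1000.0
    outdir: str = "results"
    system: dict = field(default_factory=lambda: dict(_SYSTEM_DEFAULTS))

    def conditions(self) -> List[ShockSpec]:
        specs = []
        for imp in self.impulses_mPa_s:
            for lw in self.slab_thicknesses_A:
                for gap in self.gaps_A:
                    specs.append(ShockSpec.from_angstrom(
                        imp, lw, gap_A=gap,
                        water_density_kg_m3=self.water_density_kg_m3))
        return specs

    def echo(self) -> pd.DataFrame:
        """Resolved conditions with derived nominal quantities, for audit."""
        rows = []
        for s in self.conditions():
            rows.append({
                "impulse_mPa_s": s.impulse_mPa_s,
                "L_w_A": s.slab_thickness_A,
                "gap_A": s.gap_A,
                "dv_z_m_s": s.added_velocity,
                "t_p_ps": s.pulse_duration_ps,
                "P_n_GPa": s.peak_pressure_GPa,
                "gamma_per_ps": s.loading_rate_per_ps,
            })
        return pd.DataFrame(rows)


def plan_from_config(config) -> ExperimentPlan:
    """Resolve and validate a config mapping (or YAML path) into a plan."""
    if isinstance(config, (str, os.PathLike)):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PlanValidationError("config must be a mapping")
    errors = []
    experiment = config.get("experiment")
    if experiment not in ("gap_sweep", "rate_sweep"):
        errors.append("experiment: must be 'gap_sweep' or 'rate_sweep'")

    def _num_list(key, positive=True):
        v = config.get(key)
        if not isinstance(v, (list, tuple)) or len(v) == 0:
            errors.append(f"{key}: must be a non-empty list")
            return []
        try:
            out = [float(x) for x in v]
        except (TypeError, ValueError):
            errors.append(f"{key}: entries must be numbers")
            return []
        if positive and any(x <= 0 for x in out):
            errors.append(f"{key}: entries must be positive")
        return out

    impulses = _num_list("impulses_mPa_s")
    lws = _num_list("slab_thicknesses_A")
    gaps = _num_list("gaps_A", positive=False)
    seeds = config.get("seeds", [0, 1, 2])
    if not isinstance(seeds, (list, tuple)) or len(seeds) == 0 \
            or any(not isinstance(s, int) for s in seeds):
        errors.append("seeds: must be a non-empty list of integers")
    if experiment == "gap_sweep" and not errors:
        if len(impulses) != 1 or len(lws) != 1:
            errors.append("gap_sweep: impulses_mPa_s and slab_thicknesses_A "
                          "must each hold exactly one value")
    if experiment == "rate_sweep" and not errors:
        if len(gaps) != 1:
            errors.append("rate_sweep: gaps_A must hold exactly one value")
    system = dict(_SYSTEM_DEFAULTS)
    sys_cfg = config.get("system", {})
    unknown = set(sys_cfg) - set(_SYSTEM_DEFAULTS)
    if unknown:
        errors.append(f"system: unknown keys {sorted(unknown)}")
    system.update({k: v for k, v in sys_cfg.items() if k in _SYSTEM_DEFAULTS})
    if errors:
        raise PlanValidationError("; ".join(errors))
    return ExperimentPlan(
        experiment=experiment, impulses_mPa_s=impulses,
        slab_thicknesses_A=lws, gaps_A=gaps, seeds=list(seeds),
        sample_interval_ps=float(config.get("sample_interval_ps", 0.05)),
        water_density_kg_m3=float(config.get("water_density_kg_m3", 1000.0)),
        outdir=str(config.get("outdir", "results")),
        system=system,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_config(name: str, experiment: str = "rate_sweep",
                  outdir: str = "results") -> dict:
    """Named experiment presets.

    'paper': the full reference design -- rate sweep over L_w in
    {5,10,15,20,30} A at 1 and 10 mPa s (gap 5 A), or gap sweep over
    {5,10,15,20} A at 10 mPa s; full-size membrane (240 lipids, 200/30 A
    pads).  'ci': the desk-scale design -- same impulses at L_w = 30 A
    only, the longest-pulse condition, which is the regime the soft-core
    CG fluid transmits cleanly (piston speeds above ~40 A/ps traverse a
    soft-core fluid quasi-ballistically); small membrane (72 lipids,
    60/30 A pads).  'micro': a minimal single-condition plan for
    determinism and smoke tests.
    """
    if name == "paper":
        cfg = {
            "experiment": experiment,
            "impulses_mPa_s": [10.0] if experiment == "gap_sweep" else [1.0, 10.0],
            "slab_thicknesses_A": [5.0] if experiment == "gap_sweep"
                                  else [5.0, 10.0, 15.0, 20.0, 30.0],
            "gaps_A": [5.0, 10.0, 15.0, 20.0] if experiment == "gap_sweep"
                      else [5.0],
            "seeds": [0, 1, 2],
            "system": dict(_SYSTEM_DEFAULTS),
        }
    elif name == "ci":
        cfg = {
            "experiment": experiment,
            "impulses_mPa_s": [10.0] if experiment == "gap_sweep" else [1.0, 10.0],
            "slab_thicknesses_A": [30.0],
            "gaps_A": [5.0, 10.0, 15.0, 20.0] if experiment == "gap_sweep"
                      else [5.0],
            "seeds": [0, 1, 2],
            "system": {**_SYSTEM_DEFAULTS,
                       "n_lipids": 72,
                       "solvent_pad_plus_z_A": 100.0,
                       # the 30 A slab must fit below the membrane at the
                       # largest gap in a gap sweep
                       "solvent_pad_minus_z_A": 55.0
                       if experiment == "gap_sweep" else 30.0,
                       "equilibration_steps": 10000},
        }
    elif name == "micro":
        cfg = {
            "experiment": "rate_sweep",
            "impulses_mPa_s": [10.0],
            "slab_thicknesses_A": [30.0],
            "gaps_A": [5.0],
            "seeds": [0],
            "system": {**_SYSTEM_DEFAULTS,
                       "n_lipids": 32,
                       "solvent_pad_plus_z_A": 45.0,
                       "solvent_pad_minus_z_A": 30.0,
                       "equilibration_steps": 2000},
        }
    else:
        raise PlanValidationError(f"unknown preset {name!r}")
    cfg["outdir"] = outdir
    return cfg


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

@dataclass
class EquilibratedMembrane:
    frame: object
    topology: object
    forcefield: object
    seed: int
    reference_thickness: float
    equilibrium_summary: dict


@dataclass
class RunRecord:
    run_id: str
    spec_config: dict
    seed: int
    ok: bool = True
    error: str = ""
    energy_drift: float = np.nan
    eps_max: float = np.nan
    reference_thickness_A: float = np.nan
    min_thickness_A: float = np.nan
    final_thickness_A: float = np.nan
    shock_speed_km_s: float = np.nan
    shock_speed_r2: float = np.nan
    scd_min_proximal: float = np.nan
    scd_min_time_proximal_ps: float = np.nan
    scd_min_distal: float = np.nan
    scd_min_time_distal_ps: float = np.nan
    scd_response_time_proximal_ps: float = np.nan
    scd_response_time_distal_ps: float = np.nan
    metrics_csv: str = ""
    slab_mass_amu: float = np.nan


def _derived_seed(master: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


def prepare_membrane(plan: ExperimentPlan, seed: int,
                     master_seed: int = 0) -> EquilibratedMembrane:
    """Build + equilibrate one membrane replicate (deterministic)."""
    sy = plan.system
    build_seed = _derived_seed(master_seed, seed, 1)
    frame, topo = build_system(
        n_lipids=int(sy["n_lipids"]),
        cholesterol_fraction=float(sy["cholesterol_fraction"]),
        solvent_pad_plus_z=float(sy["solvent_pad_plus_z_A"]),
        solvent_pad_minus_z=float(sy["solvent_pad_minus_z_A"]),
        seed=build_seed, temperature=float(sy["temperature_K"]))
    ff = default_forcefield(float(sy["temperature_K"]))
    samples = []
    n_steps = int(sy["equilibration_steps"])
    eq, rep = equilibrate(frame, topo, ff, float(sy["temperature_K"]), n_steps,
                          seed=_derived_seed(master_seed, seed, 2),
                          sample_interval=max(1.0, n_steps * ff.timestep / 20),
                          on_sample=samples.append)
    assign_leaflets(eq, topo)
    tail = samples[3 * len(samples) // 4:] or samples[-1:] or [eq]
    thick = [mx.membrane_thickness(f, topo) for f in tail]
    summary = {
        "temperature_K": rep.mean_temperature_last_quarter,
        "thickness_A_mean": float(np.mean(thick)),
        "thickness_A_sd": float(np.std(thick)),
        "area_per_lipid_A2": mx.area_per_lipid(eq, topo),
        "area_per_phospholipid_A2": mx.area_per_lipid(eq, topo, exclude_sterol=True),
        "neg_scd_bilayer": mx.order_parameter_sch(eq, topo),
        "neg_scd_proximal": mx.order_parameter_sch(eq, topo, LEAFLET_PROXIMAL),
        "neg_scd_distal": mx.order_parameter_sch(eq, topo, LEAFLET_DISTAL),
    }
    return EquilibratedMembrane(frame=eq, topology=topo, forcefield=ff,
                                seed=seed,
                                reference_thickness=float(np.mean(thick)),
                                equilibrium_summary=summary)


def _series_min(series: mx.MetricSeries, window: float = 0.25):
    sm = mx.moving_average(series, window) if len(series.times) > 2 else series
    vals = sm.smoothed if sm.smoothed is not None else sm.values
    k = int(np.argmin(vals))
    return float(vals[k]), float(sm.times[k] - sm.times[0])


def run_condition(membrane: EquilibratedMembrane, spec: ShockSpec,
                  plan: ExperimentPlan, run_id: str) -> RunRecord:
    rec = RunRecord(run_id=run_id, spec_config=spec.to_config(),
                    seed=membrane.seed)
    try:
        res = run_nve_shock(membrane.frame, membrane.topology,
                            membrane.forcefield, spec,
                            sample_interval=plan.sample_interval_ps)
        topo, ff = membrane.topology, membrane.forcefield
        ts = mx.thickness_series(res.frames, topo)
        po = mx.order_series(res.frames, topo, LEAFLET_PROXIMAL)
        do = mx.order_series(res.frames, topo, LEAFLET_DISTAL)
        ps = mx.pressure_series(res.frames, topo, ff)
        ps_smooth = mx.moving_average(ps, 0.25) if len(ps.times) > 2 else ps
        profiles = [mx.local_pressure_profile(f, topo, ff, 5.0)
                    for f in res.frames]
        href = membrane.reference_thickness
        rec.reference_thickness_A = href
        rec.eps_max = mx.max_compressive_strain(ts, href)
        rec.min_thickness_A = float(np.min(ts.values))
        rec.final_thickness_A = float(ts.values[-1])
        rec.energy_drift = res.energy_drift
        rec.slab_mass_amu = res.slab_mass
        try:
            fit = mx.shock_speed(profiles)
            rec.shock_speed_km_s = fit.speed_km_s
            rec.shock_speed_r2 = fit.r_squared
        except mx.MetricError:
            pass
        rec.scd_min_proximal, rec.scd_min_time_proximal_ps = _series_min(po)
        rec.scd_min_distal, rec.scd_min_time_distal_ps = _series_min(do)
        rec.scd_response_time_proximal_ps = mx.response_time(po, drop=0.02)
        rec.scd_response_time_distal_ps = mx.response_time(do, drop=0.02)

        outdir = Path(plan.outdir) / "runs"
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for series, leaflet in ((ts, ""), (ps, ""), (po, "proximal"),
                                (do, "distal")):
            for t, v in zip(series.times, series.values):
                rows.append((t, series.name, v, leaflet, run_id))
        for t, v in zip(ps_smooth.times,
                        ps_smooth.smoothed if ps_smooth.smoothed is not None
                        else ps_smooth.values):
            rows.append((t, "pressure_GPa_smoothed", v, "", run_id))
        for p in profiles:
            zpk = mx._refine_peak(p.bin_centers, p.pressure)
            rows.append((p.time, "pressure_peak_z_A", zpk, "", run_id))
        df = pd.DataFrame(rows, columns=["time_ps", "metric", "value",
                                         "leaflet", "run_id"])
        path = outdir / f"{run_id}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        rec.metrics_csv = str(path)
    except Exception as exc:   # noqa: BLE001 - per-run failures are recorded
        rec.ok = False
        rec.error = f"{type(exc).__name__}: {exc}"
    return rec


def run_plan(plan: ExperimentPlan, master_seed: int = 0,
             workers: int = 1) -> List[RunRecord]:
    """Execute every condition x seed of the plan (serially; ``workers`` is
    accepted for interface compatibility, outputs are identical for any
    value).  Raises nothing per-run: failures are recorded in the records.
    """
    Path(plan.outdir).mkdir(parents=True, exist_ok=True)
    plan.echo().to_csv(Path(plan.outdir) / "conditions.csv", index=False,
                       float_format="%.10g")
    membranes = {}
    records = []
    for seed in plan.seeds:
        membranes[seed] = prepare_membrane(plan, seed, master_seed)
    eq_summary = {str(s): m.equilibrium_summary for s, m in membranes.items()}
    with open(Path(plan.outdir) / "equilibrium_summary.json", "w") as fh:
        json.dump(eq_summary, fh, indent=1, sort_keys=True)
    for spec in plan.conditions():
        for seed in plan.seeds:
            run_id = (f"{plan.experiment}_I{spec.impulse_mPa_s:g}"
                      f"_Lw{spec.slab_thickness_A:g}"
                      f"_gap{spec.gap_A:g}_s{seed}")
            records.append(run_condition(membranes[seed], spec, plan, run_id))
    with open(Path(plan.outdir) / "run_records.json", "w") as fh:
        json.dump([_record_json(r) for r in records], fh, indent=1,
                  sort_keys=True)
    return records


def _record_json(rec: RunRecord) -> dict:
    d = asdict(rec)
    for k, v in d.items():
        if isinstance(v, float) and np.isnan(v):
            d[k] = None
    return d


def report(records: Sequence[RunRecord], outdir: str,
           make_plots: bool = True) -> dict:
    """Summary tables (eps_max vs gap / vs t_p per impulse) and figures."""
    if not any(r.ok for r in records):
        raise ValueError("no successful run records to report on")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        c = r.spec_config
        rows.append({
            "run_id": r.run_id, "ok": r.ok, "error": r.error,
            "impulse_mPa_s": c["impulse_mPa_s"],
            "L_w_A": c["slab_thickness_A"], "gap_A": c["gap_A"],
            "t_p_ps": c["derived"]["pulse_duration_ps"],
            "P_n_GPa": c["derived"]["peak_pressure_GPa"],
            "gamma_per_ps": c["derived"]["loading_rate_per_ps"],
            "seed": r.seed, "eps_max": r.eps_max,
            "shock_speed_km_s": r.shock_speed_km_s,
            "energy_drift": r.energy_drift,
            "scd_min_time_proximal_ps": r.scd_min_time_proximal_ps,
            "scd_min_time_distal_ps": r.scd_min_time_distal_ps,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "run_summary.csv", index=False, float_format="%.10g")
    ok = df[df["ok"]]
    eps_vs_gap = (ok.groupby(["impulse_mPa_s", "L_w_A", "gap_A"])["eps_max"]
                  .agg(["mean", "std", "count"]).reset_index())
    eps_vs_gap.to_csv(out / "eps_max_vs_gap.csv", index=False,
                      float_format="%.10g")
    eps_vs_tp = (ok.groupby(["impulse_mPa_s", "t_p_ps", "L_w_A", "P_n_GPa"])
                 ["eps_max"].agg(["mean", "std", "count"]).reset_index())
    eps_vs_tp.to_csv(out / "eps_max_vs_pulse_duration.csv", index=False,
                     float_format="%.10g")
    summary = {
        "n_runs": int(len(df)), "n_failed": int((~df["ok"]).sum()),
        "failed_runs": df.loc[~df["ok"], "run_id"].tolist(),
    }
    if make_plots:
        _plots(records, out)
    with open(out / "report_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _plots(records: Sequence[RunRecord], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for r in records:
        if not r.ok or not r.metrics_csv or not os.path.exists(r.metrics_csv):
            continue
        df = pd.read_csv(r.metrics_csv)
        fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
        th = df[df.metric == "thickness_A"]
        axes[0].plot(th.time_ps, th.value)
        axes[0].set_ylabel("thickness (A)")
        pr = df[df.metric == "pressure_GPa_smoothed"]
        axes[1].plot(pr.time_ps, pr.value)
        axes[1].set_ylabel("box pressure (GPa)")
        for leaf in ("proximal", "distal"):
            oc = df[(df.metric.str.startswith("neg_scd")) & (df.leaflet == leaf)]
            axes[2].plot(oc.time_ps, oc.value, label=leaf)
        axes[2].set_ylabel("-S_CD")
        axes[2].set_xlabel("time (ps)")
        axes[2].legend()
        fig.suptitle(r.run_id)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{r.run_id}.png", dpi=110)
        plt.close(fig)
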