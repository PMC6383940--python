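# Methods

## The shock prescription

A planar shock pulse is injected into an equilibrated membrane + solvent
system by a momentum impulse: every solvent molecule whose centre of mass
lies in a slab of thickness L_w adjacent to the membrane receives a uniform
increment Δv_z to its z-velocity.  The prescription is parameterised by the
pressure impulse Î (the time integral of pressure over the pulse, equal to
the momentum delivered per unit area — units Pa·s, typically quoted in
mPa·s = 10⁻³ N·m⁻²·s), the slab thickness L_w, and the water density ρ:

    Δv_z = Î / (ρ L_w)            added velocity
    t_p  = L_w / Δv_z             nominal pulse duration
    P_n  = ρ Δv_z²                nominal peak pressure
    γ    = 1 / t_p                loading rate

so that P_n·t_p = Î identically.  These are *nominal* square-wave
quantities: the injected slab steepens into a triangular front within a
fraction of a picosecond, so P_n is an order-of-magnitude estimate and t_p
the slab passing time.  At Î = 1 mPa·s, L_w ∈ {5…30} Å spans
t_p = 0.25–9 ps and P_n = 4–0.11 GPa; at 10 mPa·s, t_p = 0.025–0.9 ps and
P_n = 400–11 GPa.

Design choices the prescription leaves open, and how this package fixes
them:

* **ρ is a user-supplied constant**, default 1000 kg/m³ (bulk water), not
  the instantaneous slab density.  The instantaneous slab mass is reported
  with every run so the discrepancy is visible; with it, the exact injected
  momentum is Σᵢ mᵢ Δv_z.
* **Slab membership is by molecule centre of mass** in the half-open
  interval [z₀, z₀+L_w), so whole molecules are always kicked (no energy
  into intramolecular bonds) and adjacent slabs partition space.
* **The gap** is measured from the slab's membrane-proximal face to the
  proximal head-group *density peak* — the prescription's reference surface
  is otherwise ambiguous.  This is configurable.
* **Net momentum is zeroed immediately before injection**, so the imparted
  momentum is unambiguous against thermostat-era drift.
* Shock runs are NVE (velocity Verlet) and terminate at t_end = L_z/v_est,
  where v_est is a configured wave-speed estimate, so no reflected wave
  re-enters the frame.  Default v_est = max(20, 1.1·Δv_z) Å/ps, chosen from
  front speeds measured in this model by pressure-peak tracking (a ~17 Å/ps
  sonic floor for weak pulses; ballistic ≈ Δv_z for strong ones); the
  slight overshoot guarantees termination before one box traversal while
  leaving post-transit time to observe membrane recovery.  The actual speed
  is always re-estimated post hoc from the local-pressure profiles.

## The coarse-grained stand-in

The simulator is a bead–spring, explicit-solvent coarse-grained model, not
a chemically mapped force field.  It exists to exercise the shock protocol
and the analysis suite end-to-end at desk scale and to reproduce the
*qualitative* membrane phenomenology: an equilibrated bilayer with a
well-defined thickness and order parameter; compression during shock
transit and subsequent recovery; a stronger response at higher impulse;
the shock-facing (proximal) leaflet responding before the distal one; and
a propagating triangular pressure front.

**Geometry.**  Two leaflets of n/2 lipids on a near-square lateral lattice
(7.5 Å spacing ⇒ 56.25 Å² per lipid), bilayer normal along z.  The default
emulated composition is 90% phospholipid-like, 10% cholesterol-like
lipids.  Solvent fills an asymmetric column: a long +z pad (default 200 Å,
100 Å in the CI preset) for the wave to run into and a short −z pad (30 Å)
hosting the shock slab.

**Beads and bonded terms.**  Every bead carries 72 amu (≈ 4 waters, or one
chain segment).  The phospholipid-like species is double-chained — one
head bead with two 4-bead tails — because a single-chain lipid cannot fill
its lattice-cell volume and the bilayer collapses (thickness = lipid
volume / area is a hard geometric constraint at fixed box).  The
cholesterol-like species is a shorter, 3× stiffer single chain (H–T–T–T,
4.5 Å bonds).  Bonds are harmonic (default 20 kT/Å²); chain straightness
comes from 1–3 next-nearest-neighbour springs (default 15 kT/Å²) rather
than three-body angle potentials, so that *every* interaction is a central
pair force — Newton's third law, the scalar virial and the Irving–Kirkwood
local-pressure apportionment are then exact by construction.

**Nonbonded terms.**  DPD-style soft repulsion U = A_ij(1−r/r_c)² with
r_c = 7.5 Å and role-pair amplitudes (in kT at 310 K): solvent–solvent,
head–head, head–solvent and tail–tail 12.5; head–tail 25; solvent–tail 40
(the hydrophobic contrast that segregates the bilayer).  Tail–tail beads
additionally attract with a smooth well of depth 1.5 kT (flat inside
4.5 Å, cos²-tapered to zero at r_c); this cohesion is what lets the
bilayer re-form after a strong shock.  The 1.5 kT default was chosen, once,
as the value at which the bilayer both holds a stable thickness plateau
(≈ 27 ± 1 Å at 310 K) and survives the 10 mPa·s/L_w = 30 Å condition;
weaker cohesion (1.0 kT) gives a thicker (~34 Å) but more fragile
membrane.

**Integration.**  Equilibration: velocity Verlet with a BAOAB-split
Langevin thermostat (friction 1 ps⁻¹), fixed box.  There is no barostat —
the builder places the system at its target density, and the kinetic
temperature settles within 5% of target in a few ps.  Shock runs: plain
velocity Verlet, timestep min(0.005 ps, 0.3 Å / v_max) so the fastest
bead moves a bounded fraction of the core radius per step; NVE drift is
~10⁻⁶–10⁻⁵ relative over a run and tested to converge as O(dt²).
Internal units are Å, ps, amu (k_B = 0.83145 amu·Å²·ps⁻²·K⁻¹); a single
conversion table (`memshock.units`) maps to SI; all public reports are SI.

**Neighbour handling.**  Linked-cell lists when every box dimension holds
≥ 3 cells, otherwise an all-pairs kernel; an independent pure-numpy
O(N²) oracle is kept for tests.  Correctness, not speed, is the contract;
serial kernels keep runs bit-reproducible.

**Seed policy.**  One integer master seed; build seeds, thermostat streams
and replicate seeds derive from it via `numpy.random.SeedSequence`.
Re-running any preset with the same master seed reproduces every metric
CSV bit-for-bit.

## Analysis definitions

* **Thickness**: distance between the two head-bead density peaks along z
  (1 Å histogram, 3-point parabolic sub-bin refinement, leaflets split at
  the head z-median so the measure survives whole-membrane drift).
* **Maximal compressive strain** ε_max = max_t (h_ref − h(t))/h_ref with
  h_ref the pre-shock equilibrium thickness (mean over the last quarter of
  equilibration samples).
* **Order parameter**: the operator computes −⟨(3cos²θ − 1)/2⟩ over
  director pairs supplied by the topology, θ measured to the membrane
  normal; with all-atom C–H directors this is the standard −S_CD
  (range [−1, ½]).  The CG model has no hydrogens; its directors are
  consecutive tail-bead bonds, and the reported −S_CD uses the
  axial-symmetry identity S_CH = −S_chain/2 (methylene C–H bonds are
  distributed uniformly about the chain axis), i.e. −S_CD =
  ⟨P₂(cos θ_chain)⟩/2, which keeps the conventional scale (max ½,
  equilibrium ≈ 0.17 here).  During shock runs the *instantaneous*
  (single-frame) value is used — the response develops over picoseconds,
  so long-time averages would wash it out; equilibrium reports use time
  averages.
* **Response onset**: the first time the 0.25 ps-smoothed per-leaflet
  −S_CD falls 0.02 below its starting value.  This is the timing statistic
  used for the proximal-vs-distal comparison; the global minimum and its
  time are recorded too, but at desk scale slow NVE heating (below) often
  places the literal minimum at the end of the record for both leaflets,
  making it uninformative about transit order.
* **Pressure**: global virial pressure P = (2KE/3 + Σ r·f/3)/V in GPa,
  positive = compression.  The local profile assigns kinetic terms to the
  particle's 5 Å z-bin and apportions each pair's virial over bins by
  fractional segment overlap; the volume-weighted bin average equals the
  global pressure to 1e−6 relative (tested).  Because a mean-box pressure
  during non-equilibrium flow conflates bulk-flow kinetic energy with
  thermal pressure, a streaming-corrected variant (per-bin mass-weighted
  streaming velocity subtracted) is also available; both are computed,
  the raw variant is what the history plots show.
* **Moving average**: centred boxcar over samples within ± window/2
  (default 0.25 ps); edges use the truncated window, no padding.
* **Shock speed**: parabolic-refined z of the maximum-pressure bin,
  tracked over frames; least-squares slope of z_peak(t) with R² reported,
  falling back to a Theil–Sen median-of-slopes fit (with a warning) when
  the track is not monotonic — which is the norm for the weak 1 mPa·s
  pulse, whose peak barely exceeds thermal pressure fluctuations at this
  system size.

## What the desk-scale stand-in does and does not show

The CI preset (72 lipids, ~2800 beads, 100/30 Å pads, 50 ps equilibration,
L_w = 30 Å shocks at 1 and 10 mPa·s × 3 membrane replicates) runs in a few
minutes on one CPU.  Two systematic desk-scale effects must be kept in
mind when reading its numbers:

1. **NVE heating.**  The injected energy ½·M_slab·Δv_z² is shared among
   ~10² fewer degrees of freedom per unit membrane area than in a
   million-particle atomistic system, so the post-shock system runs hot
   and the membrane slowly thins toward a hotter-state equilibrium after
   the transit dip.  ε_max at 1 mPa·s therefore contains a drift component
   (≈ 10%) on top of the ~5% transit dip, recovery after strong shocks is
   partial within the run window (run-end thickness is typically 60–100%
   of pre-shock), and comparisons across impulses are made at matched run
   protocol.  The acceptance band for recovery — a rebound of ≥ 0.3 Å off
   the minimum and a run-end thickness ≥ 45% of pre-shock — states exactly
   this.
2. **Soft-core ballistic limit.**  A DPD-style soft fluid cannot transmit
   piston speeds much above ~40 Å/ps: the pair repulsion barrier (≈ 12.5–40
   kT) is small against the kinetic energy of a 50+ Å/ps bead, so thin
   slabs at 10 mPa·s (Δv_z = 50–200 Å/ps) traverse the solvent and the
   membrane quasi-ballistically, depositing little coherent compression.
   The matched-impulse comparisons are therefore exercised at L_w = 30 Å
   (Δv_z = 3.3 vs 33 Å/ps), the regime the model transmits cleanly.  The
   full-size preset still enumerates all slab thicknesses; its thin-slab
   strong-impulse rows probe the model's ballistic regime, not the
   atomistic physics.

Within that envelope the stand-in reproduces the reference phenomenology:
equilibrium plateau (27 ± 1 Å, −S_CD ≈ 0.18, 56 Å²/lipid), a ~5% transit
dip (plus heating drift) at 1 mPa·s vs ~30–60% at 10 mPa·s with recovery,
proximal-before-distal leaflet response (onsets ≈ 0.45 vs 0.6–0.9 ps at
10 mPa·s), a triangular pressure front whose peak advances monotonically
at ≈ 1.8 km/s (10 mPa·s) vs ≈ 0.7–0.9 km/s tracked for the weak pulse,
and front-local pressures of the same order as P_n.  What it cannot show:
absolute atomistic numbers (40.24 Å thickness, 63.93 Å² per
phospholipid, 3 and 8 km/s TIP3P shock speeds, the ε_max optimum at
t_p = 0.225 ps), chemistry-specific ordering (per-carbon S_CD), pore
formation, or permeation — all outside this model's resolution or scope.

## Known limitations

* No barostat: equilibration is NVT at the build density; membrane
  tension is set implicitly by the lattice area per lipid.
* No reflected-wave handling and no oblique incidence: runs end before
  one box traversal, normal incidence only.
* GRO/XYZ interchange quantises (0.01 Å positions in GRO); the internal
  .npz container keeps full precision and is what the metrics read.
* The thermostat acts on all beads during equilibration (no
  profile-unbiased thermostatting); irrelevant for the NVE shock phase.
* `run_plan` executes conditions serially; the `workers` argument is
  accepted for interface stability but does not parallelise.
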