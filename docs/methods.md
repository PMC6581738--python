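# Methods

## The two-cell model

Two identical endothelial cells are coupled by juxtacrine DLL4–Notch
signalling and driven by independent external VEGF inputs `V_A`, `V_B`
(dimensionless concentration units, "c.u."; time in model units).  Eight
species per cell evolve by mass action:

| species | meaning |
|---|---|
| `R_free`, `VR` | free receptor and VEGF–receptor complex; `R_free + VR = receptor_total` is conserved (no receptor synthesis or turnover) |
| `DLL4` | Notch ligand, produced from `VR` |
| `Notch_free`, `DN` | free Notch and the trans-complex with the *neighbour's* DLL4 |
| `NICD` | cleaved Notch intracellular domain |
| `HE` | consolidated HES/HEY/HER repressor induced by NICD |
| `P` | VEGF-induced positive-feedback factor |

The feedback law is `V_eff = V * (1 + k6 * P^n)` with `n = 2` (presumed
cooperativity of at least two feedback pathways).  `P` is produced at rate
`fb_prod * VR`, so `fb_prod` is the sweepable "feedback level" knob of all
one- and two-parameter analyses; `fb_prod = 0` or `k6 = 0` recovers the
feedback-free model exactly, which a test verifies against an
independently written feedback-free implementation to 1e-8.

Two closure choices were genuinely open and are worth stating:

- **Notch bookkeeping.**  Irreversible NICD cleavage consumes the
  trans-complex.  If nothing replenished Notch, the only equilibrium would
  be Notch-free and lateral inhibition would vanish at steady state.  We
  recycle the receptor stub on cleavage (`DN -> NICD + Notch_free`), which
  conserves the per-cell Notch pool exactly like the receptor pool and
  keeps the model free of basal production terms (the all-zero state has
  identically zero rates).  The alternative — basal Notch synthesis and
  turnover — adds two constants without changing any regime studied here.
- **Repression site and cooperativity.**  HE attenuates the cell's VEGFR
  pathway output through `sigma(HE) = 1 / (1 + (repress_gain * HE)^m)`.
  By default sigma multiplies DLL4 production ("activity" repression); a
  config flag (`repress_site: binding`) moves it onto the receptor
  binding rate instead.  The exponent `m = repress_exp = 2` is required:
  with `m = 1` the mutual-repression map `D_i = A / (1 + g*HE(D_j))` has
  slope magnitude `x/(1+x) < 1` at any fixed point, so the symmetric state
  can never destabilise and no parameter choice patterns.  Hill-2 is the
  minimal cooperativity that supports lateral inhibition, consistent with
  how juxtacrine patterning models are normally closed.

### Reference calibration

All rates default to order-1 dimensionless values.  Exactly two constants
were calibrated, once, against the printed model-scale anchors, and are
frozen in the shipped configs (`scripts/calibrate_reference.py` re-derives
them):

- **Bifurcation config** (`configs/bifurcation.yaml`).  Because repression
  acts downstream of the receptor, the per-cell `(VR, P)` subsystem is
  autonomous; with `x = VR/receptor_total` its equilibria satisfy
  `V(x) = s*x / ((1-x)(1 + a*x^2))`, `s = vegf_bind_off/vegf_bind_on`,
  `a = k6*(fb_prod/deg_p)^2`.  Solving for the saddle-node folds at
  V = 2.49 and 0.98 gives `k6 = 361.499126`, `vegf_bind_off = 89.558378`
  (at `fb_prod = 1`), so the 0.05-step quasi-static sweep detects
  switch-on at 2.50 and switch-off at 1.00.  `dll4_prod = 1.5` keeps the
  winning cell's DLL4 above the tip threshold along the whole upper branch
  down to the fold, so threshold detection and the fold coincide.
  The three feedback regimes are `fb_prod = 0` (monostable low on the
  whole sweep), `1` (bistable window) and `100` (folds below the sweep
  grid: operationally monostable active).  The feedback axis is in the
  model's own units; only the regime structure, not the numeric label of
  the high regime, is meaningful.
- **Matrix config** (`configs/matrix.yaml`).  Same parameters except
  `vegf_bind_off = 0.0818`, bisected once so that without feedback the
  most easily-resolving pair of a low-VEGF square (one cell at V, the
  other at the 0.005 grid floor) first patterns at V ≈ 0.049 c.u., the
  geometric midpoint of the two log-grid values bracketing 0.05 c.u.
  The two configs are two independently calibrated VEGF scales (the
  bistability analyses run on a 0–4 axis, the patterning matrices on a
  0.005–0.1 c.u. axis); they are deliberately not interconverted.

### Numerics

Stiff integration uses LSODA at rtol 1e-8 / atol 1e-10; solver failure
raises with diagnostics rather than returning NaNs.  Equilibration is
declared when every |rate| falls below 1e-7 across a trailing 10-time-unit
window.  Trajectory values are kept as the solver produced them (tiny
negative undershoots possible within tolerance) and clipped to zero only
at write-out.  Equal-input patterning requires symmetry breaking: a
deterministic nudge of `1e-4 * receptor_total` on cell A's free receptor
is applied at the start of every simulation and re-applied at every
quasi-static sweep step (on the invariant symmetric manifold the
deterministic ODE could never pattern).  Outcome classification: a cell is
*tip* (resp. *inhibited*) if its DLL4 stays at/above the tip threshold
(at/below the inhibited threshold) continuously through the end of the
run for at least `hold_time = 10`; a pair is resolved only as a
complementary tip/inhibited pair, and the patterning time is the earliest
time from which both conditions hold.  Thresholds are 0.3 / 0.1 c.u. in
both configs.

Steady-state search runs multi-start (default 12 starts: 5 deterministic
anchors plus seeded random points) damped root finding in reduced
coordinates that eliminate the two conserved pools per cell, so the
stability Jacobian (central differences, relative step 1e-6) has no
structural zero modes.  Solutions are kept when the residual < 1e-8,
deduplicated at 1e-6 L-infinity, and verified by a 1-time-unit
re-integration staying within 1e-6.  The cusp map counts *distinct stable
activation levels* (winning-cell VR, merged at 0.01·receptor_total), so
the tip/stalk relabelling of the same activation branch is not counted as
extra multistability; bistable means two levels (inactive + active).
Continuation is quasi-static sweeping plus multi-start root finding —
fold points are located at grid resolution, which is also how the switch
thresholds are reported; no pseudo-arclength machinery.

The patterning horizon (500 time units, with a warning below 10
characteristic times) is a package choice: the slowest resolving pairs
near the failure boundary pattern within ~250 time units, so the horizon
is not the binding constraint except exactly at the boundary, where
"unresolved at horizon" is the intended failure flag.

## Lattice selection competition

The memAgent selection competition is re-implemented on a fixed geometry:
8 cells in a row, each `cell_span x nz = 4 x 2 = 8` surface memAgents, a
static VEGF field above the row increasing along y, and no mechanics
(springs, filopodia, migration, shape change and proliferation are out of
scope; the object of study is selection counts and timing only).  Receptor
activation per memAgent is linear in its receptor level against the
sink-depleted neighbourhood VEGF, `max(0, E - Vsink*sink_unit/26)` per
site — the sink (Flt1 mimic, normally 9) enters subtractively, so
activation strictly decreases as the sink rises; this directionality is
the normative content of the activation law, and the printed multiplicative
placement of the sink term is not used because it would inverse it.
Dll4 induction from summed activation is Hill-2 saturating (linear
induction leaves the inhibited cells' residual Dll4 strong enough to pull
tips back below threshold — no stable pattern).  Notch inhibition
downregulates the *baseline* receptor level of the two row neighbours with
a one-step delay (gene-expression lag) and relaxation fraction 0.12 per
step; the neighbour term is the mean (not sum) of adjacent Dll4 so that a
uniform state is an exact invariant of the update map and symmetric inputs
stalemate rather than being resolved by the row ends.  A cell is a *tip*
while its summed activation exceeds 0.14; a cell is *selected* in a
replicate if it held tip state for 10 consecutive steps ending inside the
early window, timesteps 20–60 — the first interval in which control tip
counts plateau under the defaults.  Ensembles are 100 replicates x up to
200 steps with per-cell ±5% seeded jitter on the baseline receptor level;
identical master seeds reproduce ensembles bit for bit.  Conditions:
control (field amplitude 0.04, Vsink 9), VEGF-inhibited (amplitude 0.038),
flt1 knockdown (Vsink 8).  Because the sink nearly cancels the control
field at the cell-adjacent sites, the 5% field reduction translates into a
~35% drop in available VEGF — the thresholding that makes selection
counts sensitive to modest VEGF perturbations.

## Synthetic cohorts

The generator emulates the structure, not the biology, of the imaging
measurements: selection events are a homogeneous Poisson process
(`rate = 0.4` events/vessel/hour from 19 hpf) truncated at a closure time
(`window_close = 25` hpf; `None` emulates loss of Notch-dependent closure,
where selection continues across the span), so the control mean by 24 hpf
is `0.4 * 5 = 2` selections per vessel.  Proliferation is one Bernoulli
draw per selected EC (p = 0.3; elevated to 0.6 in the closure-less
variant as a flag, not a mechanism).  Nuclei tracks are constant-speed
dorsal motion (10 um/h) on top of a shared random-walk embryo drift
(3 um/step at the 0.3 h imaging interval) plus i.i.d. Gaussian noise
(0.5 um); the dorsal-aorta reference track carries the same drift, and
track normalisation subtracts it per timepoint.  Per-genotype effect
sizes are figure-borne in vivo, so the multipliers encode direction only
(flt1 loss 1.5x, VEGFR inhibition 0.5x, feedback-mutant 0.6x).  What
passing tests show is therefore that the *quantifiers* are correct and the
generator is self-consistent (rate and closure time are recovered within
5% / one sampling interval at n = 2000); they show nothing about real
selection kinetics beyond the calibrated 2-by-24-hpf anchor.  Vessels with
zero selections are excluded from cellularity scoring (no vessel forms).
Mean ± SEM is the only summary statistic; hypothesis testing is out of
scope.

The robustness protocol equilibrates the two-cell model in the active
state at a reference VEGF (3.0, bifurcation config), scales the receptor
binding rate by (1 − inhibition) per level, and re-equilibrates from the
active baseline.  With feedback the output stays near baseline until the
effective input leaves the bistable window (collapse at inhibition 0.70,
i.e. effective VEGF 0.90 ≈ the 0.98 lower fold, at the protocol's 0.05
level resolution); without feedback the output declines gradedly from the
first level.  The transcript candidate filter is a pure row predicate at
the printed cut-offs and runs on synthetic toy tables; reproducing the
in-vivo candidate count would require the deposited microarray data and is
out of scope.

## Known limitations

- The two-cell reaction scheme is a minimal reconstruction of the
  signalling wiring, not a transcription of any published rate list; all
  claims tested are about regime structure (monostable/bistable,
  feedback-only patterning, orderings), which is insensitive to the
  closure details above.
- The cusp is mapped at grid resolution; fold positions between grid
  points are not interpolated.
- The lattice model has fixed geometry and no mechanics; its selected
  counts are not comparable quantitatively to the original
  membrane-agent/spring implementation, only in condition ordering and
  the existence of an early discriminating window.
- Synthetic cohorts use the simplest standard distributions (Poisson,
  Bernoulli, Gaussian/lognormal); each distribution is a named, swappable
  component but no alternative is shipped.
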