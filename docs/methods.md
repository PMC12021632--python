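# Methods

`pleurasim` is a lumped-parameter virtual patient built to study how a large
unilateral pleural effusion deforms the respiratory pump — hemidiaphragms,
mediastinum, rib cage — and what pleural manometry, spirometry and blood
gases can (and cannot) reveal during stepwise therapeutic thoracentesis.
This note describes the model, its assumptions, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## 1. Mechanical model

### Geometry and state

Each lung is divided into `n_layers` horizontal layers (default 100) inside a
vertical prismatic hemithorax of capacity 3.5 L and height 24 cm (uniform
cross-section).  Pleural fluid of volume `V_pf` pools at the bottom of the
ipsilateral hemithorax; its surface height is `V_pf / area` and the local
pleural pressure of a submerged layer exceeds the apex pressure by the
hydrostatic column `rho_f * g * depth` (0.0981 kPa per cm of water).  The
fluid-free hemithorax carries no gravitational pleural gradient by default.

The dynamic state is the per-layer gas volumes plus the two hemidiaphragm
displacement volumes `x_di` (positive caudal).  Two volume-compatibility
constraints — the contents of each hemithorax (lung gas + fluid) must equal
the volume enclosed by its share of the rib cage, its hemidiaphragm and the
mediastinal membrane — determine rib-cage volume and mediastinal displacement
algebraically.  At every right-hand-side evaluation the two apex pleural
pressures are obtained from a 2x2 linear solve of

* the rib-cage Kelvin–Voigt balance
  `(P_pl_ipsi + P_pl_contra)/2 + P_mus_rc = V_rc/C_rc + R_rc dV_rc/dt`, and
* the mediastinal elastic balance `P_pl_ipsi − P_pl_contra = V_med / C_med`.

Because the pressures come from algebraic elimination rather than a penalty,
flow continuity at the carina and the mediastinal pressure–volume relation
hold to machine precision at every accepted step.

### Constitutive laws

* **Lung layers**: exponential recoil `P_el = −(1/k) ln(1 − V/Vmax)`,
  concave and stiffening toward `Vmax`.  Defaults `Vmax = 1.8 L` per lung and
  `k = 2.1972 kPa⁻¹` place relaxed FRC at 1.2 L per lung for a relaxed
  pleural pressure of −0.5 kPa.  The low ceiling matters: when one lung is
  collapsed, the ventilated lung must run up the stiff part of this curve to
  preserve tidal volume, which is what elevates the pre-drainage pleural
  pressure amplitude (Section 4).
* **Airways**: mouth → trachea (`R_tr`) → main bronchi (`R_mb`) → per-layer
  peripheral branch.  Each branch combines a collapsible airway,
  `R = R0 (1 + beta * max(0, 1 − V/V_half))` — caliber falls with layer
  volume, the volume-domain equivalent of transmural compression — and a
  viscous parenchymal resistance in series.  Closed layers carry no flow.
* **Rib cage and abdomen**: Kelvin–Voigt elements.  The abdominal dashpot
  acts on hemidiaphragm displacement rate (the diaphragm is what displaces
  abdominal content); abdominal elasticity couples the two hemidiaphragms
  through a common abdominal pressure.
* **Mediastinum**: purely elastic, compliance `C_med` (default 0.5 L/kPa).
  The presets `stiff_mediastinum` and `compliant_mediastinum` divide and
  multiply `C_med` by 5.

### Recruitment and derecruitment

Every layer carries a hysteresis flag.  An open layer's gating pressure is
its alveolar-minus-local-pleural pressure (elastic recoil plus the viscous
parenchymal drop); it closes below `P_close` (default 0 kPa: collapse when
alveolar pressure falls below the surrounding pleural pressure).  A closed
layer seals its gas (volume frozen, "trapped") and gates on the pressure
available at the collapsed airway entrance — upstream main-bronchus pressure
minus local pleural pressure; it reopens above `P_open` (default 0.3 kPa,
the offset preventing open/close chatter).  A layer squeezed to (near) zero
gas closes unconditionally.  The flag update is the classic scalar
hysteresis automaton and is unit-tested as such.

### Respiratory muscles

One neural drive feeds rib-cage muscles (fraction `rc_share = 0.22`) and
both hemidiaphragms.  The waveform rises parabolically to its peak at
end-inspiration (`Ti/T = 0.4`) and releases exponentially afterwards
(post-inspiratory braking, time constant `0.1 T`).  A half-sinusoid profile
was tried first and rejected: its active pressure is zero at the volume
peak, which makes the end-inspiratory pleural pressure of an inverted
hemidiaphragm indistinguishable from the end-expiratory one and structurally
suppresses the left-leaning loop.

Each hemidiaphragm multiplies the drive by a signed mechanical-advantage
factor `psi(x) = phi(x) * dir(x)`:

* `phi` is the force–length factor: 1 at (or beyond) the side's relaxed
  baseline displacement, falling linearly over `di_phi_span = 2.0 L` of
  caudal displacement, floored at `di_phi_floor = 0.12`.  A hemidiaphragm
  stretched by the effusion (contralateral) is strong; a deeply displaced
  (inverted) one starts weak and regains force as its dome rises — the
  within-breath positive feedback that concentrates the paradoxical squeeze
  in late inspiration.
* `dir = tanh((x_inv − x)/w)` flips the volume effect of contraction once
  the dome is inverted (`x_inv = 0.3 L`, width 0.1 L): contraction of an
  inverted dome lifts it cephalad and **raises** ipsilateral pleural
  pressure during inspiration.

A deterministic controller scales the drive amplitude until tidal volume is
within 2% of `VT_target` (the respiratory centre holds ventilation), with
warm starts across thoracentesis aliquots.

### Calibration

The physiological anchors this calibration reproduces: a 3 L effusion leaves a
small apical part of the ipsilateral lung aerated while its dependent layers
are collapsed and the hemidiaphragm is deeply inverted; a stiff mediastinum
yields a left-leaning, self-intersecting (figure-eight) loop with pendelluft
confined to end-inspiration/beginning-of-expiration; a compliant mediastinum
yields a right-leaning simple loop; and under a compliant mediastinum the
pleural amplitude is elevated before drainage, falls over the early aliquots
and rises again once recruitment completes.  The resulting defaults
(`C_rc = 2`, `C_ab = 4`, `C_di = 1.5` L/kPa, `R_ab = 0.05`,
`R_tr = R_mb = 0.05`, `R_small = 0.06`, `R_par = 0.05` kPa s/L) are ordinary
adult-physiology magnitudes; every one is config-overridable, so calibration
is data, not code.

### Integration

Fixed-step RK4 at `dt = 2 ms` (bit-reproducible runs; all relevant time
constants are ≥ 30 ms, so the step is dominated by accuracy, not stability).
The recruitment automaton is applied before each step using the instantaneous
network solution.  Three wash-in breaths are discarded; recorded cycles must
be periodic (relative change of VT and FRC between the last two cycles below
0.5%, else an error naming the diagnostic).  Sign conventions: flow positive
into the patient, `V_med` positive toward the contralateral side, pleural
pressures reported at the lung apex; recordings also carry the tissue-mean
(volume-site-averaged) pleural pressure per side, which is what perfusion
responds to.

## 2. Gas exchange and circulation

Each lung is one well-mixed alveolar compartment (layers enter through their
summed open-layer ventilation and end-expiratory open volume; per-layer gas
would add cost without an observable, since airflow and alveolar gas are
reported per main bronchus).  Inspired gas is humidified:
`P_IO2 = FiO2 (P_atm − 6.27 kPa)`.  Anatomical dead space (0.15 L total) is
split between the lungs in proportion to inspired volume.

Perfusion: each layer's vascular conductance falls with its local pleural
pressure, `g = g0 / (1 + exp((P_pl − 0.5)/0.3))` (extramural compression);
cardiac output (5 L/min) is distributed over layers in proportion to
conductance, and the flow reaching closed layers is the shunt.  Flows sum to
cardiac output exactly.  A two-compartment (side-mean) variant of the same
law is provided for recordings without layer information.

Blood transport: Hill oxyhemoglobin curve (`P50 = 3.55 kPa`, `n = 2.7`,
Hb 14 g/dL, 1.34 mL O2/g, dissolved 0.003 mL/dL/mmHg) and a CO2 content
curve linearized around 40 mmHg (48 mL/dL, slope 3.5 mL/dL/kPa).  No
Bohr–Haldane interaction, no acid–base chemistry.

Steady state: a fixed point over the mixed-venous contents — per-lung gas
balances are solved against perfusion-weighted uptake with end-capillary
equilibration, arterial blood is mixed in *content* space (inverted back to
partial pressures numerically for O2, in closed form for CO2), and the Fick
principle closes the venous return with fixed tissue VO2/VCO2 (0.25 and
0.20 L/min).  A time-stepping `alveolar_step` is provided and converges to
the same fixed point (tested).  Mean alveolar O2 then sits ≈ 7–8 kPa below
dry atmospheric P_O2 at baseline — the fresh-gas dilution by FRC + dead
space, quantified by the ratio `VT/(FRC + VD)`.

The "atmospheric P_O2" reference in the baseline-offset number is the dry
value `FiO2 * P_atm`; the humidified inspired pressure is what the mass
balance itself uses.

## 3. Loop analysis

The P–V loop pairs ipsilateral pleural pressure with the cumulative
inhaled/exhaled volume of the whole respiratory system (trapezoidal flow
integral, re-zeroed at each breath onset to remove drift).  Breaths are
delimited at inspiratory-onset zero crossings of mouth flow with a ±2%
hysteresis band; a recording that starts inside the band counts its first
sample as an onset.  Phase labels follow the flow sign, so loop endpoints
sit at the volume extremes, as on a clinical loop display.

* **Lean**: `left` if P(end-inspiration) − P(end-expiration) > ε (functional
  hemidiaphragm inversion), `right` if < −ε, else `vertical`; ε defaults to
  0.05 kPa (configurable; no published value exists).
* **Figure-eight**: a proper self-intersection of the closed polyline,
  detected by a vectorized orientation test over all non-adjacent segment
  pairs (revisited vertices count, e.g. a curve sampled exactly at its
  node).  Degenerate (collinear) loops are rejected — note a symmetric
  figure-eight has zero *signed* area, so the shoelace sum is not a
  degeneracy test.  The implementation is cross-checked against shapely's
  `is_simple` on 1000 random closed curves.
* **Amplitude**: median across breaths of per-breath max − min pleural
  pressure (median for robustness to a single irregular breath).
* **Pendelluft**: fraction of samples where the two main-bronchial flows
  have opposite signs, both beyond a dead-band of 1% of the larger series'
  peak flow (a common band; a per-series band would count opposed
  sub-millilitre settling flows at end-expiration that no observer would
  call pendulum breathing).  A quadrant mask (early/late inspiration and
  expiration halves) localizes the events.
* **Two-stage trends**: ordinary least squares per withdrawal stage, split
  at 1.9 L withdrawn; a stage with fewer than two points yields NaN, not an
  exception.  Gas/vitals trends are regressed on time, amplitude on
  withdrawn volume (both offered).

For simulated breaths the loop of one representative steady-state cycle is
used; for recorded/synthetic sessions each interval's breaths are folded
into a pointwise-median cycle (noise shrinks ~ 1/sqrt(n_breaths)), lightly
smoothed, before morphology classification.

## 4. Thoracentesis sessions

`make_schedule` reproduces the clinical aliquot protocol (200 mL portions to
1 L, then 100 mL; final portion truncated).  After each aliquot the model is
re-equilibrated to a periodic breathing steady state before recording — the
clinical 1-minute pause idealized as "until periodic", which removes
arbitrary transients from the metrics.  "P_pl at FRC" is operationalized as
the end-expiratory pleural pressure at the catheter site — the lung base,
i.e. the apex pressure plus the remaining hydrostatic fluid column — which is
what intra-procedural manometry reads and why it falls steadily as fluid is
withdrawn even when the apex pressure barely moves.  Sessions are bit-deterministic
under the fixed-step solver.

Each aliquot is re-initialized from static equilibrium at the current fluid
volume (solved by continuation in `V_pf` with the recruitment pattern
iterated to a fixed point).  One consequence: recruitment along withdrawal
follows the static hysteresis path, so the open-layer count is non-decreasing
as fluid leaves.

Mechanism summary the sessions expose (each an emergent result, not a coded
rule): the stiff-mediastinum amplitude trace follows the loop rotation
left → vertical → right (smallest when vertical); the compliant-mediastinum
trace starts elevated (single-lung ventilation on the stiff part of the
recoil curve, transmitted through the compliant mediastinum), falls during
early recruitment and rises again toward full drainage; PaO2 responds
non-monotonically because fluid removal restores perfusion to still-collapsed
tissue (transient shunt) before recruitment catches up.

## 5. Synthetic recordings

`synthetic_signals` emulates the recording protocol only — 1-minute 25 Hz
intervals of pleural pressure and mouth flow between aliquots, plus
per-interval vitals — with a two-harmonic pressure parameterization: flow is
a pure sinusoid scaled to VT; `P_pl = mean + a sin(wt + phi) + b sin(2wt +
phi2) + noise`.  The fundamental's phase sets the lean (endpoint difference
`−2a sin(phi)`, a closed form used as ground truth), and a sufficient
second-harmonic weight bends the ellipse into a figure-eight.  Per-interval
means and amplitudes follow declared linear trajectories in withdrawn
volume, so trend-slope recovery can be checked against the declared slopes.
One RNG stream per session, keyed by the mandatory seed; equal specs give
byte-identical CSVs.

What it does **not** emulate: breath-to-breath variability in rate and
depth, baseline wander, swallowing/cough artifacts, sensor quantization, or
any mechanics (the parameterization is a signal-level stand-in, not a
physiological model).  Passing round-trip tests therefore demonstrates the
analyzer's correctness on clean protocol-shaped data, not robustness to
every clinical artifact.

## 6. Known limitations

* The abdomen is a single compliant compartment; organ support of the right
  hemidiaphragm (the liver) is representable only as a lower `C_ab`/`C_di`.
* Alveolar gas is quasi-steady per aliquot; within-breath alveolar
  oscillations and washin dynamics between aliquots are not resolved.
* No airway gas inertance, no posture dependence, no ventilator coupling,
  no acid–base chemistry, no transcutaneous-electrode physics.
* The loop-morphology findings are *sufficient-condition* demonstrations:
  parameter sets exist that produce each observed loop class; the model does
  not claim these are the only routes to them.
* Problem sizes used in the shipped analyses: 100 layers (200 for the
  convergence check), 2 recorded breaths per condition after 3 wash-in
  breaths, full 25-aliquot drainage for the session-level experiments.
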