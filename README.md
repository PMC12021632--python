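# pleurasim

A lumped-parameter **virtual patient** for studying how a large unilateral
pleural effusion deforms the respiratory pump, and what happens during
stepwise therapeutic thoracentesis — together with the signal-analysis
pipeline used on pleural manometry + spirometry recordings (P–V loops,
pendelluft, amplitude trends).

## Who this is for

Respiratory physiologists and pulmonologists interested in pleural-space
mechanics: why a massive effusion need *not* functionally invert the
hemidiaphragm, why some pleural pressure–volume loops are 8-shaped, why
blood gases respond so little to fluid withdrawal, and why the pleural
pressure amplitude can *fall* during early drainage.  All four are emergent
behaviors of the simulator, not coded rules, and all hinge on one parameter:
the **mediastinal compliance** `C_med`.

## The model in brief

Each lung is a stack of horizontal layers (default 100) in a prismatic
hemithorax; pleural fluid pools at the bottom and raises local pleural
pressure hydrostatically (ρg·depth).  Layers have exponential recoil
`P_el = −(1/k)·ln(1 − V/V_max)`, collapsible peripheral airways, and
open/close across a transmural-pressure hysteresis band `[P_close, P_open]`.
The hemithoraces share a viscoelastic rib cage, are closed by two
hemidiaphragms on a common abdomen, and are coupled by an elastic
mediastinum obeying `P_pl,ipsi − P_pl,contra = V_med / C_med` exactly at
every solver step.  Hemidiaphragm drive carries a force–length factor and an
inversion direction factor: contraction of an inverted dome *raises*
ipsilateral pleural pressure (paradoxical).  Perfusion follows a pleural-
pressure-gated vascular conductance per layer (flow to closed tissue =
shunt); alveolar/arterial gases come from per-lung mass balances closed
through the Hill O₂ and linearized CO₂ content curves and the Fick
principle.

The loop analysis implements the clinical definitions: a loop **leans left**
(functional hemidiaphragm inversion) when pleural pressure at
end-inspiration exceeds that at end-expiration; a **figure-eight** is a
proper self-intersection of the closed P–V polyline; **pendelluft** is
opposite-signed main-bronchial flows; trend slopes are fitted separately
below and above 1.9 L withdrawn.

See `docs/methods.md` for the full model description, assumptions and
limitations.

## Worked example

```python
from pleurasim import build_patient, simulate_breaths, run_tt
from pleurasim.gases_circulation import gases_for_recording
from pleurasim.loop_analysis import classify_lean, detect_eight, loops_from_recording

# a stiff-mediastinum patient with 3 L of right-sided effusion
params = build_patient("stiff_mediastinum")
rec, state = simulate_breaths(params, V_pf=3.0, n_breaths=2)

loop = loops_from_recording(rec)[-1]
print(classify_lean(loop))            # left   (functionally inverted)
print(detect_eight(loop)[0])          # True   (8-shaped loop)
print(round(state.open_fraction[0], 2))   # 0.37 - only the upper lung stays aerated

gas = gases_for_recording(rec, params, state=state)
print(round(gas.PaO2, 1), round(gas.q_shunt, 2))  # 8.5 kPa, 0.82 L/min shunt
```

The same patient with a *compliant* mediastinum
(`build_patient("compliant_mediastinum")`) produces a right-leaning, simple
loop: the contralateral hemidiaphragm works the ipsilateral hemithorax
through the mediastinum, so the hemidiaphragm is not *functionally*
inverted even though it is anatomically displaced.

A stepwise drainage session with the clinical aliquot protocol
(200 mL portions to 1 L, then 100 mL):

```python
session = run_tt(build_patient("compliant_mediastinum"), V_pf0=3.0, stop=0.6)
print([round(a.amp_median, 3) for a in session.aliquots])
# [0.142, 0.123, 0.113, 0.126]  - the amplitude falls over the early aliquots
print([round(a.P_pl_at_FRC, 3) for a in session.aliquots])
# [1.526, 1.393, 1.26, 1.127]   - catheter-site pleural pressure falls steadily
```

## Command line

```bash
pleurasim simulate --preset stiff_mediastinum --pe-volume 3.0 --out rec.csv
pleurasim tt --preset compliant_mediastinum --pe-volume 3.0 --out session.json
pleurasim analyze --recording rec.csv --fs 25 --out metrics.json
pleurasim synth --seed 7 --out synth.csv --truth truth.json
pleurasim experiment --question 2 --out q2.json --plots
```

`pleurasim experiment --question N` reproduces the four experiment grids
(1: C_med sweep → loop lean; 2: stiff-mediastinum loop + phase-resolved
bronchial flows; 3: gases/shunt along a full drainage; 4: amplitude
trajectories under compliant vs. stiff mediastinum).  Questions 3 and 4 run
full 25-aliquot sessions and take a few minutes each.

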