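# guytonsim

A tested simulator of the geometrical Guyton model of the circulation, for
intensive-care physiology: given the independent variables of the system —
mean systemic filling pressure (P_MSF), pericardial pressure (P_PC),
resistance to venous return (R_VR) and "cardiac resistance" (R_cardiac) —
it solves for the circulation's *operating point*, the equilibrium whose
coordinates are right atrial pressure (P_RA) and total circulatory flow
(Q_circulatory). Both coordinates are outputs: the model's central claim is
that neither P_RA nor cardiac output is an independent knob. The package is
aimed at clinician-researchers and educators reasoning about ICU
interventions — fluids, vasoactives, ventilator settings and especially
prone positioning in ARDS.

## The model

Venous return and cardiac function are piecewise-linear curves in the
(P_RA, flow) plane:

- venous return = (P_MSF − P_RA) / R_VR on its sloped limb, plateauing at
  (P_MSF − P_CRIT) / R_VR once P_RA falls below the great-vein collapse
  pressure P_CRIT (vascular waterfall);
- cardiac output = (P_RA − P_PC) / R_cardiac between its x-intercept P_PC
  and the plateau onset P_RAplat, constant above it.

When both curves are on their sloped limbs the intersection is closed-form:

    Q = (P_MSF − P_PC) / (R_cardiac + R_VR)

Otherwise the operating point sits on a plateau and the regime is
**cardiac-limited** (Q = (P_RAplat − P_PC)/R_cardiac; peripheral variables
move only P_RA — the physiology of preload unresponsiveness),
**venous-limited** (Q = (P_MSF − P_CRIT)/R_VR; cardiac variables move only
P_RA), or **doubly-limited** when both plateaus coincide.

Pericardial pressure is decomposed as

    P_PC = P_PL + P_AW · (E_CW / E_RS) + P_PC_EL

— pleural pressure, the ventilator-transmitted share of mean airway
pressure set by the chest-wall/respiratory-system elastance ratio, and
pericardial elastic recoil. The recoil term can be solved
self-consistently: it depends on transmural P_RA, which depends on the
solution (`self_consistent_solve`).

Units: pressures in mmHg, flows weight-indexed in mL·kg⁻¹·min⁻¹ so the
canonical conductance estimates (G_cardiac = 35, G_VR = 10 mL/kg/min per
mmHg) are usable verbatim; absolute L/min only via explicit body-mass
conversion.

## Worked example

```python
from guytonsim import CardiacFunctionCurve, VenousReturnCurve, solve_operating_point

vr = VenousReturnCurve(p_msf=8.0, r_vr=1/10, p_crit=-2.0)
cf = CardiacFunctionCurve(p_pc=0.0, r_cardiac=1/35, p_ra_plat=6.0)
op = solve_operating_point(vr, cf)
print(op.p_ra, op.q_circulatory, op.regime)
```

prints

```
P_RA           = 1.778 mmHg
Q_circulatory  = 62.22 mL/kg/min
               = 4.36 L/min at 70 kg
regime         = unlimited
```

i.e. the canonical resting adult sits at a right atrial pressure of
1.8 mmHg and a flow of 62 mL/kg/min (≈4.4 L/min at 70 kg), with neither
curve on its plateau. The `examples/` directory has one short script per
capability (operating point, R_VR anatomy, prone transitions, the
preload-responsiveness probe, sweeps and cohorts); each prints its numbers
with a line on what they mean.

## Command line

```bash
guytonsim solve                      # default scenario -> operating-point JSON
guytonsim solve --config my.yaml --mass-kg 70
guytonsim curves --range -4:10:0.1 --out curves.csv
guytonsim sweep --param p_msf --range 4:12:1 --out sweep.csv
guytonsim prone --fixture preload_responsive
guytonsim cohort --n 100 --seed 7 --out cohort.csv
```

Scenario files are flat YAML/JSON maps; every key has a validated default,
so `{}` is the canonical resting circulation. Example:

```yaml
p_msf: 11          # mmHg
g_vr: 10           # mL/kg/min per mmHg
g_cardiac: 35
p_crit: -2
p_ra_plat: 6
p_aw: 12           # mmHg mean airway pressure
e_cw_ratio: 0.3    # chest-wall / respiratory-system elastance
p_pl: -2.5
body_mass: 70
```

Exit codes: 0 success, 1 validation error, 2 no physiological equilibrium
(P_PC ≥ P_MSF).

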