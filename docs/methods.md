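# Methods note

## Model

The circulation is reduced to two piecewise-linear curves in the
(P_RA, flow) plane whose intersection defines the operating point.

**Venous return.** On the sloped limb,
Q_VR = (P_MSF − P_RA) / R_VR. Below the great-vein collapse pressure
P_CRIT the driving gradient saturates (vascular waterfall) and the curve
plateaus at Q_VR,max = (P_MSF − P_CRIT) / R_VR. Flow above P_MSF is not
clamped (the curve goes negative), so a cardiac curve that would demand
P_RA > P_MSF has no physiological intersection.

**Cardiac function.** Between the x-intercept P_PC and the plateau onset
P_RAplat, Q_CO = (P_RA − P_PC) / R_cardiac; above P_RAplat it is constant
at (P_RAplat − P_PC) / R_cardiac; below P_PC it is zero. "Cardiac
resistance" R_cardiac is the reciprocal of the slope of the cardiac
function curve, not a hydraulic resistance.

**Pericardial pressure.** P_PC = P_PL + P_AW·(E_CW/E_RS) + P_PC_EL:
pleural pressure, the fraction of mean airway pressure transmitted to the
heart (set by the chest-wall to respiratory-system elastance ratio), and
pericardial elastic recoil. Recoil is itself a piecewise-linear function
of transmural P_RA (zero below an engagement threshold, then a shallow
and a steep slope), which makes P_PC depend on the solution;
`self_consistent_solve` closes the loop.

**Equilibrium.** The solver is closed-form with four regimes:

- *unlimited* — both sloped limbs intersect:
  Q = (P_MSF − P_PC)/(R_cardiac + R_VR), P_RA = P_PC + Q·R_cardiac,
  accepted iff P_CRIT ≤ P_RA ≤ P_RAplat;
- *cardiac-limited* — Q = (P_RAplat − P_PC)/R_cardiac,
  P_RA = P_MSF − Q·R_VR; peripheral parameters then move only P_RA;
- *venous-limited* — Q = (P_MSF − P_CRIT)/R_VR, P_RA = P_PC + Q·R_cardiac;
  cardiac parameters then move only P_RA;
- *doubly-limited* — both plateau flows agree within tolerance; P_RA is
  reported as the midpoint of [P_RAplat, intersection range], the
  conventional choice on the indeterminate segment.

If P_PC ≥ P_MSF no forward-flow equilibrium exists and the solver raises
`NoEquilibriumError` rather than returning a degenerate point.

**Resistance to venous return.** For a parallel venous anatomy,
R_VR = Σ fᵢ·Rᵢ·Cᵢ / C_TOT — segment time constants weighted by flow
fraction and normalised by total compliance. This design choice treats
G_VR = 1/R_VR as an independent composite constant rather than deriving
it from arterial resistance; routing flow through long-time-constant
(splanchnic) beds raises R_VR even with per-segment resistances fixed.

**Vessel geometry.** For a cylindrical vessel at fixed length, diameter
ratio d scales volume as d² and Poiseuille resistance as d⁻⁴, so a
venoconstrictor trades stressed-volume recruitment against a steep
resistance penalty.

## Parameters, units, defaults

Pressures are mmHg; flows are weight-indexed mL·kg⁻¹·min⁻¹; resistances
are mmHg·kg·min·mL⁻¹ (reciprocal conductances). Defaults describe a
canonical resting adult:

| Parameter | Default | Rationale |
|---|---|---|
| P_MSF | 8 mmHg | canonical mean systemic filling pressure |
| G_VR = 1/R_VR | 10 mL/kg/min per mmHg | canonical venous-return conductance |
| G_cardiac = 1/R_cardiac | 35 mL/kg/min per mmHg | canonical cardiac-function slope |
| P_CRIT | −2 mmHg | great-vein collapse pressure |
| P_RAplat | 6 mmHg | cardiac plateau onset |
| P_PL, P_AW, P_PC_EL | 0 mmHg | spontaneous breathing, slack pericardium |
| E_CW/E_RS | 0.3 when P_AW is used | typical elastance ratio |
| recoil: engage 5, steep 11 mmHg; slopes 0.5, 1.5 | — | configurable model choice, not a fitted constant |
| body mass | 70 kg | for mL/kg/min → L/min conversion only |

The recoil breakpoints and slopes, like everything in the table, are
scenario-configurable; none are fitted to data by this package.

## Numerics

- Closed-form solver with tolerance-ordered regime checks (branch
  tolerance 1e-6 mL/kg/min for the doubly-limited tie).
- Verification oracle: `scipy.optimize.brentq` on
  cardiac_output(P_RA) − venous_return(P_RA), which is monotone
  nondecreasing; bracket [min(P_CRIT, P_PC)−5, P_MSF+5], xtol 1e-10. The
  test suite checks closed-form vs oracle agreement below 1e-6 on 1000
  random valid states, with identical regime labels.
- Sensitivities are analytic per regime; requests within 1e-6 of a
  regime breakpoint raise `NondifferentiablePointError` instead of
  returning a one-sided derivative.
- `self_consistent_solve` iterates P_PC_EL by damped fixed point
  (damping 0.5, max 100 iterations); non-convergence raises
  `ConvergenceError` carrying the last iterate.
- Negative demanded flow is an error, never silently clipped.

## Synthetic cohort

`generate_cohort` rejection-samples parameter vectors uniformly from
configurable ranges and keeps only structurally valid, solvable states.
It emulates *parameter spread*, not patients: draws are independent and
uniform, with none of the covariance real physiology imposes (e.g. high
P_MSF co-occurring with venoconstriction). It is intended for exercising
the solver across regimes and for seeded, reproducible examples — not
for epidemiological inference.

## Limitations

- Steady-state only: no pulsatility, no heart-lung interaction within a
  breath, no autonomic reflexes or volume kinetics over time.
- Piecewise-linear curves idealise smoothly curvilinear physiology;
  behaviour exactly at breakpoints is a convention.
- Prone positioning is represented as parameter steps (ΔP_MSF, R_VR and
  R_cardiac factors, elastance-ratio shift), without quantitating
  abdominal-compartment mechanics.
- Left and right hearts are lumped into one cardiac function curve;
  pulmonary vascular effects enter only through the chosen parameters.
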