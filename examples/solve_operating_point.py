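"""Solve the resting circulation's operating point.

Builds the canonical adult state (P_MSF 8 mmHg, cardiac conductance 35 and
venous conductance 10 mL/kg/min per mmHg) and solves for the equilibrium.
"""

from guytonsim import CardiacFunctionCurve, VenousReturnCurve, solve_operating_point
from guytonsim.config import flow_to_absolute

vr = VenousReturnCurve(p_msf=8.0, r_vr=1 / 10, p_crit=-2.0)
cf = CardiacFunctionCurve(p_pc=0.0, r_cardiac=1 / 35, p_ra_plat=6.0)
op = solve_operating_point(vr, cf)

print(f"P_RA           = {op.p_ra:.3f} mmHg")
print(f"Q_circulatory  = {op.q_circulatory:.2f} mL/kg/min")
print(f"               = {flow_to_absolute(op.q_circulatory, 70):.2f} L/min at 70 kg")
print(f"regime         = {op.regime}")
# Both coordinates are outputs: right atrial pressure and total flow fall
# out of the venous/cardiac equilibrium together; neither causes the other.
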