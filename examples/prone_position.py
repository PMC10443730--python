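"""Prone-position transitions on the two packaged baselines.

The preload-responsive baseline gains flow with pronation; the
cardiac-limited baseline only sees its right atrial pressure rise, because
flow on the cardiac plateau is set entirely by the cardiac side.
"""

from guytonsim import load_prone_fixture, prone_transition

for name in ("preload_responsive", "cardiac_limited"):
    state, prone = load_prone_fixture(name)
    result = prone_transition(state, prone)
    print(f"{name}:")
    print(f"  supine P_PC = {state.cardiac.curve().p_pc:.2f} mmHg")
    print(f"  Q:    {result.before.q_circulatory:.2f} -> "
          f"{result.after.q_circulatory:.2f} mL/kg/min (dQ = {result.delta_q:+.2f})")
    print(f"  P_RA: {result.before.p_ra:.2f} -> {result.after.p_ra:.2f} mmHg "
          f"(dP_RA = {result.delta_p_ra:+.2f})")
    print(f"  regime: {result.regime_change[0]} -> {result.regime_change[1]}")
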