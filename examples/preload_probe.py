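"""Detect cardiac limitation with a passive-leg-raise-style probe.

Raises P_MSF transiently by 2 mmHg and classifies the state as preload
responsive if relative flow gain reaches 10%.
"""

from guytonsim import load_prone_fixture, preload_responsiveness

for name in ("preload_responsive", "cardiac_limited"):
    state, _ = load_prone_fixture(name)
    responsive, relative = preload_responsiveness(state)
    verdict = "responsive" if responsive else "UNRESPONSIVE (cardiac-limited)"
    print(f"{name}: dQ/Q = {relative:+.1%} -> {verdict}")
# Zero gain identifies the cardiac plateau: more filling pressure moves
# only P_RA, not flow — the clinical signature of preload unresponsiveness.
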