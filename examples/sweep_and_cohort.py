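"""Parameter sweeps and a seeded synthetic cohort.

Sweeps filling pressure on the default patient, then generates a small
cohort and tabulates the regime mix.
"""

from collections import Counter

from guytonsim import ScenarioConfig, generate_cohort, parameter_sweep

state = ScenarioConfig().patient_state()
table = parameter_sweep(state, "p_msf", [4, 6, 8, 10, 12])
print(table.to_string(index=False))
# Flow rises ~7.8 mL/kg/min per mmHg of P_MSF while unlimited
# (the slope is 1/(R_cardiac + R_VR)).

cohort = generate_cohort(n=200, seed=7)
regimes = Counter(s.solve().regime for s in cohort)
print("\ncohort regime mix:", dict(regimes))
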