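"""Where the resistance to venous return comes from.

Composes R_VR from vascular segments via flow-fraction-weighted time
constants, and shows the diameter scaling trade-off of venoconstriction.
"""

from guytonsim import VascularSegment, compose_rvr, vessel_geometry_scaling

splanchnic = VascularSegment(resistance=1.0, compliance=10.0, flow_fraction=0.7)
non_splanchnic = VascularSegment(resistance=1.0, compliance=2.0, flow_fraction=0.3)

print(f"mixed routing      R_VR = {compose_rvr([splanchnic, non_splanchnic]):.3f}")
all_splanchnic = [s.model_copy(update={"flow_fraction": f})
                  for s, f in [(splanchnic, 1.0), (non_splanchnic, 0.0)]]
all_fast = [s.model_copy(update={"flow_fraction": f})
            for s, f in [(splanchnic, 0.0), (non_splanchnic, 1.0)]]
print(f"all splanchnic     R_VR = {compose_rvr(all_splanchnic):.3f}  (long time constant)")
print(f"all non-splanchnic R_VR = {compose_rvr(all_fast):.3f}  (short time constant)")

# Venoconstriction recruits stressed volume but raises resistance sharply:
vol, res = vessel_geometry_scaling(0.8)
print(f"20% narrower vein: volume down {100 * (1 - vol):.0f}%, "
      f"resistance at {100 * res:.0f}% of baseline")
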