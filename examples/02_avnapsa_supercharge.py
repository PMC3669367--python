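"""Exposure-ranked (AvNAPSA) supercharging of a mixed helix.

Candidates (N/Q plus D/E for positive polarity) are sorted by AvNAPSA value
from low (most exposed) to high and mutated to lysine one by one until the
target net charge is reached.  Each mutation adds +1 (N/Q -> K) or +2
(D/E -> K) charge units, so the mutation count per charge lies between 0.5
and 1.  The protocol is fully deterministic.
"""

from supercharge import apply_avnapsa_design, candidate_list, net_formal_charge
from supercharge.fixtures import FixtureSpec, make_structure
from supercharge.reporting import output_name, pymol_selection

helix = make_structure(FixtureSpec("ANQEKDLSTNQRVKEA", "ideal_helix"))
print(f"native sequence: {helix.sequence()}  net charge {net_formal_charge(helix):+d}")

print("\ncandidates sorted by exposure (low AvNAPSA = most exposed):")
for c in candidate_list(helix, "positive"):
    print(f"  {c.native_aa}{c.site[1]:<3d} -> {c.new_aa}  "
          f"avnapsa={c.avnapsa:6.1f}  delta={c.charge_delta:+d}")

result = apply_avnapsa_design(helix, "positive", target_charge=5)
print(f"\ntarget +5: {len(result.mutations)} mutations, achieved "
      f"{result.net_charge_after:+d} (overshoot by one is allowed when a +2 "
      f"swap crosses the target)")
for m in result.mutations:
    print(f"  {m.native_aa}{m.site[1]}{m.new_aa}  avnapsa={m.avnapsa:.1f}")
print(f"\ndesigned sequence: {result.structure.sequence()}")
print(pymol_selection(result))
print(f"output PDB would be named: {output_name(result, 'helix16')}")
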