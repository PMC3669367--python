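"""Why the two protocols diverge: a crafted hydrogen-bond motif.

The fixture holds an aspartate whose carboxylate accepts a strong (-1.0
energy unit) hydrogen bond from a backbone amide.  The exposure-ranked
protocol sees only solvent accessibility and mutates the aspartate,
destroying the bond; the energy-guided protocol preserves any side chain
in a bond stronger than -0.5 and leaves it untouched.
"""

from supercharge import (
    DesignOptions,
    apply_avnapsa_design,
    compare_designs,
    comparison_report,
    detect_sidechain_hbonds,
    supercharge_with_refweights,
)
from supercharge.fixtures import make_hbond_motif

motif = make_hbond_motif("sidechain_to_backbone_loop")
for hb in detect_sidechain_hbonds(motif):
    print(f"native bond: {hb.donor_site}/{hb.donor_atom} -> "
          f"{hb.acceptor_site}/{hb.acceptor_atom}  energy {hb.energy:.2f} ({hb.kind})")

avnapsa = apply_avnapsa_design(motif, "positive", target_charge=1)
energy = supercharge_with_refweights(
    motif, refweights={"K": -5.0}, options=DesignOptions(include_lys=True), seed=0
)
print(f"\navnapsa mutated: {sorted(avnapsa.mutated_sites())}")
print(f"energy mutated:  {sorted(energy.mutated_sites())}")

comparison = compare_designs(motif, avnapsa, energy)
print()
print(comparison_report(comparison))
print()
print(f"strong bonds lost by the exposure protocol: "
      f"{comparison.hbonds_a.lost_strong}; by the energy protocol: "
      f"{comparison.hbonds_b.lost_strong}")
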