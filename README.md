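# supercharge

Automated redesign of protein surfaces for high net charge
("supercharging").  Raising the magnitude of a protein's net charge adds
charge–charge repulsion between molecules, which suppresses aggregation of
partially unfolded states and can make thermal unfolding reversible.  The
hard part is choosing *which* surface residues to mutate: every mutation
risks destabilizing the native state.

This package implements two complementary, fully automated protocols behind
one library + CLI:

* **AvNAPSA mode** (exposure-ranked, deterministic).  Every N/Q and D/E
  (positive polarity) or R/K (negative polarity) residue is ranked by its
  **AvNAPSA** value — the **Av**erage number of **N**eighboring **A**toms
  **P**er **S**ide-chain **A**tom within 10 Å; low values mean high solvent
  exposure.  Candidates are mutated in order of exposure (DENQ→K for
  positive charging; RKQ→E, N→D for negative) until the requested net
  charge is reached, or all candidates below a surface cutoff are used.
  Arginine is never introduced, and aspartate only at native asparagines.

* **Energy mode** (stochastic, energy-guided).  Surface positions are
  redesigned by fixed-backbone rotamer packing (simulated annealing with
  Metropolis acceptance) under a simplified full-atom energy with
  score12-shaped terms: Lennard-Jones attraction/repulsion, a polar-burial
  solvation penalty, a ±0.5 statistical pair term for charge
  complementarity, geometric hydrogen bonding, rotamer priors, and
  per-residue-type **reference energies**.  Net charge is steered by the
  reference energies of the included charged types (defaults R −0.98,
  K −0.65, D −0.67, E −0.81): lowering them recruits more charged residues.
  A target-charge mode ramps the weights down in 0.05 steps until the
  target is reached.  By default the protocol preserves
  glycine/proline/cysteine, residues already bearing the desired charge,
  and any side chain in a hydrogen bond stronger than −0.5 energy units.

Net formal charge is counted as (#Arg + #Lys) − (#Asp + #Glu), histidine
neutral, termini ignored.

Everything is testable offline: a fixtures module builds ideal-geometry
peptides, helix bundles and crafted hydrogen-bond motifs from embedded
internal-coordinate templates — no structure downloads required.

## Worked example

```python
from supercharge import apply_avnapsa_design, net_formal_charge
from supercharge.fixtures import FixtureSpec, make_structure

helix = make_structure(FixtureSpec("ANQEKDLSTNQRVKEA", "ideal_helix"))
print(net_formal_charge(helix))          # +0
result = apply_avnapsa_design(helix, "positive", target_charge=5)
for m in result.mutations:
    print(m.native_aa, m.site[1], m.new_aa, round(m.avnapsa, 1))
```

prints

```
0
N 2 K 39.0
Q 3 K 41.8
E 4 K 48.4
E 15 K 53.4
```

i.e. the four most exposed candidates (lowest AvNAPSA) are charged first;
the two E→K swaps add +2 each, so four mutations reach +6 (the target +5
may overshoot by one when a +2 swap crosses it).  The same run from the
shell:

```sh
supercharge fixtures --sequence ANQEKDLSTNQRVKEA --out helix.pdb
supercharge run --pdb helix.pdb --mode avnapsa --polarity pos --target-charge 5 --out-dir out
```

writes the design log, the governing residue file, and a self-documenting
output PDB (`helix_A_netq+6_avn53.pdb`: protocol, net charge, largest
AvNAPSA among mutated residues).  The energy mode is analogous:

```sh
supercharge run --pdb helix.pdb --mode energy --include-lys --target-charge 6 --seed 11 --out-dir out
```

More narrative walk-throughs live in `examples/` (surface annotation, both
protocols, and a crafted-motif comparison showing why the two protocols
diverge on hydrogen-bonded surface residues).

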