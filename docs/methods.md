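# Methods

This note documents the models and numerical choices behind the package:
what each component computes, which parameters matter, and what the
synthetic fixtures do and do not establish about behavior on real
structures.

## Structure model

Structures are chains of canonical residues carrying heavy atoms only.
Parsing (via biotite) drops HETATM records, waters, hydrogens, alternate
locations after the first (occupancy ignored, so parsing is deterministic),
and non-canonical residues; residues missing any of N/CA/C are dropped with
a warning, while residues with incomplete *side chains* are retained —
exposure metrics average over the atoms that are present.  Hydrogens in
input files are discarded even when present, so neighbor counts do not
depend on whether a model was protonated.  Multi-chain inputs are parsed
whole; design is restricted to one chain (default: the first), with the
remaining chains contributing as fixed context to neighbor counts and
energies.

Net formal charge is (#R + #K) − (#D + #E).  Histidine is treated as
neutral and termini are ignored: the charge count is a side-chain
bookkeeping device, not a pKa model.

## Surface definitions

Two definitions coexist, as used by the two protocols:

* *atom-based*: the AvNAPSA value — mean number of heavy atoms of other
  residues within 10 Å of each side-chain heavy atom.  Neighbor counting
  excludes the residue's own atoms and includes backbone atoms of other
  residues (backbone atoms contribute to burial).  Glycine has no side
  chain, hence no AvNAPSA value, and is never an AvNAPSA candidate.
* *residue-based*: the number of other residues with Cβ–Cβ distance < 10 Å
  (Cα substitutes for glycine).  Insensitive to side-chain conformation.

All comparisons are strict (`<`), both at the 10 Å neighbor distance and at
the classification cutoffs (defaults: 120 atom-based, 16 residue-based;
extended variants 200 / 30 admit peripheral or partially buried sites and
are plain configuration values, not separate code paths).

Open choice: whether the neighbor distance is measured side-chain-atom →
any-heavy-atom (used here) or restricted to side-chain atoms on both ends
is underdetermined; the former is fixed throughout and exercised by the
brute-force oracles in the tests.

## The exposure-ranked protocol

Candidates are sorted ascending by AvNAPSA (ties broken by chain then
residue number) and mutated in order.  Selection stops at the first prefix
whose cumulative charge delta reaches or passes the target; a ±2 swap may
therefore overshoot the target by one, and the achieved charge is reported.
Residues already bearing the desired charge are never candidates.  Because
the backbone is fixed and counting uses heavy atoms of the *native*
structure, AvNAPSA values cannot change as mutations are applied, so the
sort is computed once (re-sorting after each mutation would be a no-op).
Side-chain placement after each forced mutation uses the same
lowest-clash-rotamer machinery as the energy mode.

The module is deliberately free of randomness: identical inputs give
identical outputs.

## The energy model

The energy is intentionally *not* a reproduction of any published force
field.  The protocols only require a pairwise-decomposable energy with the
right shapes, and pairwise decomposability is what lets the packer
precompute one-body/two-body tables.  Terms (weights all 1.0 by default,
editable in one config block):

* **fa_atr / fa_rep** — 6-12 Lennard-Jones on per-element radii/well
  depths (C 1.80/0.10, N 1.65/0.17, O 1.55/0.21, S 2.00/0.25; contact
  distance = sum of radii), split at the minimum into attractive and
  repulsive branches.  The repulsive branch is linearly capped below
  0.6 × contact so clashes grade rather than explode; the attractive branch
  is switched to zero between 5 and 6 Å.
* **fa_sol** — burial: every heavy-atom contact within 5.5 Å (switched
  from 4.0 Å) adds +0.08 per polar atom (N/O) and −0.008 per carbon on
  each side of the pair.  This is a per-neighbor, fully pairwise form of a
  neighbor-count burial penalty: the threshold is effectively zero, which
  keeps the term decomposable for the packer tables at the cost of
  penalizing even the first few contacts of an exposed polar atom.
* **fa_pair** — statistical electrostatics: ±0.5 when two charged side
  chains' group centers (R:CZ, K:NZ, D:CG, E:CD) are within 6.5 Å,
  negative for opposite signs.  No long-range electrostatics and no
  cation–π term are attempted.
* **hbond_bb_sc / hbond_sc** — geometric: donor–acceptor heavy-atom
  distance in [2.4, 3.6] Å with a piecewise-linear ramp peaking at 2.8 Å,
  times squared-cosine angular factors on both the donor and acceptor side
  that are maximal for collinear base→atom→partner geometry.  Ideal
  geometry scores −1.0 × weight; the energy is continuous in distance.
  Backbone–backbone hydrogen bonds are excluded everywhere: they cannot
  change under fixed-backbone design.  Bonds are classed strong
  (< −0.5, also the preservation threshold) or weak ([−0.5, −0.1));
  anything weaker than −0.1 is ignored as numerical dust.
* **rotamer** — −ln(prior) of the library rotamer nearest in chi space.
* **reference** — per-type constant; defaults are zero except R −0.98,
  K −0.65, D −0.67, E −0.81.  This is the design dial: lowering a type's
  reference energy lowers any structure's score by exactly
  (count × delta), so more negative values recruit more of that type.

1-2/1-3/1-4 interactions across the peptide bond between adjacent residues
are excluded by covalent-bond separation (≤ 3 bonds), computed from the
residue topology graphs.  Pair terms are split half/half between partners,
so the per-residue decomposition sums exactly to the total.

Because the angular model is maximal for collinear geometry, naturally
occurring motifs (helix caps and the like) score weak under it; the crafted
fixtures therefore place partner residues with exactly collinear geometry
when a strong bond is required.

## Rotamers and packing

The rotamer library is a compact, embedded, backbone-independent set
(canonical gauche−/trans/gauche+ combinations, ≤ 4 rotamers per type,
priors summing to 1) plus internal-coordinate templates for building side
chains on any backbone.  This trades rotamer coverage for determinism and
zero external data; it is not a substitute for a backbone-dependent
library when modeling real proteins.

The design task marks every residue designable or fixed with a recorded
reason (`not_surface`, `glyprocys`, `correct_charge`, `hbonded_sidechain`,
`resfile_excluded`); each preservation rule can be switched off
independently.  Preserved hydrogen-bonded side chains are fully frozen
(type and conformation — the conservative reading of "preserve"), not
merely barred from changing type.  Resfiles use a two-command dialect:
`start`, then `<resnum> <chain> NATRO` or `<resnum> <chain> PIKAA <letters>`
per line; a PIKAA set intersects the allowed types but the native type is
always allowed.

Packing enumerates, per designable site, the native observed conformation
plus every library rotamer of every allowed type; one-body (reference +
rotamer + fixed-environment) and two-body tables are precomputed, and
simulated annealing (uniform proposals over site×choice, Metropolis
acceptance, geometric cooling kT 10 → 0.3 over 30 × total-choices steps)
returns the best assignment encountered.  Starting from the native
assignment guarantees the result is never worse than the native.  The same
tables back an exhaustive enumerator (refused above 10⁵ states) used as
the optimality oracle on small tasks.  Reference-energy overrides apply at
pack time, so a ramp re-anneals without rebuilding tables.  Same seed,
same result; distinct seeds may differ (`nstruct` runs several and keeps
the best).

## Energy-guided supercharging

`supercharge_with_refweights` packs once at given reference energies; at
least one charged type must be included (`include_arg` / `include_lys` /
`include_asp` / `include_glu`, all off by default) and polarity is inferred
from the included set, erroring on mixed signs.  `supercharge_to_target`
ramps the included types' reference energies down by 0.05 per iteration —
both types together, preserving their default offset — re-packing *from
the native structure* each iteration with a fresh derived seed, until the
net charge reaches the target or 60 iterations pass.  Re-packing from the
native (rather than from the previous iterate) makes each result a
function of the final weights plus seed only.  The step and cap are sized
so the ramp spans defaults down to roughly −3.7, which saturates every
fixture long before the cap.  The optional pre-pack is a native repack (no
minimization) of the designable sites, giving energy comparisons a relaxed
baseline.

Reported energy tables and protocol comparisons are always computed with
*default* reference energies, regardless of the weights used during
design, so designs produced at different weights are comparable.

## Comparison statistics

Shared-position fractions use the union of mutated positions as the
denominator (the symmetric choice; the fraction restricted to matching
(position, new-type) pairs shares the same denominator, so it can never
exceed the position fraction).  Two mutation-free designs compare as fully
shared.  Hydrogen-bond gain/loss counts match bonds by
(donor site, donor atom, acceptor site, acceptor atom); lost bonds are
classed by their native energy, gained bonds by their design energy.
Mutations-per-charge is #mutations / |Δ net charge| — bounded in
[0.5, 1.0] for the exposure protocol (every swap contributes 1 or 2 charge
units), unbounded above for the energy protocol, which may charge neutral
residues one unit at a time.

## Fixtures, problem sizes, and what the tests show

All test inputs are generated: peptides with ideal backbone dihedrals
(helix −57/−47, strand −120/+120, extended 180/180) and ideal bond
geometry, side chains placed by lowest-clash rotamer; a two-helix bundle
(two parallel helices ~9.5 Å apart) supplies buried/surface contrast;
crafted motifs place a partner glycine exactly collinear with a side-chain
donor or acceptor at 2.8 Å (strong, energy −1.0) or 3.36 Å (weak, −0.3) to
make hydrogen-bond preservation observable.  An optional perturbation seed
adds 0.03 Å Gaussian jitter.

The standard panel is four structures of 8–24 residues; the acceptance
script uses this panel, 30 random small packing tasks, and ramps over all
reachable targets on two peptides.  These sizes keep the whole suite in
the tens of seconds while exercising every code path.

What the fixtures do **not** emulate: real packing density (toy surfaces
are almost entirely exposed, so the energy mode charges a larger fraction
of the surface at default reference energies than it would on a folded
protein), realistic rotamer strain, long-range electrostatics, and any
wet-lab observable (expression, melting, refolding are out of scope).
Passing tests establish protocol correctness — ordering, bookkeeping,
preservation rules, optimality of packing, determinism — not predictive
accuracy for real proteins.  The qualitative trends the package reproduces
at desk scale are: the exposure protocol needs fewer mutations per unit
charge than the energy protocol; the two protocols choose largely
different mutation sets; and the exposure protocol destroys strong
surface hydrogen bonds that the energy protocol preserves.

## Degenerate inputs and tie-breaks

Empty candidate lists are legal (selection may return an empty design);
an unreachable target raises an error carrying the best achievable charge
(and, for ramps, the final weights).  Rotamer clash ties keep the first
library rotamer.  Sites tied exactly at a surface cutoff are excluded
(strict `<`).  A design task in which every surface site is preserved
yields a 0-mutation result with a warning rather than an error.
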