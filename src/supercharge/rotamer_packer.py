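"""Fixed-backbone side-chain packing.

The packer works the classic way: every designable position gets a discrete
choice list (the native observed side chain plus library rotamers of every
allowed type), one-body and two-body energies are precomputed into tables,
and simulated annealing with Metropolis acceptance searches the assignment
space.  An exhaustive enumerator over the same tables serves as the oracle
for small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import build, chemdata
from .energy_function import (
    EnergyModel,
    default_model,
    detect_sidechain_hbonds,
    one_body_energies,
    score_structure,
)
from .errors import SearchSpaceError, UsageError, ValidationError
from .structure_model import AtomRecord, ProteinStructure, ResidueSite, Site

PRESERVE_REASONS = (
    "not_surface",
    "glyprocys",
    "hbonded_sidechain",
    "correct_charge",
    "resfile_excluded",
)

_CA_PREFILTER = 22.0  # must match score_structure's pair prefilter


@dataclass(frozen=True)
class RotamerSet:
    """Per-type chi-angle rotamers with prior probabilities summing to 1."""

    library: dict[str, list[tuple[tuple[float, ...], float]]] = field(
        default_factory=lambda: dict(chemdata.ROTAMER_LIBRARY)
    )

    def __post_init__(self):
        for aa in chemdata.CANONICAL_AA:
            rotamers = self.library.get(aa)
            if not rotamers:
                raise ValidationError(f"rotamer library missing type {aa}")
            total = sum(p for _, p in rotamers)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"rotamer probabilities for {aa} sum to {total}, not 1"
                )

    def rotamers(self, aa: str):
        return self.library[aa]


DEFAULT_ROTAMERS = RotamerSet()


@dataclass(frozen=True)
class AnnealingSchedule:
    kt_start: float = 10.0
    kt_end: float = 0.3
    steps_per_choice: int = 30


@dataclass
class DesignTask:
    """Designable sites with allowed types; fixed sites with their reason."""

    designable: dict[Site, tuple[str, ...]]
    fixed: dict[Site, str]

    def __post_init__(self):
        overlap = set(self.designable) & set(self.fixed)
        if overlap:
            raise ValidationError(f"sites both designable and fixed: {overlap}")
        for reason in self.fixed.values():
            if reason not in PRESERVE_REASONS:
                raise ValidationError(f"unknown preservation reason {reason!r}")

    def n_designable(self) -> int:
        return len(self.designable)


# ---------------------------------------------------------------------------
# residue files (resfile dialect: `start`, then NATRO / PIKAA lines)

def read_resfile(path: str | Path) -> dict[tuple[str, int], tuple[str, frozenset | None]]:
    """Parse a resfile into {(chain, resnum): ("NATRO", None) | ("PIKAA", set)}."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or lines[0].lower() != "start":
        raise ValidationError(f"resfile {path} must begin with a 'start' line")
    entries: dict[tuple[str, int], tuple[str, frozenset | None]] = {}
    for line in lines[1:]:
        fields = line.split()
        if len(fields) < 3:
            raise ValidationError(f"malformed resfile line: {line!r}")
        resnum, chain, command = int(fields[0]), fields[1], fields[2].upper()
        if command == "NATRO":
            entries[(chain, resnum)] = ("NATRO", None)
        elif command == "PIKAA":
            if len(fields) < 4:
                raise ValidationError(f"PIKAA line missing amino-acid letters: {line!r}")
            letters = frozenset(fields[3].upper())
            bad = letters - chemdata.CANONICAL_AA
            if bad:
                raise ValidationError(f"non-canonical PIKAA letters {sorted(bad)}")
            entries[(chain, resnum)] = ("PIKAA", letters)
        else:
            raise ValidationError(f"unsupported resfile command {command!r}")
    return entries


def write_resfile(task: DesignTask, path: str | Path) -> None:
    lines = ["start"]
    for site in sorted(task.fixed, key=lambda s: (s[0], s[1], s[2])):
        lines.append(f"{site[1]} {site[0]} NATRO")
    for site in sorted(task.designable, key=lambda s: (s[0], s[1], s[2])):
        letters = "".join(sorted(task.designable[site]))
        lines.append(f"{site[1]} {site[0]} PIKAA {letters}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# design-task construction (the preservation rules)

_CORRECT_CHARGE = {"positive": {"R", "K"}, "negative": {"D", "E"}}


def hbonded_sidechain_sites(
    structure: ProteinStructure, model: EnergyModel
) -> set[Site]:
    """Sites whose *side chain* participates in a hydrogen bond stronger than
    the preservation threshold."""
    strong = set()
    for hb in detect_sidechain_hbonds(structure, model):
        if hb.energy < model.hbond_preserve_threshold:
            if hb.donor_atom not in chemdata.BACKBONE_ATOMS:
                strong.add(hb.donor_site)
            if hb.acceptor_atom not in chemdata.BACKBONE_ATOMS:
                strong.add(hb.acceptor_site)
    return strong


def build_design_task(
    structure: ProteinStructure,
    surface: set[Site],
    polarity: str,
    model: EnergyModel,
    include_types: set[str] = frozenset(),
    preserve_glyprocys: bool = True,
    preserve_hbonded_sidechains: bool = True,
    preserve_correct_charge: bool = True,
    resfile: dict | None = None,
) -> DesignTask:
    """Apply the preservation rules to the surface set and record, for every
    fixed residue, why it was preserved.  Each rule can be switched off."""
    if polarity not in _CORRECT_CHARGE:
        raise UsageError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    surface = {tuple(s) for s in surface}
    for site in surface:
        if not structure.has_site(site):
            raise ValidationError(f"surface site {site} not in structure")
    resfile = resfile or {}
    known = {(r.chain, r.number) for r in structure.residues}
    for key in resfile:
        if key not in known:
            raise ValidationError(f"resfile site {key} not in structure")

    hbonded = (
        hbonded_sidechain_sites(structure, model)
        if preserve_hbonded_sidechains
        else set()
    )
    designable: dict[Site, tuple[str, ...]] = {}
    fixed: dict[Site, str] = {}
    for res in structure.residues:
        site = res.site
        entry = resfile.get((res.chain, res.number))
        if site not in surface:
            fixed[site] = "not_surface"
        elif entry is not None and entry[0] == "NATRO":
            fixed[site] = "resfile_excluded"
        elif preserve_glyprocys and res.aa in {"G", "P", "C"}:
            fixed[site] = "glyprocys"
        elif preserve_correct_charge and res.aa in _CORRECT_CHARGE[polarity]:
            fixed[site] = "correct_charge"
        elif site in hbonded:
            fixed[site] = "hbonded_sidechain"
        else:
            allowed = {res.aa} | set(include_types)
            if entry is not None and entry[0] == "PIKAA":
                allowed &= entry[1] | {res.aa}
            designable[site] = tuple(sorted(allowed))
    return DesignTask(designable=designable, fixed=fixed)


# ---------------------------------------------------------------------------
# the packer

@dataclass(frozen=True)
class _Choice:
    residue: ResidueSite
    aa: str
    rotamer_e: float  # -ln(prior)


def _library_choices(
    res: ResidueSite, allowed: tuple[str, ...], rotamers: RotamerSet
) -> list[_Choice]:
    """Native observed conformation first, then library rotamers per type."""
    choices = [
        _Choice(res, res.aa, one_body_rot(res))
    ]
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    backbone = list(res.backbone_atoms)
    for aa in allowed:
        for chis, prob in rotamers.rotamers(aa):
            atoms = tuple(backbone) + tuple(
                AtomRecord(name, elem, pos)
                for name, elem, pos in build.build_sidechain_coords(aa, n, ca, c, chis)
            )
            candidate = ResidueSite(res.chain, res.number, res.icode, aa, atoms)
            choices.append(_Choice(candidate, aa, -math.log(prob)))
    return choices


def one_body_rot(res: ResidueSite) -> float:
    chis = build.measure_chis(res.coords_by_name(), res.aa)
    _, prob = build.nearest_rotamer(res.aa, chis)
    return -math.log(prob)


class Packer:
    """Precomputed one-body/two-body energy tables over a design task.

    Reference-energy overrides can be supplied per pack/enumerate call, so a
    reference-energy ramp re-anneals without rebuilding any table.
    """

    def __init__(
        self,
        structure: ProteinStructure,
        task: DesignTask,
        model: EnergyModel | None = None,
        rotamers: RotamerSet = DEFAULT_ROTAMERS,
    ):
        from .energy_function import are_adjacent, pair_energy_total

        self.structure = structure
        self.task = task
        self.model = model or default_model()
        model = self.model

        positions = {r.site: i for i, r in enumerate(structure.residues)}
        self.design_positions = sorted(
            (positions[s] for s in task.designable), key=int
        )
        self.design_sites = [structure.residues[p].site for p in self.design_positions]
        self.choices: list[list[_Choice]] = []
        for p in self.design_positions:
            res = structure.residues[p]
            self.choices.append(
                _library_choices(res, task.designable[res.site], rotamers)
            )

        fixed_positions = [
            i for i, r in enumerate(structure.residues)
            if r.site not in task.designable
        ]
        residues = structure.residues

        # constant part: fixed-fixed pairs plus fixed one-body energies
        self._e_const_nonref = 0.0
        self._fixed_ref_count: dict[str, int] = {}
        for i in fixed_positions:
            ob = one_body_energies(residues[i], model)
            self._e_const_nonref += model.weights["rotamer"] * ob["rotamer"]
            aa = residues[i].aa
            self._fixed_ref_count[aa] = self._fixed_ref_count.get(aa, 0) + 1
        for a, i in enumerate(fixed_positions):
            for j in fixed_positions[a + 1:]:
                if _ca_dist(residues[i], residues[j]) > _CA_PREFILTER:
                    continue
                self._e_const_nonref += pair_energy_total(
                    residues[i], residues[j], model, are_adjacent(structure, i, j)
                )

        # environment energies: each choice vs every fixed residue
        self.e_env: list[np.ndarray] = []
        for k, p in enumerate(self.design_positions):
            env = np.zeros(len(self.choices[k]))
            for c, choice in enumerate(self.choices[k]):
                total = 0.0
                for j in fixed_positions:
                    if _ca_dist(choice.residue, residues[j]) > _CA_PREFILTER:
                        continue
                    adjacent = (
                        abs(p - j) == 1
                        and choice.residue.chain == residues[j].chain
                    )
                    # argument order must follow chain order: the peptide-bond
                    # exclusion assumes the first residue precedes the second
                    first, second = (
                        (choice.residue, residues[j])
                        if p < j
                        else (residues[j], choice.residue)
                    )
                    total += pair_energy_total(first, second, model, adjacent)
                env[c] = total
            self.e_env.append(env)

        # pair energies between designable choices
        self.e_pair: dict[tuple[int, int], np.ndarray] = {}
        for a in range(len(self.design_positions)):
            for b in range(a + 1, len(self.design_positions)):
                pa, pb = self.design_positions[a], self.design_positions[b]
                adjacent = (
                    abs(pa - pb) == 1
                    and residues[pa].chain == residues[pb].chain
                )
                table = np.zeros((len(self.choices[a]), len(self.choices[b])))
                for ca_, cha in enumerate(self.choices[a]):
                    for cb_, chb in enumerate(self.choices[b]):
                        if _ca_dist(cha.residue, chb.residue) > _CA_PREFILTER:
                            continue
                        table[ca_, cb_] = pair_energy_total(
                            cha.residue, chb.residue, model, adjacent
                        )
                self.e_pair[(a, b)] = table

    # -- energies ----------------------------------------------------------

    def _ref(self, aa: str, override: dict[str, float] | None) -> float:
        if override and aa in override:
            return override[aa]
        return self.model.reference_energies[aa]

    def _e_const(self, override) -> float:
        ref = sum(
            count * self.model.weights["reference"] * self._ref(aa, override)
            for aa, count in self._fixed_ref_count.items()
        )
        return self._e_const_nonref + ref

    def _one_body(self, k: int, c: int, override) -> float:
        choice = self.choices[k][c]
        return (
            self.model.weights["reference"] * self._ref(choice.aa, override)
            + self.model.weights["rotamer"] * choice.rotamer_e
            + self.e_env[k][c]
        )

    def total_energy(self, assignment: list[int], override=None) -> float:
        total = self._e_const(override)
        for k, c in enumerate(assignment):
            total += self._one_body(k, c, override)
        for (a, b), table in self.e_pair.items():
            total += table[assignment[a], assignment[b]]
        return float(total)

    def realize(self, assignment: list[int]) -> ProteinStructure:
        out = self.structure
        for k, c in enumerate(assignment):
            out = out.with_residue(self.design_sites[k], self.choices[k][c].residue)
        return out

    # -- search ------------------------------------------------------------

    def pack(
        self,
        seed: int,
        schedule: AnnealingSchedule | None = None,
        refweight_override: dict[str, float] | None = None,
    ) -> tuple[ProteinStructure, float, list[int]]:
        """Simulated annealing from the native assignment; returns the best
        assignment encountered.  Deterministic for a given seed."""
        schedule = schedule or AnnealingSchedule()
        nsites = len(self.choices)
        assignment = [0] * nsites  # index 0 is the native observed conformation
        current = self.total_energy(assignment, refweight_override)
        best, best_assignment = current, list(assignment)
        if nsites == 0:
            return self.structure, current, []

        flat = [(k, c) for k in range(nsites) for c in range(len(self.choices[k]))]
        steps = max(1, round(schedule.steps_per_choice * len(flat)))
        rng = np.random.default_rng(seed)
        ratio = schedule.kt_end / schedule.kt_start
        for step in range(steps):
            kt = schedule.kt_start * ratio ** (step / max(1, steps - 1))
            k, c = flat[rng.integers(len(flat))]
            old = assignment[k]
            if c == old:
                continue
            delta = (
                self._one_body(k, c, refweight_override)
                - self._one_body(k, old, refweight_override)
            )
            for (a, b), table in self.e_pair.items():
                if a == k:
                    delta += table[c, assignment[b]] - table[old, assignment[b]]
                elif b == k:
                    delta += table[assignment[a], c] - table[assignment[a], old]
            if delta <= 0 or rng.random() < math.exp(-delta / kt):
                assignment[k] = c
                current += delta
                if current < best - 1e-12:
                    best, best_assignment = current, list(assignment)
        best = self.total_energy(best_assignment, refweight_override)  # exact re-sum
        return self.realize(best_assignment), best, best_assignment

    def exhaustive(
        self,
        refweight_override: dict[str, float] | None = None,
        max_states: int = 100_000,
    ) -> tuple[ProteinStructure, float, list[int]]:
        sizes = [len(c) for c in self.choices]
        n_states = int(np.prod(sizes)) if sizes else 1
        if n_states > max_states:
            raise SearchSpaceError(
                f"exhaustive enumeration refused: {n_states} states "
                f"(limit {max_states})"
            )
        best, best_assignment = None, None
        for combo in itertools.product(*(range(s) for s in sizes)):
            e = self.total_energy(list(combo), refweight_override)
            if best is None or e < best - 1e-12:
                best, best_assignment = e, list(combo)
        if best_assignment is None:  # zero designable sites
            return self.structure, self.total_energy([], refweight_override), []
        return self.realize(best_assignment), best, best_assignment


def _ca_dist(res_a: ResidueSite, res_b: ResidueSite) -> float:
    return float(np.linalg.norm(res_a.coord("CA") - res_b.coord("CA")))


# ---------------------------------------------------------------------------
# module-level API

def pack(
    structure: ProteinStructure,
    task: DesignTask,
    model: EnergyModel | None = None,
    seed: int = 0,
    schedule: AnnealingSchedule | None = None,
) -> tuple[ProteinStructure, float]:
    """Monte-Carlo pack; same seed, same result."""
    packer = Packer(structure, task, model)
    result, energy, _ = packer.pack(seed=seed, schedule=schedule)
    return result, energy


def exhaustive_pack(
    structure: ProteinStructure,
    task: DesignTask,
    model: EnergyModel | None = None,
) -> tuple[ProteinStructure, float]:
    """Global optimum by full enumeration (small instances only)."""
    packer = Packer(structure, task, model)
    result, energy, _ = packer.exhaustive()
    return result, energy
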