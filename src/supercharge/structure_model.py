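"""Atomic data model and PDB input/output.

The model is deliberately minimal: chains of canonical residues carrying
heavy atoms only.  Parsing drops everything the design protocols ignore
(HETATM records, waters, hydrogens, alternate locations after the first,
non-canonical residues) and requires an intact N/CA/C backbone per residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile

from . import build, chemdata
from .errors import LookupSiteError, ParseError, StructureError

logger = logging.getLogger(__name__)

#: (chain, residue number, insertion code) — the key identifying a residue
Site = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: PDB atom name, element and Cartesian position in A."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_backbone(self) -> bool:
        return self.name in chemdata.BACKBONE_ATOMS

    @property
    def is_sidechain(self) -> bool:
        return not self.is_backbone


@dataclass(frozen=True)
class ResidueSite:
    """A canonical residue at (chain, number, icode) with its atoms."""

    chain: str
    number: int
    icode: str
    aa: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self):
        if self.aa not in chemdata.CANONICAL_AA:
            raise ValueError(f"non-canonical residue type {self.aa!r}")
        names = [a.name for a in self.atoms]
        for required in ("N", "CA", "C"):
            if required not in names:
                raise ValueError(
                    f"residue {self.site} missing backbone atom {required}"
                )
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def site(self) -> Site:
        return (self.chain, self.number, self.icode)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.site} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coord(self, name: str) -> np.ndarray:
        return self.atom(name).position

    @property
    def backbone_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.is_backbone)

    @property
    def sidechain_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.is_sidechain)

    def coords_by_name(self) -> dict[str, np.ndarray]:
        return {a.name: a.position for a in self.atoms}


@dataclass
class ProteinStructure:
    """Ordered residues (file order within each chain) plus a source label."""

    residues: list[ResidueSite]
    source_name: str = ""
    _index: dict[Site, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.residues:
            raise StructureError("structure contains no residues")
        self._index = {}
        for i, res in enumerate(self.residues):
            if res.site in self._index:
                raise StructureError(f"duplicate residue site {res.site}")
            self._index[res.site] = i

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def get(self, site: Site) -> ResidueSite:
        try:
            return self.residues[self._index[tuple(site)]]
        except KeyError:
            raise LookupSiteError(f"no residue at site {site}") from None

    def has_site(self, site: Site) -> bool:
        return tuple(site) in self._index

    def sites(self) -> list[Site]:
        return [r.site for r in self.residues]

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def sequence(self, chain: str | None = None) -> str:
        return "".join(r.aa for r in self.residues if chain is None or r.chain == chain)

    def with_residue(self, site: Site, new_residue: ResidueSite) -> "ProteinStructure":
        residues = list(self.residues)
        residues[self._index[tuple(site)]] = new_residue
        return ProteinStructure(residues, source_name=self.source_name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigid-body transformed copy (x -> R x + t)."""
        residues = []
        for res in self.residues:
            atoms = tuple(
                replace(a, position=rotation @ a.position + translation)
                for a in res.atoms
            )
            residues.append(replace(res, atoms=atoms))
        return ProteinStructure(residues, source_name=self.source_name)

    def all_atom_positions(self) -> np.ndarray:
        return np.array([a.position for r in self.residues for a in r.atoms])


def read_pdb(path: str | Path, chain_filter: str | None = None) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    HETATM records (including waters and ligands), hydrogens and all but the
    first alternate location are discarded; residues with an incomplete
    N/CA/C backbone are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises various parse failures
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    keep = ~arr.hetero
    if keep.any() and np.any(np.char.strip(arr.chain_id[keep].astype(str)) == ""):
        raise ParseError(f"{path}: ATOM record without a chain identifier")

    keep &= ~np.isin(arr.element, ("H", "D"))
    canon3 = np.array(sorted(chemdata.AA3_TO_1), dtype="U3")
    keep &= np.isin(arr.res_name, canon3)
    if chain_filter is not None:
        keep &= arr.chain_id == chain_filter
    arr = arr[keep]

    residues: list[ResidueSite] = []
    if arr.array_length() > 0:
        ins = (
            arr.ins_code
            if "ins_code" in arr.get_annotation_categories()
            else np.full(arr.array_length(), "", dtype="U1")
        )
        order: list[Site] = []
        grouped: dict[Site, list[int]] = {}
        for i in range(arr.array_length()):
            site = (str(arr.chain_id[i]), int(arr.res_id[i]), str(ins[i]).strip())
            if site not in grouped:
                grouped[site] = []
                order.append(site)
            grouped[site].append(i)
        for site in order:
            idx = grouped[site]
            names = set()
            atoms = []
            for i in idx:
                name = str(arr.atom_name[i])
                if name in names:  # duplicate atom (altloc leakage); keep first
                    continue
                names.add(name)
                atoms.append(
                    AtomRecord(name, str(arr.element[i]).upper(), arr.coord[i].copy())
                )
            if not {"N", "CA", "C"} <= names:
                logger.warning(
                    "%s: dropping residue %s with incomplete backbone", path, site
                )
                continue
            aa = chemdata.AA3_TO_1[str(arr.res_name[idx[0]])]
            residues.append(ResidueSite(site[0], site[1], site[2], aa, tuple(atoms)))

    if not residues:
        raise StructureError(
            f"{path}: no canonical protein residues remain after filtering"
        )
    return ProteinStructure(residues, source_name=path.stem)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write standard fixed-width ATOM records with one TER per chain."""
    path = Path(path)
    lines = []
    serial = 0
    current_chain = None

    def ter_line(serial, res):
        return (
            f"TER   {serial:5d}      {chemdata.AA1_TO_3[res.aa]:>3s} "
            f"{res.chain:1s}{res.number:4d}{res.icode or '':1s}"
        )

    prev_res = None
    for res in structure.residues:
        if current_chain is not None and res.chain != current_chain:
            serial += 1
            lines.append(ter_line(serial, prev_res))
        current_chain = res.chain
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.position
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {chemdata.AA1_TO_3[res.aa]:>3s} "
                f"{res.chain:1s}{res.number:4d}{res.icode or '':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
        prev_res = res
    serial += 1
    lines.append(ter_line(serial, prev_res))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def net_formal_charge(structure: ProteinStructure) -> int:
    """(#Arg + #Lys) - (#Asp + #Glu); histidine neutral, termini ignored."""
    return sum(chemdata.FORMAL_CHARGE.get(r.aa, 0) for r in structure.residues)


def mutate_residue(
    structure: ProteinStructure,
    site: Site,
    new_aa: str,
    rotamers: dict | None = None,
) -> ProteinStructure:
    """Replace the side chain at ``site`` with the lowest-clash rotamer of
    ``new_aa`` built on the unchanged backbone.  Returns a new structure.
    """
    if new_aa not in chemdata.CANONICAL_AA:
        raise ValueError(f"non-canonical target type {new_aa!r}")
    library = (rotamers or chemdata.ROTAMER_LIBRARY)[new_aa]
    res = structure.get(site)
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")

    env_positions, env_elements = [], []
    for other in structure.residues:
        if other.site == res.site:
            continue
        for a in other.atoms:
            env_positions.append(a.position)
            env_elements.append(a.element)
    env_positions = np.array(env_positions) if env_positions else np.empty((0, 3))

    best = None
    for chis, _prob in library:
        candidate = build.build_sidechain_coords(new_aa, n, ca, c, chis)
        score = build.clash_score(candidate, env_positions, env_elements)
        if best is None or score < best[0] - 1e-12:
            best = (score, candidate)
    _, sidechain = best

    atoms = list(res.backbone_atoms) + [
        AtomRecord(name, element, pos) for name, element, pos in sidechain
    ]
    new_res = ResidueSite(res.chain, res.number, res.icode, new_aa, tuple(atoms))
    return structure.with_residue(site, new_res)
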