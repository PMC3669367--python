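"""Programmatic toy structures: ideal-geometry peptides and crafted
hydrogen-bond motifs.

Everything here is synthetic and built from ideal internal coordinates —
no downloads, no external templates.  Fixtures are deterministic for a
given spec; an optional perturbation seed adds small Gaussian coordinate
jitter so randomized test panels are not all bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import build, chemdata
from .errors import ValidationError
from .geometry import normalize, place_atom
from .structure_model import AtomRecord, ProteinStructure, ResidueSite

# ideal backbone internal coordinates
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8

BACKBONE_DIHEDRALS = {
    "ideal_helix": (-57.0, -47.0),
    "ideal_strand": (-120.0, 120.0),
    "extended": (180.0, 180.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic peptide: sequence, backbone class, jitter seed."""

    sequence: str
    backbone: str = "ideal_helix"
    perturbation_seed: int | None = None
    chain: str = "A"
    start_number: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError("fixture sequence must be non-empty")
        bad = set(self.sequence) - chemdata.CANONICAL_AA
        if bad:
            raise ValidationError(f"non-canonical letters in sequence: {sorted(bad)}")
        if self.backbone not in BACKBONE_DIHEDRALS:
            raise ValidationError(f"unknown backbone class {self.backbone!r}")


def _build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0):
    """N/CA/C/O coordinates for an ideal-dihedral chain."""
    coords = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_N_CA, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, _CA_C, _ANG_N_CA_C, 0.0)
    for i in range(n_res):
        if i > 0:
            n_next = place_atom(n, ca, c, _C_N, _ANG_CA_C_N, psi)
            ca_next = place_atom(ca, c, n_next, _N_CA, _ANG_C_N_CA, omega)
            c_next = place_atom(c, n_next, ca_next, _CA_C, _ANG_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
        o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, psi - 180.0)
        coords.append({"N": n, "CA": ca, "C": c, "O": o})
    return coords


def _lowest_clash_sidechain(aa, bb, env_positions, env_elements):
    best = None
    for chis, _prob in chemdata.ROTAMER_LIBRARY[aa]:
        atoms = build.build_sidechain_coords(aa, bb["N"], bb["CA"], bb["C"], chis)
        score = build.clash_score(atoms, env_positions, env_elements)
        if best is None or score < best[0] - 1e-12:
            best = (score, atoms)
    return best[1]


def make_structure(spec: FixtureSpec) -> ProteinStructure:
    """Build a peptide with ideal backbone geometry and clash-minimized
    template side chains.  Deterministic for a given spec."""
    phi, psi = BACKBONE_DIHEDRALS[spec.backbone]
    backbones = _build_backbone(len(spec.sequence), phi, psi)

    # environment grows as side chains are placed, so placement is sequential
    env_pos = [bb[name] for bb in backbones for name in ("N", "CA", "C", "O")]
    env_elem = ["N", "C", "C", "O"] * len(backbones)

    residues = []
    for i, (aa, bb) in enumerate(zip(spec.sequence, backbones)):
        sidechain = _lowest_clash_sidechain(
            aa, bb, np.array(env_pos), env_elem
        )
        atoms = [
            AtomRecord("N", "N", bb["N"]),
            AtomRecord("CA", "C", bb["CA"]),
            AtomRecord("C", "C", bb["C"]),
            AtomRecord("O", "O", bb["O"]),
        ] + [AtomRecord(name, elem, pos) for name, elem, pos in sidechain]
        for name, elem, pos in sidechain:
            env_pos.append(pos)
            env_elem.append(elem)
        residues.append(
            ResidueSite(spec.chain, spec.start_number + i, "", aa, tuple(atoms))
        )

    structure = ProteinStructure(residues, source_name=f"fixture_{spec.backbone}")
    if spec.perturbation_seed is not None:
        rng = np.random.default_rng(spec.perturbation_seed)
        jitter_res = []
        for res in structure.residues:
            atoms = tuple(
                replace(a, position=a.position + rng.normal(scale=0.03, size=3))
                for a in res.atoms
            )
            jitter_res.append(replace(res, atoms=atoms))
        structure = ProteinStructure(jitter_res, source_name=structure.source_name)
    return structure


def merge_structures(parts: list[ProteinStructure], name: str = "merged") -> ProteinStructure:
    residues = [r for part in parts for r in part.residues]
    return ProteinStructure(residues, source_name=name)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(u)))] = 1.0
    return normalize(np.cross(u, axis))


def _donor_glycine(acceptor: np.ndarray, base: np.ndarray, distance: float,
                   chain: str, number: int) -> ResidueSite:
    """A lone glycine whose backbone N donates to ``acceptor`` with collinear
    base->acceptor->N geometry (the model's ideal donor arrangement)."""
    u = normalize(acceptor - base)
    n = acceptor + distance * u
    ca = n + _N_CA * u
    perp = _perpendicular(u)
    c = place_atom(n + perp, n, ca, _CA_C, _ANG_N_CA_C, 90.0)
    o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, 40.0)
    atoms = (
        AtomRecord("N", "N", n), AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", c), AtomRecord("O", "O", o),
    )
    return ResidueSite(chain, number, "", "G", atoms)


def _acceptor_glycine(donor: np.ndarray, base: np.ndarray, distance: float,
                      chain: str, number: int) -> ResidueSite:
    """A lone glycine whose carbonyl O accepts from ``donor`` collinearly."""
    u = normalize(donor - base)
    o = donor + distance * u
    c = o + _C_O * u
    perp = _perpendicular(u)
    ca = place_atom(o + perp, o, c, _CA_C, _ANG_CA_C_O, 90.0)
    n = place_atom(o, c, ca, _N_CA, _ANG_N_CA_C, 160.0)
    atoms = (
        AtomRecord("N", "N", n), AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", c), AtomRecord("O", "O", o),
    )
    return ResidueSite(chain, number, "", "G", atoms)


HBOND_MOTIFS = ("sidechain_to_backbone_loop", "helix_cap", "NQ_donor_acceptor")

# donor-acceptor distances chosen on the model's linear ramp (ideal 2.8 A,
# zero at 3.6 A): 2.8 -> energy -1 (strong), 3.36 -> energy -0.3 (weak)
_STRONG_D, _WEAK_D = 2.8, 3.36


def make_hbond_motif(name: str) -> ProteinStructure:
    """A structure containing exactly one crafted strong (< -0.5) side-chain
    hydrogen bond, built by placing a partner glycine with ideal geometry."""
    if name == "sidechain_to_backbone_loop":
        core = make_structure(FixtureSpec("GADAG", backbone="extended"))
        asp = core.get(("A", 3, ""))
        partner = _donor_glycine(
            asp.coord("OD1"), asp.coord("CG"), _STRONG_D, "B", 1
        )
        return merge_structures(
            [core, ProteinStructure([partner])], name="motif_loop"
        )
    if name == "helix_cap":
        core = make_structure(FixtureSpec("NAAAA", backbone="ideal_helix"))
        asn = core.get(("A", 1, ""))
        partner = _donor_glycine(
            asn.coord("OD1"), asn.coord("CG"), _STRONG_D, "B", 1
        )
        return merge_structures(
            [core, ProteinStructure([partner])], name="motif_cap"
        )
    if name == "NQ_donor_acceptor":
        core = make_structure(FixtureSpec("GGNGG", backbone="extended"))
        asn = core.get(("A", 3, ""))
        acc_partner = _acceptor_glycine(
            asn.coord("ND2"), asn.coord("CG"), _STRONG_D, "B", 1
        )
        don_partner = _donor_glycine(
            asn.coord("OD1"), asn.coord("CG"), _WEAK_D, "C", 1
        )
        return merge_structures(
            [core, ProteinStructure([acc_partner]), ProteinStructure([don_partner])],
            name="motif_nq",
        )
    raise ValidationError(f"unknown hbond motif {name!r}")


def make_bundle(
    seq_a: str = "ADKELANQSLKA",
    seq_b: str = "ATNQKDLEVSQA",
    separation: float = 9.5,
) -> ProteinStructure:
    """Two parallel helices ~separation A apart: the facing residues pick up
    high neighbor counts, giving buried/surface contrast absent in a lone helix."""
    a = make_structure(FixtureSpec(seq_a, backbone="ideal_helix", chain="A"))
    b = make_structure(FixtureSpec(seq_b, backbone="ideal_helix", chain="B"))
    ca = np.array([r.coord("CA") for r in a.residues])
    axis = normalize(ca[-1] - ca[0])
    offset = _perpendicular(axis) * separation
    b = b.transformed(np.eye(3), offset)
    return merge_structures([a, b], name="bundle")


def fixture_panel(perturbation_seed: int | None = None) -> list[tuple[str, ProteinStructure]]:
    """The standard small panel used for protocol comparisons and tests."""
    seeds = [None] * 3
    if perturbation_seed is not None:
        ss = np.random.SeedSequence(perturbation_seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    panel = [
        (
            "helix16",
            make_structure(
                FixtureSpec("ANQEKDLSTNQRVKEA", "ideal_helix", seeds[0])
            ),
        ),
        (
            "strand12",
            make_structure(
                FixtureSpec("TNQVEDKSANQL", "ideal_strand", seeds[1])
            ),
        ),
        (
            "helix20",
            make_structure(
                FixtureSpec("AQNDKELSANQTVRENQKLA", "ideal_helix", seeds[2])
            ),
        ),
        ("bundle", make_bundle()),
    ]
    return panel
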